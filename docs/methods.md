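# Methods

## Problem setting

A metal-oxide-semiconductor (MOS) electronic nose is calibrated once on a
labeled batch of gas samples and then used for months.  Two nuisances
then degrade classification:

1. **Concentration background.**  The same analyte at different
   concentrations produces different array fingerprints (MOS steady-state
   response is roughly a power law `R_s = a_{s,g} · c^{β_{s,g}}`), so
   concentration inflates within-class spread, and — because the
   class-concentration composition of the data is rarely controlled —
   concentration also acts as a *confound* that classifiers exploit as a
   shortcut.
2. **Long-term sensor drift.**  Aging, poisoning and environment change
   the response curves between the calibration (source) batch and later
   (target) batches, shifting the class structure batch-coherently.

The package treats this as transductive transfer learning: target
batches are available (unlabeled) at fit time; no target label is ever
used before scoring.

## MICF: a concentration-independent kernel subspace

Labeled samples are assigned a concentration level, the integer part of
`ln c` (ppm), remapped to contiguous indices `1..c`.  Level one-hot codes
form `Y ∈ R^{c×n}` (all-zero columns for unlabeled samples) with linear
kernel `K_y = YᵀY`.  For a sample kernel `K_x` (linear by default) and
centering matrix `H = I − n⁻¹11ᵀ`, the transform `W ∈ R^{n×h}` with
`WᵀW = I` maximizes

    tr(−Wᵀ K_x H K_y H K_x W + μ Wᵀ K_x H K_x W),

i.e. projected variance minus an empirical-HSIC penalty on dependence
between the projected features `Z = Wᵀ K_x` and the concentration
levels.  The solution is the `h` leading eigenvectors of the symmetric
matrix `K_x(−H K_y H + μH)K_x`.  The empirical HSIC itself is
`(n−1)⁻² tr(K H L H)`; the scaling constant cancels in the argmax, so
only reported HSIC values depend on the `(n−1)` convention chosen here.

Numerical choices: the eigenproblem is solved with a dense symmetric
solver; eigenvalues are sorted descending; eigenvector signs are fixed
(largest-magnitude entry positive) and exact ties broken
lexicographically, so fits are bit-stable.  Log-concentration values
within 1e-9 of an integer are snapped before flooring so that
concentrations of exactly `e^k` land on level `k`.

Defaults: `μ = 1`, `h = min(m, n−1)` with `m` sensor features, linear
`K_x`.  Both are exposed in the run configuration.  Levels are computed
from source concentrations only; target columns of `Y` are zero.  `K_x`
is built over the union of source and target samples (transductive); no
out-of-sample extension is provided.

## IFLD: iterative pseudo-label Fisher discriminant

Fisher's discriminant uses the pooled within-class scatter
`S_w = Σ_i Σ_{z∈i} (z−μ_i)(z−μ_i)ᵀ` and the weighted between-class
scatter `S_b = Σ_i λ_i (μ_i−μ)(μ_i−μ)ᵀ` with `λ_i = n_i/N` by default
(per-class weights can be overridden).  The transform `V` stacks the `k`
leading generalized eigenvectors of `S_b V = λ(S_w + εI)V`, solved via
the symmetric-definite reduction; `ε = 1e-6·tr(S_w)/d`, floored at 1e-12
so the reduction stays valid when `S_w` is singular (e.g. singleton
classes).

Across domains the target labels are unknown, so IFLD alternates:
a benchmark classifier fit on the source predicts target pseudo-labels;
`S_w, S_b` are built on the union of true source labels and target
pseudo-labels; `V` is solved; the classifier is refit on `V`-projected
source features and the target re-predicted.  The loop stops when the
fraction of pseudo-labels changed between successive discriminant passes
is ≤ `tol` (default 0, i.e. exact stability — the first pass therefore
never terminates the loop) or after `max_iter` (default 20) passes.
`V` is recomputed from scratch each pass; transforms are not composed.
At `tol = 0`, convergence implies the returned classifier reproduces the
final pseudo-labels on the projected target exactly (a fixed point).

The default classifier is multinomial logistic regression — chosen as a
deterministic, convex benchmark learner; a seeded one-hidden-layer
feed-forward network (`classifier: mlp`) is available for users who want
a back-propagation-style learner.  Hard-EM schemes do not guarantee
monotone improvement, and none is asserted; the tests require only that
refinement does not fall below the one-shot source classifier on a
controlled drift family, and that the full pipeline wins on the
simulated protocol in the mean.

## Evaluation protocol

The earliest batch is the labeled source; every later batch is an
unlabeled target.  Each feature is z-scored within each batch
(population variance, ε-guarded), a transductive normalization that uses
each batch's own statistics.  MICF is fit once over all samples; IFLD
then adapts each target batch against the source independently (a
pooled-target variant is available).  Accuracy is the fraction of
correct labels per target batch; the reported average is the unweighted
mean over target batches (the sample-weighted alternative can be derived
from the emitted per-batch counts).  Hidden evaluation labels live in a
separate field of the data container that only the scoring step reads;
a test corrupts them and verifies predictions are unchanged.

## Synthetic data generator

The simulator emulates a multi-batch MOS acquisition campaign and emits
the field-standard log-conductance features

    x_s = ln a_{s,g} + β_{s,g} · d_{b,s} · ln c + ln(gain_b) + offset_b + ε,

with `ε ~ N(0, noise_sd)` (additive log-noise = multiplicative response
noise; the default 0.05 is 5% response noise).  Per-sensor base gains
are log-uniform on [0.5, 2] and shared across classes, modulated ±25%
per class; exponents are U(0.45, 0.85) per sensor, modulated ±0.12 per
class — class identity is thus carried both by a concentration-stable
gain pattern and by concentration-interacting slope differences, and the
fingerprint *shape* changes with concentration.

Three batch effects:

* **Affine drift** — per-batch gain (default 1 → 1.6) and offset.  The
  protocol's per-batch z-scoring removes per-feature affine effects
  exactly; this term only affects raw tables.
* **Exponent drift** — `d_{b,s} = 1 + (e_b − 1)·w_s` multiplies the
  response exponents, with a concave fast-early schedule
  `e_b = 1 + (0.6 − 1)·sqrt((b−1)/(B−1))` (aging is fastest right after
  calibration) and per-sensor susceptibilities `w_s ~ Beta(0.3, 0.3)`
  (a subset of sensors ages; the rest are stable).  This drift is
  nonlinear in concentration, survives standardization, and is
  class-coherent — the component IFLD suppresses.
* **Concentration composition shift** — each (batch, class) draws its
  concentrations from the 8-point log grid on [10, 1000] ppm with
  probabilities ∝ `c^γ`, `γ ~ U(−1.5, 1.5)`, emulating the uncontrolled
  composition of real long-term campaigns.  This makes concentration a
  confound whose shortcut value breaks across batches — the effect MICF
  removes.  With `concentration_tilt = 0` the generator produces the
  exact balanced (batch, class, concentration) cell design used by the
  deterministic invariants in the test suite.

The default scenario is 3 classes × 8 sensors × 5 batches × 40
samples/class/batch (8 grid points × 5 replicates); batch 1 is the
labeled source, batches 2–5 are targets with truth hidden in the
evaluation fields.  Everything derives from one integer seed and is
byte-reproducible.

What the generator does **not** model: physically calibrated MOS
chemistry (Clifford–Tuma response forms, humidity/temperature
dependence), transient-feature extraction, cross-sensitivity mixing
between analytes, and label noise.  Passing tests therefore show that
the pipeline removes additive log-domain concentration structure and
suppresses class-coherent exponent drift; they do not certify
performance on raw-conductance features or on drift mechanisms outside
this family.

## Problem sizes used by the tests and the acceptance script

The default scenario (600 samples, 8 features) keeps a full
three-pipeline comparison under half a second, so the end-to-end checks
average 12–20 independent simulated campaigns; estimator-level checks
use 50–100 random instances of size n ≤ 10 against brute-force oracles.

## Known limitations

* With a linear sample kernel and `h` equal to the feature count, the
  MICF projection spans the full feature space and differs from the raw
  features only through the regularization geometry of the downstream
  classifier; genuine removal requires `h` below the feature rank or a
  nonlinear kernel.  The default keeps the variance-preserving `h`;
  users targeting aggressive concentration removal should lower `h` or
  raise the penalty via `μ`.
* Hard pseudo-labels can entrench errors when the one-shot source
  classifier starts poorly (≲ 60% on three classes); confidence
  thresholding and soft labels are deliberately out of scope.
* The per-batch z-scoring assumes each target batch is fully available
  before prediction (transductive deployment).
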