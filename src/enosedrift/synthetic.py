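"""Synthetic multi-batch E-nose data with concentration and drift effects.

Metal-oxide sensor steady-state responses follow a power law in analyte
concentration, R_s = a_{s,g} * c^{beta_{s,g}}, with gain a and exponent
beta depending on both the sensor s and the gas class g.  The simulator
emits the standard log-conductance features

    x_s = ln a_{s,g} + beta_{s,g} * d_{b,s} * ln c + ln gain_b + offset_b + eps,

so concentration enters as an additive component along the exponent
pattern, class identity as a concentration-independent gain pattern, and
multiplicative response noise becomes additive Gaussian noise eps with
standard deviation ``noise_sd`` (0.05 = 5% response noise).

Three batch effects are simulated:

* affine drift — per-batch gain factor (default 1 -> 1.6) and offset on
  every sensor: classical sensitivity/baseline drift.  The evaluation
  protocol's per-batch z-scoring removes per-feature affine effects
  exactly, so this mechanism alone cannot degrade a classifier that sees
  standardized features; it is kept for realism of the raw tables.
* exponent drift — a per-batch factor d_{b,s} on the response exponents
  (aging changes the dose-response slope), concentrated on a random
  subset of drift-susceptible sensors and fastest right after
  calibration (concave schedule).  It is nonlinear in concentration,
  survives standardization, and is class-coherent — the component the
  iterative discriminant has to absorb.
* concentration composition shift — each (batch, class) pair draws its
  concentrations from the grid with a random tilt p(c) ~ c^gamma,
  gamma ~ U(-tilt, tilt), emulating the uncontrolled class-concentration
  composition of real long-term acquisitions.  This makes concentration
  a confound: a classifier trained on raw source features learns
  magnitude shortcuts that break in later batches, which is precisely
  the "concentration background" the MICF subspace removes.

Batch 1 is the labeled source; later batches are targets whose true
labels and concentrations are moved into the hidden evaluation fields.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_data import UNLABELED, SampleSet


@dataclass
class DriftSimConfig:
    """Simulator settings; the defaults are the "tab3-mini" scenario.

    samples_per_cell counts replicates per (batch, class, concentration)
    cell, so each class contributes len(concentration_grid) *
    samples_per_cell samples per batch (40 by default).  With
    ``concentration_tilt > 0`` the same number of samples per class is
    drawn from the grid with tilted probabilities instead of the exact
    balanced design.
    """

    n_classes: int = 3
    n_sensors: int = 8
    n_batches: int = 5
    samples_per_cell: int = 5
    concentration_grid: tuple[float, ...] = tuple(
        float(c) for c in np.geomspace(10.0, 1000.0, 8)
    )
    response_gain: np.ndarray | None = None        # (n_sensors, n_classes)
    response_exponent: np.ndarray | None = None    # (n_sensors, n_classes)
    batch_gain_drift: tuple[float, ...] | None = None      # default 1 -> 1.6
    batch_offset_drift: tuple[float, ...] | None = None    # default 0
    batch_exponent_drift: tuple[float, ...] | None = None  # default 1 -> 0.6
    drift_susceptibility: np.ndarray | None = None  # per-sensor, in [0, 1]
    concentration_tilt: float = 1.5
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_classes", "n_sensors", "n_batches", "samples_per_cell"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        conc = np.asarray(self.concentration_grid, dtype=float)
        if conc.size == 0 or np.any(conc <= 0) or np.any(~np.isfinite(conc)):
            raise ValueError("concentration_grid must be positive and finite")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.concentration_tilt < 0:
            raise ValueError("concentration_tilt must be nonnegative")
        for name in (
            "batch_gain_drift",
            "batch_offset_drift",
            "batch_exponent_drift",
        ):
            v = getattr(self, name)
            if v is not None:
                v = tuple(float(x) for x in v)
                if len(v) != self.n_batches or not np.all(np.isfinite(v)):
                    raise ValueError(
                        f"{name} must give one finite factor per batch"
                    )
                setattr(self, name, v)


def _default_response(
    rng: np.random.Generator, n_sensors: int, n_classes: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-(sensor, class) power-law gains and exponents.

    Base gain per sensor is log-uniform on [0.5, 2] and shared across
    classes (raw magnitude alone is not a class giveaway), modulated
    +/-25% per class; exponents are U(0.45, 0.85) per sensor with +/-0.12
    class modulation, so classes differ in both their gain pattern
    (concentration-stable evidence) and their dose-response slopes
    (concentration-interacting evidence).
    """
    base_gain = np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=n_sensors))
    gain_mod = rng.uniform(-1.0, 1.0, size=(n_sensors, n_classes))
    a = base_gain[:, None] * (1.0 + 0.25 * gain_mod)
    base_exp = rng.uniform(0.45, 0.85, size=n_sensors)
    exp_mod = rng.uniform(-1.0, 1.0, size=(n_sensors, n_classes))
    beta = np.clip(base_exp[:, None] + 0.12 * exp_mod, 0.05, 1.0)
    return a, beta


def _concave(n: int, end: float) -> np.ndarray:
    """Fast-early drift schedule: 1 + (end - 1) * sqrt(t), t in [0, 1]."""
    if n == 1:
        return np.ones(1)
    t = np.arange(n) / (n - 1)
    return 1.0 + (end - 1.0) * np.sqrt(t)


def simulate_enose(config: DriftSimConfig | None = None) -> SampleSet:
    """Generate a multi-batch dataset; reproducible from ``config.seed``.

    Batch 1 is returned as labeled source; batches >= 2 are targets with
    labels/concentrations hidden in the evaluation fields.  Classes are
    1..n_classes; batches 1..n_batches.
    """
    cfg = config or DriftSimConfig()
    rng = np.random.default_rng(cfg.seed)
    a, beta = _default_response(rng, cfg.n_sensors, cfg.n_classes)
    w_default = rng.beta(0.3, 0.3, size=cfg.n_sensors)
    if cfg.response_gain is not None:
        a = np.asarray(cfg.response_gain, dtype=float)
    if cfg.response_exponent is not None:
        beta = np.asarray(cfg.response_exponent, dtype=float)
    if a.shape != (cfg.n_sensors, cfg.n_classes) or beta.shape != a.shape:
        raise ValueError("response arrays must be (n_sensors, n_classes)")
    if np.any(a <= 0) or np.any(beta <= 0) or np.any(beta > 1):
        raise ValueError("gains must be > 0 and exponents in (0, 1]")
    w = (
        np.asarray(cfg.drift_susceptibility, dtype=float)
        if cfg.drift_susceptibility is not None
        else w_default
    )
    if w.shape != (cfg.n_sensors,) or np.any(w < 0) or np.any(w > 1):
        raise ValueError("drift_susceptibility must be per-sensor in [0, 1]")
    gain_drift = (
        np.asarray(cfg.batch_gain_drift, float)
        if cfg.batch_gain_drift is not None
        else np.linspace(1.0, 1.6, cfg.n_batches)
    )
    if np.any(gain_drift <= 0):
        raise ValueError("batch gain factors must be positive")
    offset_drift = (
        np.asarray(cfg.batch_offset_drift, float)
        if cfg.batch_offset_drift is not None
        else np.zeros(cfg.n_batches)
    )
    exp_drift = (
        np.asarray(cfg.batch_exponent_drift, float)
        if cfg.batch_exponent_drift is not None
        else _concave(cfg.n_batches, 0.6)
    )
    grid = np.asarray(cfg.concentration_grid, dtype=float)
    log_a = np.log(a)

    feats, labels, concs, batch_ids = [], [], [], []
    n_per_class = grid.size * cfg.samples_per_cell
    for b in range(cfg.n_batches):
        d_bs = 1.0 + (exp_drift[b] - 1.0) * w
        for g in range(cfg.n_classes):
            if cfg.concentration_tilt > 0:
                gamma = rng.uniform(
                    -cfg.concentration_tilt, cfg.concentration_tilt
                )
                p = grid**gamma
                cs = rng.choice(grid, size=n_per_class, p=p / p.sum())
            else:
                cs = np.repeat(grid, cfg.samples_per_cell)
            for c in cs:
                x = (
                    log_a[:, g]
                    + beta[:, g] * d_bs * np.log(c)
                    + np.log(gain_drift[b])
                    + offset_drift[b]
                )
                feats.append(x)
                labels.append(g + 1)
                concs.append(float(c))
                batch_ids.append(b + 1)
    X = np.vstack(feats)
    if cfg.noise_sd > 0:
        X = X + rng.normal(0.0, cfg.noise_sd, size=X.shape)
    y = np.asarray(labels)
    conc = np.asarray(concs, dtype=float)
    batch = np.asarray(batch_ids)

    is_source = batch == 1
    return SampleSet(
        features=X,
        batch_ids=batch,
        labels=np.where(is_source, y, UNLABELED),
        concentrations=np.where(is_source, conc, np.nan),
        is_source=is_source,
        eval_labels=y,
        eval_concentrations=conc,
    )
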