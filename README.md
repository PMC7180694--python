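# enosedrift

Concentration- and drift-robust gas classification for metal-oxide
(MOS) electronic noses.

An E-nose is calibrated once on labeled samples and then drifts: the
same gas at a different concentration produces a different array
fingerprint, and sensor aging shifts the data distribution batch by
batch, so a classifier trained at calibration time quietly decays.
`enosedrift` implements a two-stage transductive transfer-learning
pipeline for this setting:

* **MICF** (Maximum Independence of the Concentration Features) — learns
  an orthonormal kernel projection `W` maximizing
  `tr(−WᵀK_x H K_y H K_x W + μ WᵀK_x H K_x W)`, i.e. projected variance
  minus a Hilbert–Schmidt Independence Criterion (HSIC) penalty against
  a concentration-level kernel `K_y = YᵀY`, where levels are the integer
  part of `ln c` (ppm).  The solution is the top-`h` eigenvectors of
  `K_x(−HK_yH + μH)K_x`.
* **IFLD** (Iterative Fisher Linear Discriminant) — adapts to unlabeled
  target batches EM-style: a source-trained classifier predicts target
  pseudo-labels, Fisher scatter matrices are built on the labeled+pseudo
  union, the discriminant `S_bV = λ(S_w+εI)V` is solved, the classifier
  is refit on `V`-projected source features, and the loop repeats until
  the pseudo-labels stabilize.

The package also ships a seeded synthetic MOS campaign simulator (power
-law responses, concentration-composition confounding, sensor-specific
aging drift), readers/writers for a generic CSV schema and the
`label;concentration i:v ...` drift-benchmark dialect, and the standard
evaluation protocol (train on batch 1, test on every later batch).

## Worked example

```python
from enosedrift import DriftSimConfig, MethodConfig, run_batch_protocol, simulate_enose

data = simulate_enose(DriftSimConfig(seed=0))   # 3 gases, 8 sensors, 5 batches
for tag, kw in [("baseline", dict(use_micf=False, use_ifld=False)),
                ("micf",     dict(use_micf=True,  use_ifld=False)),
                ("micf-ifld", dict())]:
    res = run_batch_protocol(data, MethodConfig(**kw))
    print(tag, {b: round(a, 3) for b, a in res.per_batch_accuracy.items()},
          "avg", round(res.average_accuracy, 4))
```

prints

```
baseline {2: 1.0, 3: 1.0, 4: 0.65, 5: 0.75} avg 0.85
micf {2: 1.0, 3: 0.667, 4: 0.75, 5: 0.875} avg 0.8229
micf-ifld {2: 1.0, 3: 0.933, 4: 0.783, 5: 1.0} avg 0.9292
```

Batch 1 is the labeled calibration batch; the dictionaries map each
later (unlabeled) batch to the fraction of its samples classified
correctly, scored against labels the pipeline never saw, and `avg` is
the unweighted mean over target batches.  On this seed the raw-feature
baseline loses up to 35 points on late batches as drift accumulates;
the full pipeline recovers most of it.  Single seeds vary — averaged
over many simulated campaigns the ordering baseline < MICF < MICF-IFLD
is stable (see below).

The same run from the shell:

```sh
enosedrift simulate --out-dir demo --seed 0
enosedrift run-protocol --data demo/dataset.csv
```

```
batch	n	n_correct	accuracy
2	120	120	1.0
3	120	112	0.9333333333333333
4	120	94	0.7833333333333333
5	120	120	1.0
average	480	446	0.9291666666666667
```

`enosedrift uci-protocol --dir <dir>` runs the same protocol on a
directory of `batch1.dat … batchN.dat` files in the drift-benchmark
dialect.  Every default (kernel, `μ`, `h`, classifier, stopping rule)
can be overridden with a YAML config passed via `--config`; see
`enosedrift.MethodConfig`.

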