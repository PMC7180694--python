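"""Iterative Fisher linear discriminant (IFLD) with pseudo-labels.

Long-term sensor drift shifts the class structure between the calibration
(source) batch and later (target) batches, and the class mixture itself
can differ across batches.  IFLD adapts in an EM-like loop: a benchmark
classifier trained on the source predicts pseudo-labels for the target;
Fisher scatter matrices are then built on the *union* of true source
labels and target pseudo-labels, the discriminant transform V is solved,
the classifier is refit on V-projected source features, and the target is
re-predicted — until the pseudo-labels stop changing.

Monotone improvement is not guaranteed (as with any hard-EM scheme), but
on drift of moderate size the refined labels track the drifted class
structure better than the one-shot source classifier.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
from sklearn.base import clone as _sk_clone
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier

from .fld import FLDModel, scatter_matrices, solve_fld


class DegenerateClassError(RuntimeError):
    """A class vanished from the source+pseudo-label union mid-iteration."""


@runtime_checkable
class ClassifierContract(Protocol):
    """Anything with sklearn-style fit/predict; deterministic given a seed."""

    def fit(self, X, y): ...

    def predict(self, X): ...


def make_classifier(name: str = "logistic", seed: int = 0, **params) -> ClassifierContract:
    """Benchmark classifier factory.

    ``logistic``      multinomial logistic regression (deterministic, convex;
                      the default benchmark learner)
    ``mlp``           one-hidden-layer feed-forward network (seeded), for
                      closer fidelity to a back-propagation network
    """
    if name == "logistic":
        defaults = dict(max_iter=2000)
        defaults.update(params)
        return LogisticRegression(**defaults)
    if name == "mlp":
        defaults = dict(
            hidden_layer_sizes=(32,), max_iter=800, random_state=seed
        )
        defaults.update(params)
        return MLPClassifier(**defaults)
    raise ValueError(f"unknown classifier {name!r}")


def _clone(clf: ClassifierContract) -> ClassifierContract:
    try:
        return _sk_clone(clf)
    except TypeError:
        return copy.deepcopy(clf)


@dataclass
class IFLDResult:
    """Outcome of the pseudo-label refinement loop.

    V                     final discriminant transform (d x k)
    classifier            classifier fitted on V-projected source features
    initial_pseudo_labels the one-shot source-classifier predictions
                          (the pre-loop baseline)
    pseudo_label_history  target label vector after each FLD pass
    n_iterations          number of FLD passes performed
    converged             True if the last two history entries agree to
                          within the change tolerance
    fld_model             FLDModel of the final pass
    """

    V: np.ndarray
    classifier: ClassifierContract
    initial_pseudo_labels: np.ndarray
    pseudo_label_history: list[np.ndarray]
    n_iterations: int
    converged: bool
    fld_model: FLDModel | None = None

    @property
    def final_pseudo_labels(self) -> np.ndarray:
        return self.pseudo_label_history[-1]


def write_pseudo_label_history(result: "IFLDResult", path) -> None:
    """Audit TSV: one row per target sample, one column per FLD pass
    (plus the pre-loop source-classifier labels)."""
    import pandas as pd

    cols = {"initial": result.initial_pseudo_labels}
    for i, labels in enumerate(result.pseudo_label_history, start=1):
        cols[f"iter{i}"] = labels
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def run_ifld(
    Z_source: np.ndarray,
    y_source: Sequence[int],
    Z_target: np.ndarray,
    clf: ClassifierContract | None = None,
    k: int | None = None,
    max_iter: int = 20,
    tol: float = 0.0,
    source_only_scatter: bool = False,
) -> IFLDResult:
    """Run the IFLD loop on already-projected features (samples as rows).

    Step 0 fits ``clf`` on the source and predicts initial target
    pseudo-labels.  Each iteration then builds S_w/S_b on source plus
    pseudo-labeled target (or source only under ``source_only_scatter``),
    solves the Fisher eigenproblem for V, refits a fresh clone of ``clf``
    on V-projected source features and re-predicts the target.  The loop
    stops when the fraction of pseudo-labels changed between successive
    FLD passes is <= ``tol`` or after ``max_iter`` passes.  V is recomputed
    from scratch every pass (no composition across iterations).
    """
    Zs = np.asarray(Z_source, dtype=float)
    Zt = np.asarray(Z_target, dtype=float)
    ys = np.asarray(y_source)
    if Zs.ndim != 2 or Zt.ndim != 2 or Zs.shape[1] != Zt.shape[1]:
        raise ValueError("source and target must share the feature dimension")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    clf = clf if clf is not None else make_classifier()
    d = Zs.shape[1]
    classes = np.unique(ys)
    if classes.size < 2:
        raise DegenerateClassError("need at least 2 source classes")
    if k is None:
        k = min(d, classes.size - 1)
    if not 1 <= k <= d:
        raise ValueError(f"k={k} outside 1..{d}")

    clf0 = _clone(clf)
    clf0.fit(Zs, ys)
    pseudo = np.asarray(clf0.predict(Zt))
    initial = pseudo.copy()

    history: list[np.ndarray] = []
    converged = False
    V = np.eye(d)[:, :k]
    fld_model: FLDModel | None = None
    clf_it: ClassifierContract = clf0
    for it in range(1, max_iter + 1):
        if source_only_scatter:
            Z_union, y_union = Zs, ys
        else:
            Z_union = np.vstack([Zs, Zt])
            y_union = np.concatenate([ys, pseudo])
        present = np.unique(y_union)
        missing = np.setdiff1d(classes, present)
        if missing.size:
            raise DegenerateClassError(
                f"class(es) {missing.tolist()} vanished from the "
                f"source+pseudo-label union at iteration {it}"
            )
        Sw, Sb = scatter_matrices(Z_union, y_union)
        fld_model = solve_fld(Sw, Sb, k=k)
        V = fld_model.V
        clf_it = _clone(clf)
        clf_it.fit(Zs @ V, ys)
        new_pseudo = np.asarray(clf_it.predict(Zt @ V))
        history.append(new_pseudo.copy())
        change = float(np.mean(new_pseudo != pseudo))
        pseudo = new_pseudo
        # Convergence compares successive post-FLD label vectors, so the
        # first pass never terminates the loop on its own.
        if it >= 2 and change <= tol:
            converged = True
            break
    return IFLDResult(
        V=V,
        classifier=clf_it,
        initial_pseudo_labels=initial,
        pseudo_label_history=history,
        n_iterations=len(history),
        converged=converged,
        fld_model=fld_model,
    )
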