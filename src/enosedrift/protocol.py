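"""Batch evaluation protocol: train on the first batch, test on the rest.

The earliest batch is the labeled calibration (source) domain; every
later batch is an unlabeled target domain.  The pipeline standardizes
each batch, builds the sample kernel K_x over the union of all samples
(transductive), fits MICF once, projects, and then adapts each target
batch against the source independently with IFLD.  Accuracy is scored
against the hidden evaluation labels only after all predictions are
made; the reported average is the unweighted mean over target batches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import micf as _micf
from .config import MethodConfig
from .ifld import make_classifier, run_ifld, _clone
from .io_data import SampleSet, standardize_per_batch
from .kernels import gram
from .micf import MICFModel

log = logging.getLogger("enosedrift")


class ProtocolError(ValueError):
    """The dataset does not satisfy the batch-protocol preconditions."""


@dataclass
class ProtocolResult:
    """Per-batch and average accuracy plus the full run record.

    per_batch_accuracy maps target batch id -> fraction correct;
    average_accuracy is the unweighted mean over target batches.
    predictions holds the final per-batch predicted labels so callers can
    audit or re-score without re-running.
    """

    per_batch_accuracy: dict[int, float]
    average_accuracy: float
    method_tag: str
    run_config: dict
    predictions: dict[int, np.ndarray] = field(default_factory=dict)
    n_per_batch: dict[int, int] = field(default_factory=dict)
    n_correct: dict[int, int] = field(default_factory=dict)
    n_iterations: dict[int, int] = field(default_factory=dict)

    def to_table(self) -> pd.DataFrame:
        rows = [
            {
                "batch": b,
                "n": self.n_per_batch.get(b, 0),
                "n_correct": self.n_correct.get(b, 0),
                "accuracy": acc,
            }
            for b, acc in sorted(self.per_batch_accuracy.items())
        ]
        rows.append(
            {
                "batch": "average",
                "n": sum(self.n_per_batch.values()),
                "n_correct": sum(self.n_correct.values()),
                "accuracy": self.average_accuracy,
            }
        )
        return pd.DataFrame(rows)


def accuracy(y_true: Sequence[int], y_pred: Sequence[int]) -> float:
    """Fraction of exactly matching labels."""
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    if yt.shape != yp.shape or yt.ndim != 1:
        raise ValueError("label vectors must be 1-d and of equal length")
    if yt.size == 0:
        raise ValueError("empty label vectors")
    return float(np.mean(yt == yp))


def _prepare_features(
    data: SampleSet, config: MethodConfig
) -> tuple[np.ndarray, MICFModel | None]:
    """Standardized (and optionally MICF-projected) samples-as-rows features."""
    if not config.use_micf:
        return data.features, None
    src = data.is_source
    coding = _micf.concentration_levels(data.concentrations[src])
    Y = _micf.build_concentration_features(
        coding.levels,
        src,
        data.n_samples,
        n_levels=coding.n_levels,
        level_map=coding.level_map,
        level_coded=config.level_coded,
    )
    Kx = gram(data.features, config.kernel)
    Ky = _micf.concentration_kernel(Y)
    h = config.h
    if h is None:
        h = min(data.n_features, data.n_samples - 1)
    model = _micf.fit_micf(
        Kx,
        Ky,
        mu=config.mu,
        h=h,
        kernel_spec=config.kernel,
        level_map=coding.level_map,
    )
    Z = _micf.project(model, Kx)  # h x n
    return Z.T, model


def fit_micf_on(data: SampleSet, config: MethodConfig | None = None) -> MICFModel:
    """Standardize, build kernels, and fit the MICF model on a dataset."""
    config = config or MethodConfig()
    data = standardize_per_batch(data)
    _, model = _prepare_features(data, config)
    if model is None:
        raise ValueError("config.use_micf is False; nothing to fit")
    return model


def run_batch_protocol(
    data: SampleSet, config: MethodConfig | None = None
) -> ProtocolResult:
    """Execute the source-batch / target-batches protocol end to end."""
    config = config or MethodConfig()
    batches = data.batches
    if batches.size < 2:
        raise ProtocolError("protocol requires at least 2 distinct batches")
    source_batch = int(batches.min())
    in_source = data.batch_ids == source_batch
    if not np.all(data.is_source[in_source]):
        raise ProtocolError(
            f"source batch {source_batch} must be fully labeled"
        )
    if np.any(data.is_source & ~in_source):
        raise ProtocolError("labeled samples found outside the source batch")

    data = standardize_per_batch(data)
    Z, micf_model = _prepare_features(data, config)

    src = data.is_source
    Zs = Z[src]
    ys = data.labels[src]
    n_classes = np.unique(ys).size
    k = config.k if config.k is not None else max(1, n_classes - 1)
    clf_proto = make_classifier(
        config.classifier, seed=config.seed, **config.classifier_params
    )

    target_batches = [int(b) for b in batches if b != source_batch]
    if config.pooled_target:
        groups = [target_batches]
    else:
        groups = [[b] for b in target_batches]

    predictions: dict[int, np.ndarray] = {}
    n_iterations: dict[int, int] = {}
    for group in groups:
        rows = np.isin(data.batch_ids, group) & ~src
        Zt = Z[rows]
        if config.use_ifld:
            res = run_ifld(
                Zs,
                ys,
                Zt,
                clf=clf_proto,
                k=min(k, Z.shape[1]),
                max_iter=config.max_iter,
                tol=config.tol,
                source_only_scatter=config.source_only_scatter,
            )
            preds = res.final_pseudo_labels
            iters = res.n_iterations
        else:
            clf = _clone(clf_proto)
            clf.fit(Zs, ys)
            preds = np.asarray(clf.predict(Zt))
            iters = 0
        batch_of_row = data.batch_ids[rows]
        for b in group:
            predictions[b] = preds[batch_of_row == b]
            n_iterations[b] = iters
        log.debug("batches %s: %d iterations", group, iters)

    # Scoring: the only place hidden evaluation labels are read.
    if data.eval_labels is None:
        raise ProtocolError("dataset carries no evaluation labels to score")
    per_batch: dict[int, float] = {}
    n_per_batch: dict[int, int] = {}
    n_correct: dict[int, int] = {}
    for b in target_batches:
        truth = data.eval_labels[(data.batch_ids == b) & ~src]
        preds = predictions[b]
        per_batch[b] = accuracy(truth, preds)
        n_per_batch[b] = int(truth.size)
        n_correct[b] = int(np.sum(truth == preds))
    avg = float(np.mean([per_batch[b] for b in target_batches]))
    return ProtocolResult(
        per_batch_accuracy=per_batch,
        average_accuracy=avg,
        method_tag=config.method_tag,
        run_config=config.to_dict(),
        predictions=predictions,
        n_per_batch=n_per_batch,
        n_correct=n_correct,
        n_iterations=n_iterations,
    )


def run_uci_protocol(
    directory: str | Path,
    config: MethodConfig | None = None,
    pattern: str = "batch*.dat",
) -> ProtocolResult:
    """Assemble ``batch<k>`` dialect files from a directory and run the
    protocol, hiding the labels of every batch after the first."""
    from .io_data import UNLABELED, read_uci_drift_file

    import re

    directory = Path(directory)
    files = sorted(
        directory.glob(pattern),
        key=lambda p: int(re.search(r"batch(\d+)", p.stem).group(1)),
    )
    if not files:
        raise ProtocolError(f"no files matching {pattern!r} in {directory}")
    parts = [read_uci_drift_file(path) for path in files]
    min_batch = min(int(p.batch_ids[0]) for p in parts)
    hidden_parts = []
    for part in parts:
        if int(part.batch_ids[0]) == min_batch:
            hidden_parts.append(part)
        else:
            hidden_parts.append(
                SampleSet(
                    features=part.features,
                    batch_ids=part.batch_ids,
                    labels=np.full(part.n_samples, UNLABELED),
                    concentrations=np.full(part.n_samples, np.nan),
                    is_source=np.zeros(part.n_samples, dtype=bool),
                    eval_labels=part.eval_labels,
                    eval_concentrations=part.eval_concentrations,
                )
            )
    return run_batch_protocol(SampleSet.concatenate(hidden_parts), config)
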