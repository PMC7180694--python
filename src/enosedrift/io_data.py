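"""Sensor-array sample tables: containers, file dialects, per-batch scaling.

A :class:`SampleSet` holds one multi-batch E-nose dataset with samples as
rows.  Source (calibration) samples carry a class label and a gas
concentration in ppm; target samples are unlabeled at fit time.  True
target labels, when known (simulations, benchmark files), live in a
separate evaluation field that fitting code never touches — only the
scoring step of the protocol reads it.

Two dialects are supported: a generic delimited table with a header, and
the libsvm-like dialect used by the public gas-sensor drift benchmark
(``label;concentration i:v i:v ...``, one sample per line, batch number in
the file name).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

UNLABELED = -1
_EPS_SD = 1e-12


class FormatError(ValueError):
    """Structurally invalid input file (bad indices, bad dialect)."""


class ParseError(FormatError):
    """A line or cell could not be parsed; message names the location."""


class SchemaError(ValueError):
    """Column-role schema does not match the table."""


@dataclass
class SampleSet:
    """Feature table with labels, concentrations, batch ids and roles.

    features        (n, m) float array, samples as rows
    batch_ids       (n,) int array
    labels          (n,) int array; class >= 0 for source rows, -1 otherwise
    concentrations  (n,) float array, ppm; NaN for target rows
    is_source       (n,) bool; True where the sample is labeled/source
    eval_labels     optional (n,) int array of hidden true labels
                    (evaluation only; -1 where unknown)
    eval_concentrations  optional (n,) float hidden true concentrations
    """

    features: np.ndarray
    batch_ids: np.ndarray
    labels: np.ndarray
    concentrations: np.ndarray
    is_source: np.ndarray
    eval_labels: np.ndarray | None = None
    eval_concentrations: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.features = np.atleast_2d(np.asarray(self.features, dtype=float))
        self.batch_ids = np.asarray(self.batch_ids, dtype=int)
        self.labels = np.asarray(self.labels, dtype=int)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.is_source = np.asarray(self.is_source, dtype=bool)
        if self.eval_labels is not None:
            self.eval_labels = np.asarray(self.eval_labels, dtype=int)
        if self.eval_concentrations is not None:
            self.eval_concentrations = np.asarray(
                self.eval_concentrations, dtype=float
            )
        n, m = self.features.shape
        if n < 2:
            raise ValueError("a SampleSet needs at least 2 samples")
        if m < 1:
            raise ValueError("a SampleSet needs at least 1 feature")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features contain non-finite values")
        for name in ("batch_ids", "labels", "concentrations", "is_source"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"{name} must have length {n}")
        if np.any(self.labels[self.is_source] < 0):
            raise ValueError("every source sample must carry a label >= 0")
        src_conc = self.concentrations[self.is_source]
        if np.any(~np.isfinite(src_conc)) or np.any(src_conc <= 0):
            raise ValueError("source concentrations must be finite and > 0")
        # Target labels must not leak into the visible fields.
        self.labels = np.where(self.is_source, self.labels, UNLABELED)
        self.concentrations = np.where(
            self.is_source, self.concentrations, np.nan
        )

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def batches(self) -> np.ndarray:
        return np.unique(self.batch_ids)

    def subset(self, index: np.ndarray) -> "SampleSet":
        """Row subset preserving order; evaluation fields follow along."""
        return SampleSet(
            features=self.features[index],
            batch_ids=self.batch_ids[index],
            labels=self.labels[index],
            concentrations=self.concentrations[index],
            is_source=self.is_source[index],
            eval_labels=None if self.eval_labels is None else self.eval_labels[index],
            eval_concentrations=(
                None
                if self.eval_concentrations is None
                else self.eval_concentrations[index]
            ),
        )

    @staticmethod
    def concatenate(parts: Sequence["SampleSet"]) -> "SampleSet":
        if not parts:
            raise ValueError("nothing to concatenate")

        def _eval(p: "SampleSet", attr: str, fill):
            v = getattr(p, attr)
            if v is not None:
                return v
            return np.full(p.n_samples, fill)

        return SampleSet(
            features=np.vstack([p.features for p in parts]),
            batch_ids=np.concatenate([p.batch_ids for p in parts]),
            labels=np.concatenate([p.labels for p in parts]),
            concentrations=np.concatenate([p.concentrations for p in parts]),
            is_source=np.concatenate([p.is_source for p in parts]),
            eval_labels=np.concatenate(
                [_eval(p, "eval_labels", UNLABELED) for p in parts]
            ).astype(int),
            eval_concentrations=np.concatenate(
                [_eval(p, "eval_concentrations", np.nan) for p in parts]
            ),
        )


# ---------------------------------------------------------------------------
# UCI drift-benchmark dialect
# ---------------------------------------------------------------------------

_BATCH_RE = re.compile(r"batch(\d+)", re.IGNORECASE)
_HEAD_RE = re.compile(r"^\s*(\d+)\s*;\s*([0-9eE+.\-]+)\s*$")


def _batch_from_filename(path: Path) -> int | None:
    m = _BATCH_RE.search(path.stem)
    return int(m.group(1)) if m else None


def read_uci_drift_file(path: str | Path, batch_id: int | None = None) -> SampleSet:
    """Parse one ``label;concentration i:v ...`` benchmark file.

    Every sample in the file is treated as labeled/source; the protocol
    runner decides later which batches have their labels hidden.  Feature
    vectors are placed by 1-based index; the width is the largest index in
    the file (128 for the real benchmark).  The batch id is taken from the
    file name (``batch<k>``) unless given explicitly.
    """
    path = Path(path)
    if batch_id is None:
        batch_id = _batch_from_filename(path)
        if batch_id is None:
            raise FormatError(
                f"{path.name}: cannot infer batch number from file name; "
                "pass batch_id explicitly"
            )
    rows: list[dict[int, float]] = []
    labels: list[int] = []
    concs: list[float] = []
    max_idx = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            head, *feats = line.split()
            m = _HEAD_RE.match(head)
            if m is None:
                raise ParseError(
                    f"{path.name}:{lineno}: expected 'label;concentration', "
                    f"got {head!r}"
                )
            label = int(m.group(1))
            conc = float(m.group(2))
            if conc <= 0:
                raise ParseError(
                    f"{path.name}:{lineno}: concentration must be > 0"
                )
            values: dict[int, float] = {}
            prev = 0
            for tok in feats:
                try:
                    idx_s, val_s = tok.split(":", 1)
                    idx = int(idx_s)
                    val = float(val_s)
                except ValueError as exc:
                    raise ParseError(
                        f"{path.name}:{lineno}: bad feature token {tok!r}"
                    ) from exc
                if idx < 1:
                    raise FormatError(
                        f"{path.name}:{lineno}: feature index {idx} out of range"
                    )
                if idx in values:
                    raise FormatError(
                        f"{path.name}:{lineno}: duplicate feature index {idx}"
                    )
                if idx <= prev:
                    raise FormatError(
                        f"{path.name}:{lineno}: feature indices must be "
                        "strictly increasing"
                    )
                prev = idx
                values[idx] = val
            if not values:
                raise ParseError(f"{path.name}:{lineno}: no feature values")
            rows.append(values)
            labels.append(label)
            concs.append(conc)
            max_idx = max(max_idx, prev)
    if not rows:
        raise FormatError(f"{path.name}: no samples")
    X = np.zeros((len(rows), max_idx))
    for i, values in enumerate(rows):
        for idx, val in values.items():
            X[i, idx - 1] = val
    n = len(rows)
    return SampleSet(
        features=X,
        batch_ids=np.full(n, batch_id),
        labels=np.array(labels),
        concentrations=np.array(concs),
        is_source=np.ones(n, dtype=bool),
        eval_labels=np.array(labels),
        eval_concentrations=np.array(concs),
    )


def write_uci_drift_file(s: SampleSet, path: str | Path) -> None:
    """Write ``label;concentration i:v ...`` lines (one per sample).

    The dialect has no unlabeled form, so hidden evaluation labels and
    concentrations are written for target rows; the reader marks everything
    source and the protocol re-hides them.
    """
    path = Path(path)
    labels = np.where(
        s.is_source,
        s.labels,
        s.eval_labels if s.eval_labels is not None else s.labels,
    )
    concs = np.where(
        s.is_source,
        s.concentrations,
        s.eval_concentrations
        if s.eval_concentrations is not None
        else s.concentrations,
    )
    if np.any(labels < 0) or np.any(~np.isfinite(concs)):
        raise ValueError(
            "UCI dialect requires a (possibly hidden) label and "
            "concentration for every sample"
        )
    with open(path, "w") as fh:
        for i in range(s.n_samples):
            feats = " ".join(
                f"{j + 1}:{s.features[i, j]:.17g}"
                for j in range(s.n_features)
            )
            fh.write(f"{labels[i]};{concs[i]:.17g} {feats}\n")


# ---------------------------------------------------------------------------
# Generic delimited tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TableSchema:
    """Column-role map for :func:`read_feature_table`.

    ``feature_columns=None`` means "every column not claimed by a role",
    taken in header order.
    """

    label: str = "label"
    concentration: str = "concentration"
    batch: str = "batch"
    eval_label: str | None = "eval_label"
    eval_concentration: str | None = "eval_concentration"
    feature_columns: tuple[str, ...] | None = None


def read_feature_table(
    path: str | Path,
    schema: TableSchema | None = None,
    sep: str = ",",
) -> SampleSet:
    """Read a delimited table with header into a SampleSet.

    Roles are inferred from the label column: rows with a label are
    source, rows with an empty/NaN label are target.  Column order in the
    file is irrelevant; the schema names the roles.
    """
    schema = schema or TableSchema()
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path.name}: no samples") from exc
    if df.shape[0] == 0:
        raise FormatError(f"{path.name}: no samples")
    for col in (schema.batch,):
        if col not in df.columns:
            raise SchemaError(f"{path.name}: missing mandatory column {col!r}")
    if schema.label not in df.columns:
        raise SchemaError(f"{path.name}: missing mandatory column {schema.label!r}")
    claimed = {schema.label, schema.concentration, schema.batch}
    for opt in (schema.eval_label, schema.eval_concentration):
        if opt:
            claimed.add(opt)
    if schema.feature_columns is None:
        feat_cols = [c for c in df.columns if c not in claimed]
    else:
        feat_cols = list(schema.feature_columns)
        missing = [c for c in feat_cols if c not in df.columns]
        if missing:
            raise SchemaError(f"{path.name}: missing feature columns {missing}")
    if not feat_cols:
        raise SchemaError(f"{path.name}: no feature columns")
    feats = df[feat_cols].apply(pd.to_numeric, errors="coerce").to_numpy(float)
    if np.any(~np.isfinite(feats)):
        bad = np.argwhere(~np.isfinite(feats))[0]
        raise ParseError(
            f"{path.name}: non-numeric feature cell at row {bad[0] + 2}, "
            f"column {feat_cols[bad[1]]!r}"
        )
    labels_raw = pd.to_numeric(df[schema.label], errors="coerce")
    is_source = labels_raw.notna().to_numpy()
    labels = labels_raw.fillna(UNLABELED).astype(int).to_numpy()
    if schema.concentration in df.columns:
        concs = pd.to_numeric(df[schema.concentration], errors="coerce").to_numpy(float)
    else:
        if is_source.any():
            raise SchemaError(
                f"{path.name}: missing mandatory column {schema.concentration!r}"
            )
        concs = np.full(len(df), np.nan)
    eval_labels = None
    if schema.eval_label and schema.eval_label in df.columns:
        eval_labels = (
            pd.to_numeric(df[schema.eval_label], errors="coerce")
            .fillna(UNLABELED)
            .astype(int)
            .to_numpy()
        )
    eval_concs = None
    if schema.eval_concentration and schema.eval_concentration in df.columns:
        eval_concs = pd.to_numeric(
            df[schema.eval_concentration], errors="coerce"
        ).to_numpy(float)
    return SampleSet(
        features=feats,
        batch_ids=pd.to_numeric(df[schema.batch]).astype(int).to_numpy(),
        labels=labels,
        concentrations=concs,
        is_source=is_source,
        eval_labels=eval_labels,
        eval_concentrations=eval_concs,
    )


def write_feature_table(s: SampleSet, path: str | Path, sep: str = ",") -> None:
    """Write the canonical CSV/TSV layout (deterministic column order)."""
    cols: dict[str, object] = {
        "batch": s.batch_ids,
        "label": [
            int(v) if src else ""
            for v, src in zip(s.labels, s.is_source)
        ],
        "concentration": [
            repr(float(v)) if src else ""
            for v, src in zip(s.concentrations, s.is_source)
        ],
    }
    if s.eval_labels is not None:
        cols["eval_label"] = [
            int(v) if v != UNLABELED else "" for v in s.eval_labels
        ]
    if s.eval_concentrations is not None:
        cols["eval_concentration"] = [
            repr(float(v)) if np.isfinite(v) else ""
            for v in s.eval_concentrations
        ]
    width = len(str(s.n_features))
    for j in range(s.n_features):
        cols[f"f{j + 1:0{width}d}"] = [repr(float(v)) for v in s.features[:, j]]
    pd.DataFrame(cols).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Per-batch standardization
# ---------------------------------------------------------------------------

def standardize_per_batch(s: SampleSet) -> SampleSet:
    """Z-score every feature within every batch (population variance).

    Each batch's features end up with mean 0 and, where the variance is
    nonzero, standard deviation 1; constant-within-batch features map to 0
    via an epsilon guard on the standard deviation.  Idempotent up to the
    guard.  This is the transductive normalization of the batch protocol:
    each batch — including target batches — is scaled with its own
    statistics.
    """
    X = s.features.copy()
    for b in np.unique(s.batch_ids):
        rows = s.batch_ids == b
        mu = X[rows].mean(axis=0)
        sd = X[rows].std(axis=0)  # population (1/n) convention
        X[rows] = (X[rows] - mu) / (sd + _EPS_SD)
    return replace(s, features=X)
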