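"""Maximum Independence of the Concentration Features (MICF).

Concentration is a nuisance variable for gas classification: the same
analyte at different concentrations produces different sensor
fingerprints, inflating within-class spread and confusing classifiers
trained at one concentration range.  MICF learns an orthonormal kernel
projection W whose features Z = W^T K_x

  * retain as much projected variance as possible,   tr(W^T K_x H K_x W)
  * while being maximally independent of a concentration-level kernel
    K_y in the HSIC sense,                         - tr(W^T K_x H K_y H K_x W)

combined as  max_{W^T W = I}  tr(W^T K_x (-H K_y H + mu H) K_x W),
whose solution is the top-h eigenvectors of the symmetric matrix
K_x (-H K_y H + mu H) K_x.

Concentration levels are the integer part of ln(concentration in ppm),
remapped to contiguous indices; labeled samples get a one-hot column in
the c x n level-coding matrix Y, unlabeled (target) samples an all-zero
column, and K_y = Y^T Y is the linear kernel on those codes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .kernels import KernelSpec, centering_matrix

_INT_SNAP = 1e-9
_ORTHO_TOL = 1e-6


@dataclass(frozen=True)
class LevelCoding:
    """Contiguous concentration levels plus the raw floor(ln c) -> 1..c map."""

    levels: np.ndarray            # contiguous indices 1..c, one per input
    level_map: dict[int, int]     # raw floor(ln c) value -> contiguous index

    @property
    def n_levels(self) -> int:
        return len(self.level_map)


@dataclass
class ConcentrationFeatureMatrix:
    """Level-coding matrix Y (c levels x n samples) and its provenance.

    Each labeled sample's column is one-hot at its concentration level
    (or carries the level index itself under the ``level_coded`` variant);
    unlabeled columns are all zero, so target samples contribute nothing
    to the concentration kernel.
    """

    Y: np.ndarray
    level_map: dict[int, int] = field(default_factory=dict)

    @property
    def n_levels(self) -> int:
        return self.Y.shape[0]

    @property
    def n_samples(self) -> int:
        return self.Y.shape[1]


@dataclass
class MICFModel:
    """Fitted MICF transform.

    W            n x h orthonormal eigenvector matrix
    mu           variance/independence trade-off (> 0 in the objective;
                 0 is allowed for the pure independence-minimising limit)
    h            subspace dimension
    kernel_spec  kernel used for K_x
    eigenvalues  the h leading eigenvalues, descending
    level_map    concentration-level remap used to build Y
    """

    W: np.ndarray
    mu: float
    h: int
    kernel_spec: KernelSpec = field(default_factory=KernelSpec)
    eigenvalues: np.ndarray = field(default_factory=lambda: np.empty(0))
    level_map: dict[int, int] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "W": self.W.tolist(),
            "mu": self.mu,
            "h": self.h,
            "kernel_spec": self.kernel_spec.to_dict(),
            "eigenvalues": np.asarray(self.eigenvalues).tolist(),
            "level_map": {str(k): v for k, v in self.level_map.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "MICFModel":
        d = json.loads(Path(path).read_text())
        return cls(
            W=np.array(d["W"], dtype=float),
            mu=float(d["mu"]),
            h=int(d["h"]),
            kernel_spec=KernelSpec.from_dict(d["kernel_spec"]),
            eigenvalues=np.array(d["eigenvalues"], dtype=float),
            level_map={int(k): int(v) for k, v in d["level_map"].items()},
        )


def concentration_levels(concentrations: Sequence[float]) -> LevelCoding:
    """Map ppm concentrations to contiguous integer levels 1..c.

    The raw level is floor(ln c); raw levels are then remapped
    order-preservingly onto 1..c so the coding matrix has no empty rows.
    Log values within 1e-9 of an integer are snapped to it first, so a
    concentration of exactly e^k lands on level k despite floating-point
    round-off in the logarithm.
    """
    conc = np.asarray(concentrations, dtype=float)
    if conc.size == 0:
        raise ValueError("no concentrations given")
    if np.any(~np.isfinite(conc)) or np.any(conc <= 0):
        raise ValueError("concentrations must be finite and > 0")
    d = np.log(conc)
    nearest = np.round(d)
    d = np.where(np.abs(d - nearest) < _INT_SNAP, nearest, d)
    raw = np.floor(d).astype(int)
    uniq = np.unique(raw)
    level_map = {int(r): i + 1 for i, r in enumerate(uniq)}
    levels = np.array([level_map[int(r)] for r in raw])
    return LevelCoding(levels=levels, level_map=level_map)


def build_concentration_features(
    levels: Sequence[int],
    labeled_mask: Sequence[bool],
    n: int,
    n_levels: int | None = None,
    level_map: dict[int, int] | None = None,
    level_coded: bool = False,
) -> ConcentrationFeatureMatrix:
    """Build the c x n matrix Y from per-labeled-sample levels.

    ``levels`` gives one contiguous level index per *labeled* sample, in
    sample order; ``labeled_mask`` says which of the n columns are
    labeled.  Labeled columns are one-hot (value 1, or the level index
    under ``level_coded``); unlabeled columns are all zero.
    """
    mask = np.asarray(labeled_mask, dtype=bool)
    if mask.shape != (n,):
        raise ValueError("labeled_mask must have length n")
    lv = np.asarray(levels, dtype=int)
    if lv.shape != (int(mask.sum()),):
        raise ValueError("levels must be given exactly for labeled samples")
    c = int(n_levels) if n_levels is not None else (int(lv.max()) if lv.size else 1)
    if lv.size and (lv.min() < 1 or lv.max() > c):
        raise ValueError(f"level index outside 1..{c}")
    Y = np.zeros((c, n))
    cols = np.flatnonzero(mask)
    for col, level in zip(cols, lv):
        Y[level - 1, col] = float(level) if level_coded else 1.0
    return ConcentrationFeatureMatrix(Y=Y, level_map=dict(level_map or {}))


def concentration_kernel(Y: ConcentrationFeatureMatrix | np.ndarray) -> np.ndarray:
    """Linear kernel on the level codes: K_y = Y^T Y.

    With one-hot coding this is binary — K_y[i, j] = 1 iff samples i and j
    are both labeled at the same concentration level — and rows/columns of
    unlabeled samples are zero.
    """
    M = Y.Y if isinstance(Y, ConcentrationFeatureMatrix) else np.asarray(Y, float)
    return M.T @ M


def _normalize_signs(W: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-|entry| component is positive."""
    W = W.copy()
    for j in range(W.shape[1]):
        i = int(np.argmax(np.abs(W[:, j])))
        if W[i, j] < 0:
            W[:, j] = -W[:, j]
    return W


def _sort_ties_lexicographically(w: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Within groups of exactly equal eigenvalues, order columns
    lexicographically for bit-stable output."""
    out = W.copy()
    j = 0
    while j < len(w):
        k = j + 1
        while k < len(w) and w[k] == w[j]:
            k += 1
        if k - j > 1:
            block = out[:, j:k]
            order = np.lexsort(block[::-1])
            out[:, j:k] = block[:, order]
        j = k
    return out


def fit_micf(
    Kx: np.ndarray,
    Ky: np.ndarray,
    mu: float = 1.0,
    h: int = 1,
    kernel_spec: KernelSpec | None = None,
    level_map: dict[int, int] | None = None,
) -> MICFModel:
    """Solve the MICF trace problem for the top-h eigenvectors.

    Forms the symmetric matrix M = K_x (-H K_y H + mu H) K_x and returns
    its h leading eigenpairs (descending).  Eigenvector signs are
    normalised (largest-|entry| component positive) and exact eigenvalue
    ties are broken lexicographically, so the fit is deterministic.
    """
    Kx = np.asarray(Kx, dtype=float)
    Ky = np.asarray(Ky, dtype=float)
    n = Kx.shape[0]
    if Kx.shape != (n, n) or Ky.shape != (n, n):
        raise ValueError("Kx and Ky must be square and of equal size")
    for name, K in (("Kx", Kx), ("Ky", Ky)):
        if not np.allclose(K, K.T, atol=1e-8):
            raise ValueError(f"{name} must be symmetric")
    if not 1 <= h <= n:
        raise ValueError(f"subspace dimension h={h} outside 1..{n}")
    if mu < 0:
        raise ValueError("mu must be nonnegative")
    H = centering_matrix(n)
    M = Kx @ (-(H @ Ky @ H) + mu * H) @ Kx
    M = (M + M.T) / 2.0
    w, U = np.linalg.eigh(M)
    w, U = w[::-1], U[:, ::-1]
    W = _normalize_signs(U[:, :h])
    W = _sort_ties_lexicographically(w[:h], W)
    return MICFModel(
        W=W,
        mu=float(mu),
        h=int(h),
        kernel_spec=kernel_spec or KernelSpec(),
        eigenvalues=w[:h].copy(),
        level_map=dict(level_map or {}),
    )


def micf_objective(
    W: np.ndarray, Kx: np.ndarray, Ky: np.ndarray, mu: float
) -> float:
    """Evaluate tr(-W^T K_x H K_y H K_x W + mu W^T K_x H K_x W)."""
    W = np.asarray(W, dtype=float)
    h = W.shape[1]
    if not np.allclose(W.T @ W, np.eye(h), atol=_ORTHO_TOL):
        raise ValueError("W must have orthonormal columns")
    n = Kx.shape[0]
    H = centering_matrix(n)
    KxW = Kx @ W
    HKxW = H @ KxW
    penalty = float(np.trace(KxW.T @ H @ Ky @ HKxW))
    variance = float(np.trace(KxW.T @ HKxW))
    return -penalty + mu * variance


def project(model: MICFModel, Kx: np.ndarray) -> np.ndarray:
    """Projected features Z = W^T K_x (h rows, one column per sample)."""
    Kx = np.asarray(Kx, dtype=float)
    if Kx.shape[0] != model.W.shape[0]:
        raise ValueError(
            f"kernel matrix has {Kx.shape[0]} rows, model expects "
            f"{model.W.shape[0]}"
        )
    return model.W.T @ Kx
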