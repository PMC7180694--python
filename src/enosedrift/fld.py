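"""Fisher linear discriminant: scatter matrices and the generalized
eigenproblem S_b V = lambda S_w V.

The within-class scatter S_w is the pooled (unweighted) sum of squared
deviations around each class mean; the between-class scatter S_b weights
the outer products of (class mean - grand mean) by per-class weights
lambda_i, defaulting to the class proportions n_i / N.  The transform V
stacks the k leading generalized eigenvectors; its directions maximise
between-class over within-class scatter.  S_w is ridge-regularised with
epsilon = 1e-6 tr(S_w)/d (floored at 1e-12) so the symmetric-definite
solver remains applicable when S_w is singular.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.linalg

_REG_SCALE = 1e-6
_REG_FLOOR = 1e-12


@dataclass
class FLDModel:
    """Fitted discriminant transform.

    V                d x k matrix of generalized eigenvectors (columns)
    gen_eigenvalues  k leading generalized eigenvalues, descending
    class_weights    the lambda_i used for S_b (class -> weight), if known
    regularization   the epsilon actually added to S_w's diagonal
    """

    V: np.ndarray
    gen_eigenvalues: np.ndarray
    class_weights: dict = field(default_factory=dict)
    regularization: float = 0.0


def scatter_matrices(
    Z: np.ndarray,
    labels: Sequence[int],
    weights: Mapping[int, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Within-class and between-class scatter of samples-as-rows Z.

    S_w = sum_i sum_{z in class i} (z - mu_i)(z - mu_i)^T
    S_b = sum_i lambda_i (mu_i - mu)(mu_i - mu)^T,  lambda_i = n_i/N default.

    ``weights`` may override lambda_i per class (must cover every class).
    """
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(labels)
    if Z.ndim != 2 or Z.shape[0] != y.shape[0]:
        raise ValueError("Z must be (n, d) with one label per row")
    n, d = Z.shape
    if n < 2:
        raise ValueError("need at least 2 samples")
    classes = np.unique(y)
    if weights is not None:
        missing = [c for c in classes if c not in weights]
        if missing:
            raise ValueError(f"no weight for classes {missing}")
    mu = Z.mean(axis=0)
    Sw = np.zeros((d, d))
    Sb = np.zeros((d, d))
    for c in classes:
        Zc = Z[y == c]
        mu_c = Zc.mean(axis=0)
        D = Zc - mu_c
        Sw += D.T @ D
        lam = weights[c] if weights is not None else Zc.shape[0] / n
        diff = (mu_c - mu)[:, None]
        Sb += lam * (diff @ diff.T)
    return (Sw + Sw.T) / 2.0, (Sb + Sb.T) / 2.0


def default_regularization(Sw: np.ndarray) -> float:
    """epsilon = 1e-6 tr(S_w)/d, floored to keep S_w + eps I definite."""
    d = Sw.shape[0]
    return max(_REG_SCALE * float(np.trace(Sw)) / d, _REG_FLOOR)


def solve_fld(
    Sw: np.ndarray,
    Sb: np.ndarray,
    k: int,
    reg: float | None = None,
    class_weights: Mapping[int, float] | None = None,
) -> FLDModel:
    """Top-k generalized eigenvectors of S_b V = lambda (S_w + eps I) V.

    Solved via scipy's symmetric-definite generalized eigensolver
    (Cholesky reduction), so eigenpairs are real; eigenvalues are returned
    descending and eigenvector signs are normalised (largest-|entry|
    component positive) for reproducibility.
    """
    Sw = np.asarray(Sw, dtype=float)
    Sb = np.asarray(Sb, dtype=float)
    d = Sw.shape[0]
    if Sw.shape != (d, d) or Sb.shape != (d, d):
        raise ValueError("Sw and Sb must be square and of equal size")
    if not 1 <= k <= d:
        raise ValueError(f"k={k} outside 1..{d}")
    eps = default_regularization(Sw) if reg is None else float(reg)
    if eps < 0:
        raise ValueError("regularization must be nonnegative")
    eps = max(eps, _REG_FLOOR)
    w, V = scipy.linalg.eigh(Sb, Sw + eps * np.eye(d))
    w, V = w[::-1], V[:, ::-1]
    Vk = V[:, :k].copy()
    for j in range(k):
        i = int(np.argmax(np.abs(Vk[:, j])))
        if Vk[i, j] < 0:
            Vk[:, j] = -Vk[:, j]
    return FLDModel(
        V=Vk,
        gen_eigenvalues=w[:k].copy(),
        class_weights=dict(class_weights or {}),
        regularization=eps,
    )
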