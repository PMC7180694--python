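"""Gram-matrix construction, double centering, and the empirical HSIC estimator.

The Hilbert-Schmidt Independence Criterion (HSIC) measures statistical
dependence between two random variables through the cross-covariance
operator between their reproducing-kernel Hilbert spaces.  Its biased
empirical estimate from n paired samples is

    HSIC = (n - 1)^-2 * tr(K H L H),

where K and L are the two n x n kernel (Gram) matrices and
H = I - n^-1 1 1^T is the centering matrix.  For suitable
(characteristic) kernels the population quantity vanishes iff the two
variables are independent, which is what the MICF subspace objective
exploits: it penalises the dependence between projected sensor features
and the concentration-level kernel.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from sklearn.metrics.pairwise import euclidean_distances


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family and parameters used to build a Gram matrix.

    kind        one of ``linear``, ``polynomial``, ``rbf``
    degree      polynomial degree (>= 1, polynomial only)
    offset      additive constant inside the polynomial (>= 0)
    bandwidth   RBF length-scale sigma, or ``"median"`` for the median
                pairwise-distance heuristic
    """

    kind: str = "linear"
    degree: int = 2
    offset: float = 1.0
    bandwidth: float | str = "median"

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "polynomial", "rbf"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if self.kind == "polynomial":
            if int(self.degree) < 1:
                raise ValueError("polynomial degree must be >= 1")
            if self.offset < 0:
                raise ValueError("polynomial offset must be >= 0")
        if self.kind == "rbf":
            if isinstance(self.bandwidth, str):
                if self.bandwidth != "median":
                    raise ValueError("bandwidth must be positive or 'median'")
            elif self.bandwidth <= 0:
                raise ValueError("bandwidth must be positive or 'median'")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "KernelSpec":
        return cls(**d)


def centering_matrix(n: int) -> np.ndarray:
    """Return H = I - n^-1 1 1^T, the n x n centering matrix.

    H is symmetric, idempotent (H @ H = H) and annihilates the constant
    vector (H @ 1 = 0).  Left/right multiplication by H centers a Gram
    matrix in feature space.
    """
    if n < 2:
        raise ValueError("centering matrix requires n >= 2")
    return np.eye(n) - np.full((n, n), 1.0 / n)


def _median_bandwidth(X: np.ndarray) -> float:
    """Median of pairwise Euclidean distances (median heuristic)."""
    D = euclidean_distances(X)
    iu = np.triu_indices_from(D, k=1)
    if iu[0].size == 0:
        return 1.0
    med = float(np.median(D[iu]))
    return med if med > 0 else 1.0


def gram(features: np.ndarray, spec: KernelSpec | None = None) -> np.ndarray:
    """Kernel matrix K[i, j] = k(x_i, x_j) for samples-as-rows ``features``.

    The result is symmetric positive semidefinite; the linear kind returns
    exact inner products.
    """
    spec = spec or KernelSpec()
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be a 2-d samples-by-features array")
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain non-finite values")
    if spec.kind == "linear":
        K = X @ X.T
    elif spec.kind == "polynomial":
        K = (X @ X.T + spec.offset) ** int(spec.degree)
    else:  # rbf
        sigma = (
            _median_bandwidth(X)
            if isinstance(spec.bandwidth, str)
            else float(spec.bandwidth)
        )
        D2 = euclidean_distances(X, squared=True)
        K = np.exp(-D2 / (2.0 * sigma**2))
    return (K + K.T) / 2.0


def hsic_estimate(K: np.ndarray, L: np.ndarray) -> float:
    """Biased empirical HSIC, (n-1)^-2 tr(K H L H).

    Both arguments must be symmetric n x n kernel matrices over the same
    samples.  Nonnegative (up to round-off) for PSD inputs; zero when
    either argument is the zero matrix.
    """
    K = np.asarray(K, dtype=float)
    L = np.asarray(L, dtype=float)
    if K.shape != L.shape or K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError("K and L must be square matrices of equal size")
    n = K.shape[0]
    if n < 2:
        raise ValueError("HSIC requires n >= 2 samples")
    H = centering_matrix(n)
    KH = H @ K @ H
    # tr(K H L H) = tr((H K H) L) = sum_ij (HKH)_ij L_ji; L symmetric.
    return float(np.sum(KH * L.T)) / (n - 1) ** 2
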