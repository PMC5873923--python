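"""Line-relationship kernels from markers: linear (GBLUP) and Gaussian.

Two n x n kernels summarize how alike the genotypes of the lines are:

* **GB** (linear / GBLUP): ``K = X X' / p`` with ``X`` the standardized
  dosage matrix and ``p`` the number of retained markers — the VanRaden-style
  genomic relationship matrix. Random line effects with covariance
  ``sigma_g^2 K`` give genomic BLUP.
* **GK** (Gaussian): ``K[i,i'] = exp(-h * d_ii'^2 / median(d^2))`` where
  ``d_ii'^2`` is the squared Euclidean distance between marker rows and the
  median is taken over strictly off-diagonal pairs, so the entry at the median
  distance always equals ``exp(-h)``. With bandwidth ``h = 1`` this kernel
  decays smoothly with genetic distance and can pick up non-additive
  (epistatic) signal that the linear kernel averages away.

Both kernels are symmetric and positive semidefinite up to numerical
round-off; validation enforces eigenvalues >= -1e-8 * lambda_max rather than
silently clipping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markers import MarkerMatrix, standardize

__all__ = [
    "KernelMatrix",
    "linear_kernel",
    "squared_distance_matrix",
    "gaussian_kernel",
    "read_kernel",
    "write_kernel",
]

PSD_RTOL = 1e-8  # eigenvalues below -PSD_RTOL * lambda_max fail validation
SYM_ATOL = 1e-10


@dataclass
class KernelMatrix:
    """Symmetric PSD line-relationship matrix with provenance metadata.

    Parameters
    ----------
    line_ids : list of str
        Line identifiers indexing rows/columns of ``K``.
    K : ndarray, shape (n, n)
    method : {"GB", "GK"}
    h : float or None
        Gaussian bandwidth (GK only, dimensionless).
    scale : float or None
        Median squared distance used as the GK scaling factor.
    """

    line_ids: list
    K: np.ndarray
    method: str = "GB"
    h: float = None
    scale: float = None
    _eig: tuple = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.K = np.asarray(self.K, dtype=float)
        self.line_ids = [str(s) for s in self.line_ids]
        n = len(self.line_ids)
        if len(set(self.line_ids)) != n:
            raise ValueError("duplicate line_ids in kernel")
        if self.K.shape != (n, n):
            raise ValueError(f"K shape {self.K.shape} does not match {n} line_ids")
        if self.method not in ("GB", "GK"):
            raise ValueError(f"unknown kernel method {self.method!r}")
        self.validate()

    def validate(self) -> None:
        if not np.all(np.isfinite(self.K)):
            raise ValueError("kernel contains non-finite entries")
        if np.max(np.abs(self.K - self.K.T), initial=0.0) > SYM_ATOL:
            raise ValueError("kernel is not symmetric within 1e-10")
        w = np.linalg.eigvalsh(self.K)
        lam_max = max(w[-1], 0.0)
        if w[0] < -PSD_RTOL * max(lam_max, 1e-300):
            raise ValueError(
                f"kernel is not numerically PSD: min eigenvalue {w[0]:.3e} "
                f"vs max {lam_max:.3e}"
            )
        if self.method == "GK":
            if np.max(np.abs(np.diag(self.K) - 1.0), initial=0.0) > 0:
                raise ValueError("GK kernel diagonal must be exactly 1")
            if np.min(self.K) <= 0 or np.max(self.K) > 1:
                raise ValueError("GK kernel entries must lie in (0, 1]")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    def eigen(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigendecomposition ``K = V diag(lam) V'`` with tiny negatives clipped to 0.

        Cached on the instance; used by the samplers and the simulator.
        """
        if self._eig is None:
            lam, V = np.linalg.eigh(self.K)
            lam_max = max(lam[-1], 0.0)
            if lam[0] < -PSD_RTOL * max(lam_max, 1e-300):
                raise ValueError("kernel is not numerically PSD")
            lam = np.clip(lam, 0.0, None)
            self._eig = (lam, V)
        return self._eig

    def subset(self, line_ids) -> "KernelMatrix":
        """Restrict/reorder the kernel to ``line_ids`` (must all be present)."""
        pos = {s: i for i, s in enumerate(self.line_ids)}
        missing = [s for s in line_ids if str(s) not in pos]
        if missing:
            raise KeyError(f"lines absent from kernel: {missing}")
        idx = np.array([pos[str(s)] for s in line_ids], dtype=int)
        return KernelMatrix(
            list(line_ids), self.K[np.ix_(idx, idx)], self.method, self.h, self.scale
        )


def linear_kernel(M: MarkerMatrix) -> KernelMatrix:
    """GBLUP kernel ``K = X X' / p`` from a (standardized) marker matrix.

    The matrix is standardized first when not already flagged as such; ``p``
    counts the markers retained after dropping zero-variance columns.
    """
    Ms = M if M.standardized else standardize(M)
    p = Ms.n_markers
    if p == 0:
        raise ValueError("no markers left to build the linear kernel")
    K = Ms.X @ Ms.X.T / p
    K = (K + K.T) / 2.0
    return KernelMatrix(Ms.line_ids, K, method="GB")


def squared_distance_matrix(M: MarkerMatrix) -> np.ndarray:
    """Pairwise squared Euclidean distances between marker rows.

    ``d2[i, i'] = sum_k (x_ik - x_i'k)^2``; zero diagonal, symmetric,
    elementwise nonnegative.
    """
    X = np.asarray(M.X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("squared distances require a finite marker matrix")
    sq = np.sum(X * X, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.fill_diagonal(d2, 0.0)
    d2 = np.maximum((d2 + d2.T) / 2.0, 0.0)
    return d2


def gaussian_kernel(M: MarkerMatrix, h: float = 1.0) -> KernelMatrix:
    """Gaussian kernel ``exp(-h d^2 / median(d^2))`` with unit diagonal.

    The median is computed over strictly off-diagonal (upper-triangle) squared
    distances; including the diagonal zeros would deflate the scale.

    Raises
    ------
    ValueError
        If the median distance is zero (all lines genetically identical).
    """
    if M.n_lines < 2:
        raise ValueError("Gaussian kernel needs at least two lines")
    if h <= 0:
        raise ValueError("bandwidth h must be positive")
    d2 = squared_distance_matrix(M)
    iu = np.triu_indices(M.n_lines, k=1)
    med = float(np.median(d2[iu]))
    if med <= 0.0:
        dup = [
            (M.line_ids[i], M.line_ids[j])
            for i, j in zip(*iu)
            if d2[i, j] == 0.0
        ][:5]
        raise ValueError(
            "median squared marker distance is zero; genotypes are degenerate "
            f"(identical pairs include {dup})"
        )
    K = np.exp(-h * d2 / med)
    np.fill_diagonal(K, 1.0)
    K = (K + K.T) / 2.0
    return KernelMatrix(M.line_ids, K, method="GK", h=h, scale=med)


def write_kernel(K: KernelMatrix, path) -> None:
    """Export a kernel as CSV with line-ID header row/column (17 sig. digits)."""
    df = pd.DataFrame(K.K, index=K.line_ids, columns=K.line_ids)
    df.index.name = "line"
    df.to_csv(path, float_format="%.17g")


def read_kernel(path, method: str = "GB", h: float = None, scale: float = None) -> KernelMatrix:
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    K = df.to_numpy(dtype=float)
    K = (K + K.T) / 2.0  # remove asymmetric round-off from text round-trip
    return KernelMatrix([str(i) for i in df.index], K, method=method, h=h, scale=scale)
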