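"""Marker dosage matrices: QC filtering, imputation, standardization, text I/O.

A marker matrix holds allele dosages for ``n`` lines at ``p`` loci. Raw coding
is either 0/1/2 (copies of the minor or reference allele) or -1/0/1; fractional
dosages (e.g. imputed) are accepted within the same range. Quality control
removes markers by missing-rate and minor-allele frequency, then mean-imputes
whatever missingness remains. Standardization centers each column and scales it
to unit sample variance (n-1 denominator), dropping monomorphic columns so no
division by zero can occur; the standardized matrix is what both relationship
kernels consume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MarkerMatrix",
    "FilterReport",
    "filter_markers",
    "standardize",
    "read_markers",
    "write_markers",
]


@dataclass
class MarkerMatrix:
    """Lines x markers dosage matrix with line identifiers.

    Parameters
    ----------
    line_ids : list of str
        Unique line identifiers, one per row of ``X``.
    X : ndarray, shape (n, p)
        Dosage matrix. May contain NaN before imputation; must be finite once
        ``standardized`` is set.
    marker_ids : list of str, optional
        Column names; generated as ``M0001..`` when omitted.
    standardized : bool
        True when every column has mean 0 and unit sample variance.
    """

    line_ids: list
    X: np.ndarray
    marker_ids: list = None
    standardized: bool = False

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D lines x markers matrix")
        self.line_ids = [str(s) for s in self.line_ids]
        if len(self.line_ids) != self.X.shape[0]:
            raise ValueError("line_ids length does not match number of rows of X")
        if len(set(self.line_ids)) != len(self.line_ids):
            raise ValueError("duplicate line_ids in marker matrix")
        if self.marker_ids is None:
            self.marker_ids = [f"M{k + 1:05d}" for k in range(self.X.shape[1])]
        else:
            self.marker_ids = [str(s) for s in self.marker_ids]
        if len(self.marker_ids) != self.X.shape[1]:
            raise ValueError("marker_ids length does not match number of columns of X")
        if self.standardized:
            if not np.all(np.isfinite(self.X)):
                raise ValueError("standardized marker matrix contains non-finite entries")
            col_means = self.X.mean(axis=0)
            if self.X.shape[0] > 1 and np.max(np.abs(col_means), initial=0.0) > 1e-8:
                raise ValueError("standardized flag set but columns are not centered")

    @property
    def n_lines(self) -> int:
        return self.X.shape[0]

    @property
    def n_markers(self) -> int:
        return self.X.shape[1]


@dataclass
class FilterReport:
    """Counts of markers removed by each QC rule."""

    n_input: int
    n_removed_missing: int
    n_removed_maf: int
    n_imputed_cells: int

    @property
    def n_kept(self) -> int:
        return self.n_input - self.n_removed_missing - self.n_removed_maf


_CODINGS = {"012": (0.0, 2.0), "-101": (-1.0, 1.0)}


def _infer_coding(X: np.ndarray) -> str:
    finite = X[np.isfinite(X)]
    if finite.size == 0:
        raise ValueError("marker matrix has no observed dosages")
    lo, hi = finite.min(), finite.max()
    if lo >= -1e-9 and hi <= 2 + 1e-9:
        return "012"
    if lo >= -1 - 1e-9 and hi <= 1 + 1e-9:
        return "-101"
    raise ValueError(
        f"unknown dosage coding: observed range [{lo:g}, {hi:g}] fits neither 0..2 nor -1..1"
    )


def filter_markers(
    X_raw,
    maf_min: float = 0.05,
    max_missing: float = 0.2,
    coding: str = "auto",
    line_ids=None,
    marker_ids=None,
) -> tuple[MarkerMatrix, FilterReport]:
    """Apply marker QC: missing-rate filter, MAF filter, mean imputation.

    Markers whose missing-rate exceeds ``max_missing`` are removed first; among
    the survivors, markers with minor-allele frequency below ``maf_min``
    (computed on observed dosages) are removed. Remaining missing cells are
    imputed to the column mean.

    Parameters
    ----------
    X_raw : MarkerMatrix or array-like
        Raw dosages; NaN marks missing cells.
    maf_min : float
        Minimum minor-allele frequency to keep a marker (0 disables).
    max_missing : float
        Maximum tolerated missing fraction per marker (1 disables).
    coding : {"auto", "012", "-101"}
        Declared dosage coding; "auto" infers from the value range.

    Returns
    -------
    (MarkerMatrix, FilterReport)
        Filtered, imputed (not yet standardized) matrix plus removal counts.
    """
    if isinstance(X_raw, MarkerMatrix):
        line_ids = X_raw.line_ids
        marker_ids = X_raw.marker_ids
        X = np.array(X_raw.X, dtype=float)
    else:
        X = np.array(X_raw, dtype=float)
        if line_ids is None:
            line_ids = [f"L{i + 1:05d}" for i in range(X.shape[0])]
        if marker_ids is None:
            marker_ids = [f"M{k + 1:05d}" for k in range(X.shape[1])]
    marker_ids = list(marker_ids)

    if coding == "auto":
        coding = _infer_coding(X)
    if coding not in _CODINGS:
        raise ValueError(f"unknown coding {coding!r}; expected '012' or '-101'")
    lo, hi = _CODINGS[coding]
    finite = X[np.isfinite(X)]
    if finite.size and (finite.min() < lo - 1e-9 or finite.max() > hi + 1e-9):
        raise ValueError(f"dosages outside declared coding {coding!r} range [{lo:g}, {hi:g}]")

    n, p = X.shape
    missing = ~np.isfinite(X)
    miss_rate = missing.mean(axis=0)
    keep_miss = miss_rate <= max_missing
    n_removed_missing = int(p - keep_miss.sum())

    # allele frequency: mean dosage mapped onto [0, 1] over observed cells
    with np.errstate(invalid="ignore"):
        col_mean = np.nanmean(np.where(missing, np.nan, X), axis=0)
    freq = (col_mean - lo) / (hi - lo)
    maf = np.minimum(freq, 1.0 - freq)
    keep_maf = maf >= maf_min
    keep = keep_miss & keep_maf
    n_removed_maf = int(np.sum(keep_miss & ~keep_maf))

    if not np.any(keep):
        raise ValueError("all markers removed by QC filters")

    Xf = X[:, keep]
    kept_ids = [m for m, k in zip(marker_ids, keep) if k]
    miss_f = ~np.isfinite(Xf)
    n_imputed = int(miss_f.sum())
    if n_imputed:
        means = np.nanmean(np.where(miss_f, np.nan, Xf), axis=0)
        Xf = np.where(miss_f, means[None, :], Xf)

    report = FilterReport(
        n_input=p,
        n_removed_missing=n_removed_missing,
        n_removed_maf=n_removed_maf,
        n_imputed_cells=n_imputed,
    )
    return MarkerMatrix(line_ids, Xf, kept_ids, standardized=False), report


def standardize(M: MarkerMatrix) -> MarkerMatrix:
    """Center and scale columns to unit sample variance (n-1 denominator).

    Columns with zero raw variance are dropped, never divided by zero. A
    matrix already flagged standardized is returned unchanged.
    """
    if M.standardized:
        return M
    X = np.asarray(M.X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("standardize requires a finite (imputed) marker matrix")
    if X.shape[0] < 2:
        raise ValueError("standardization needs at least two lines")
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not np.any(keep):
        raise ValueError("all markers are monomorphic; nothing to standardize")
    Z = (X[:, keep] - mu[keep]) / sd[keep]
    ids = [m for m, k in zip(M.marker_ids, keep) if k]
    return MarkerMatrix(M.line_ids, Z, ids, standardized=True)


def read_markers(path, missing=("", "NA", "NaN")) -> MarkerMatrix:
    """Read a delimited marker file: first column line-ID, header of marker names."""
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") > header.count(",") else ","
    df = pd.read_csv(path, sep=sep, na_values=list(missing),
                     index_col=0, float_precision="round_trip")
    return MarkerMatrix(
        line_ids=[str(i) for i in df.index],
        X=df.to_numpy(dtype=float),
        marker_ids=[str(c) for c in df.columns],
    )


def write_markers(M: MarkerMatrix, path) -> None:
    df = pd.DataFrame(M.X, index=M.line_ids, columns=M.marker_ids)
    df.index.name = "line"
    df.to_csv(path, float_format="%.17g")
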