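"""Trial layout and covariance structures for multi-environment models.

A multi-environment trial is a long-format table of (line, environment,
phenotype) records — typically stage-1 adjusted means (BLUEs). The record
ordering convention is environment-major, line-minor; every matrix built here
shares it, which makes the per-environment block structure of the covariances
visible.

For the Hadamard-family models each random term contributes a scalar variance
component times a fixed N x N covariance *pattern*:

=========  ==========================  =========================================
term       pattern                     meaning
=========  ==========================  =========================================
g          ``Zg K Zg'``                main genetic effect, shared across
                                       environments; off-diagonal environment
                                       blocks exchange information between
                                       environments
ge         ``(Zg K Zg') ∘ (ZE ZE')``   single-variance GxE deviations; the
                                       Hadamard product with the environment
                                       incidence zeroes all between-environment
                                       blocks
gE_j       block j of the above        environment-specific GxE deviation with
                                       its own variance per environment
l          ``Zg Zg'``                  iid per-line random intercept (genetic
                                       residual not captured by the kernel)
residual   ``I``                       homogeneous error
=========  ==========================  =========================================

Patterns are stored in factored form (low-rank factor or per-environment
blocks); the dense N x N realization exists for tests and desk-scale checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kernels import KernelMatrix

__all__ = [
    "TrialData",
    "DesignMatrices",
    "ComponentStructure",
    "build_incidence",
    "main_effect_structure",
    "gxe_single_structure",
    "gxe_env_specific_structures",
    "intercept_structure",
    "WideTrial",
    "to_wide",
    "read_trial",
]


class TrialData:
    """Long-format line x environment phenotype records.

    Records are canonicalized on construction: sorted environment-major,
    line-minor, with registries of unique line and environment identifiers.
    At most one record per (line, environment) cell; unbalance (lines missing
    from some environments) is allowed.

    Parameters
    ----------
    records : iterable of (line_id, env_id, y) or DataFrame with those columns
    env_order : list, optional
        Explicit environment ordering; defaults to sorted unique ids.
    line_order : list, optional
        Explicit line ordering; defaults to sorted unique ids.
    """

    def __init__(self, records, env_order=None, line_order=None):
        if isinstance(records, pd.DataFrame):
            df = records.rename(
                columns={records.columns[0]: "line", records.columns[1]: "env",
                         records.columns[2]: "y"}
                if list(records.columns[:3]) != ["line", "env", "y"]
                else {}
            )[["line", "env", "y"]].copy()
        else:
            df = pd.DataFrame(list(records), columns=["line", "env", "y"])
        df["line"] = df["line"].astype(str)
        df["env"] = df["env"].astype(str)
        df["y"] = df["y"].astype(float)
        if df.duplicated(subset=["line", "env"]).any():
            dups = df[df.duplicated(subset=["line", "env"], keep=False)]
            raise ValueError(
                f"duplicate (line, env) records, e.g. {dups.iloc[0][['line', 'env']].tolist()}"
            )
        envs = sorted(df["env"].unique()) if env_order is None else [str(e) for e in env_order]
        lines = sorted(df["line"].unique()) if line_order is None else [str(s) for s in line_order]
        if set(df["env"]) - set(envs):
            raise ValueError("env_order does not cover all environments in the data")
        if set(df["line"]) - set(lines):
            raise ValueError("line_order does not cover all lines in the data")
        env_rank = {e: i for i, e in enumerate(envs)}
        line_rank = {s: i for i, s in enumerate(lines)}
        df["_e"] = df["env"].map(env_rank)
        df["_l"] = df["line"].map(line_rank)
        df = df.sort_values(["_e", "_l"], kind="mergesort").reset_index(drop=True)
        self.df = df[["line", "env", "y"]]
        self.env_ids = list(envs)
        self.line_ids = list(lines)
        self.env_index = df["_e"].to_numpy(dtype=int)
        self.line_index = df["_l"].to_numpy(dtype=int)

    @property
    def n_records(self) -> int:
        return len(self.df)

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_envs(self) -> int:
        return len(self.env_ids)

    @property
    def y(self) -> np.ndarray:
        return self.df["y"].to_numpy(dtype=float)

    @classmethod
    def from_csv(cls, path, env_order=None, line_order=None) -> "TrialData":
        return cls(pd.read_csv(path), env_order=env_order, line_order=line_order)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False, float_format="%.17g")


def read_trial(path, env_order=None) -> TrialData:
    """Read a phenotype CSV with header ``line,env,value`` (or ``line,env,y``)."""
    return TrialData.from_csv(path, env_order=env_order)


@dataclass
class DesignMatrices:
    """Incidence matrices in canonical (environment-major) record order."""

    ZE: np.ndarray  # N x m environment incidence (fixed effects)
    Zg: np.ndarray  # N x n line incidence
    env_index: np.ndarray
    line_index: np.ndarray
    env_ids: list
    line_ids: list
    y: np.ndarray

    @property
    def n_records(self) -> int:
        return self.ZE.shape[0]

    @property
    def env_counts(self) -> np.ndarray:
        """Per-environment record counts (the diagonal of ZE'ZE)."""
        return np.bincount(self.env_index, minlength=len(self.env_ids))


def build_incidence(T: TrialData) -> DesignMatrices:
    """Realize the environment and line incidence matrices of a trial.

    Each row of ``ZE`` and of ``Zg`` carries exactly one 1; ``ZE'ZE`` is
    diagonal with per-environment record counts.
    """
    N, m, n = T.n_records, T.n_envs, T.n_lines
    ZE = np.zeros((N, m))
    ZE[np.arange(N), T.env_index] = 1.0
    Zg = np.zeros((N, n))
    Zg[np.arange(N), T.line_index] = 1.0
    return DesignMatrices(
        ZE=ZE, Zg=Zg,
        env_index=T.env_index.copy(), line_index=T.line_index.copy(),
        env_ids=list(T.env_ids), line_ids=list(T.line_ids), y=T.y,
    )


@dataclass
class ComponentStructure:
    """Unit-variance covariance pattern of one random term.

    The pattern is held in factored form:

    * ``rep == "lowrank"``: ``C = B B'`` with ``B`` of shape (N, r);
    * ``rep == "blockdiag"``: ``C`` is zero except for dense PSD blocks
      ``block_k`` on record index sets ``idx_k``.

    ``dense()`` realizes the full N x N matrix (tests / desk scale only).
    """

    name: str
    variance_symbol: str
    rep: str
    n_records: int
    B: np.ndarray = None
    blocks: list = None  # list of (index array, dense PSD block)

    def dense(self) -> np.ndarray:
        if self.rep == "lowrank":
            return self.B @ self.B.T
        C = np.zeros((self.n_records, self.n_records))
        for idx, block in self.blocks:
            C[np.ix_(idx, idx)] += block
        return C


def _check_coverage(D: DesignMatrices, K: KernelMatrix) -> KernelMatrix:
    missing = [s for s in D.line_ids if s not in set(K.line_ids)]
    if missing:
        raise KeyError(f"trial lines absent from kernel: {missing}")
    return K.subset(D.line_ids)


def main_effect_structure(D: DesignMatrices, K: KernelMatrix) -> ComponentStructure:
    """Main-effect pattern ``C = Zg K Zg'`` (environment blocks all filled).

    The (env j, env j') block holds the kernel entries for the lines observed
    in j crossed with the lines observed in j'; between-environment exchange
    of information is therefore governed entirely by the main-effect variance.
    """
    Ks = _check_coverage(D, K)
    lam, V = Ks.eigen()
    keep = lam > 1e-12 * max(lam[-1], 1e-300)
    B = D.Zg @ (V[:, keep] * np.sqrt(lam[keep])[None, :])
    return ComponentStructure(
        name="g", variance_symbol="sigma2_g", rep="lowrank",
        n_records=D.n_records, B=B,
    )


def gxe_single_structure(D: DesignMatrices, K: KernelMatrix) -> ComponentStructure:
    """Single-variance GxE pattern ``(Zg K Zg') ∘ (ZE ZE')``.

    The Hadamard product with the environment incidence zeroes every
    between-environment block, leaving the within-environment sub-kernels on
    the block diagonal.
    """
    Ks = _check_coverage(D, K)
    blocks = []
    for j in range(len(D.env_ids)):
        idx = np.where(D.env_index == j)[0]
        lines_j = D.line_index[idx]
        blocks.append((idx, Ks.K[np.ix_(lines_j, lines_j)]))
    return ComponentStructure(
        name="ge", variance_symbol="sigma2_ge", rep="blockdiag",
        n_records=D.n_records, blocks=blocks,
    )


def gxe_env_specific_structures(D: DesignMatrices, K: KernelMatrix) -> list:
    """One pattern per environment: the (j, j) block of ``Zg K Zg'``, zero elsewhere.

    Summed over environments these reproduce the single-variance GxE pattern
    exactly; each carries its own variance component.
    """
    Ks = _check_coverage(D, K)
    out = []
    for j, env in enumerate(D.env_ids):
        idx = np.where(D.env_index == j)[0]
        lines_j = D.line_index[idx]
        out.append(
            ComponentStructure(
                name=f"gE:{env}", variance_symbol=f"sigma2_gE[{env}]",
                rep="blockdiag", n_records=D.n_records,
                blocks=[(idx, Ks.K[np.ix_(lines_j, lines_j)])],
            )
        )
    return out


def intercept_structure(D: DesignMatrices) -> ComponentStructure:
    """Random per-line intercept pattern ``C = Zg Zg'``.

    Records of the same line covary with unit pattern across environments;
    distinct lines do not. Under an l-model the covariance of two records of
    one line becomes sigma2_g * K[i,i] + sigma2_l.
    """
    return ComponentStructure(
        name="l", variance_symbol="sigma2_l", rep="lowrank",
        n_records=D.n_records, B=D.Zg.copy(),
    )


@dataclass
class WideTrial:
    """Lines x environments phenotype matrix with NaN marking empty cells."""

    line_ids: list
    env_ids: list
    Y: np.ndarray  # n x m, NaN where unobserved

    @property
    def observed(self) -> np.ndarray:
        return np.isfinite(self.Y)

    @property
    def n_missing(self) -> int:
        return int((~self.observed).sum())

    def to_long(self) -> TrialData:
        recs = [
            (self.line_ids[i], self.env_ids[j], self.Y[i, j])
            for j in range(len(self.env_ids))
            for i in range(len(self.line_ids))
            if np.isfinite(self.Y[i, j])
        ]
        return TrialData(recs, env_order=self.env_ids, line_order=self.line_ids)


def to_wide(T: TrialData) -> WideTrial:
    """Lossless pivot of a long trial to a lines x environments matrix."""
    n, m = T.n_lines, T.n_envs
    Y = np.full((n, m), np.nan)
    Y[T.line_index, T.env_index] = T.y
    return WideTrial(line_ids=list(T.line_ids), env_ids=list(T.env_ids), Y=Y)
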