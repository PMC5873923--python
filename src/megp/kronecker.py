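"""Unstructured-covariance multi-environment models (MUC, MUCf).

Model, on the lines x environments matrix ``Y`` (stacked environment-major as
a vector):

    y = mu*1 + ZE betaE + u [+ f] + eps
    u ~ N(0, UE ⊗ K),   f ~ N(0, FE ⊗ I),   eps ~ N(0, Sigma ⊗ I)

``UE`` is an m x m unstructured genetic covariance between environments —
free to hold *negative* covariances, which the Hadamard family cannot
represent (there the between-environment genetic covariance is the
nonnegative main-effect variance). ``FE`` is an optional unstructured
intercept-level covariance, and ``Sigma`` a diagonal matrix of heterogeneous
per-environment error variances.

Sampling exploits the eigendecomposition ``K = V L V'``: rotating line-space
by ``V`` decouples the rows, so each retained eigen-row of the rotated
``u`` has an m-variate normal full conditional (m x m algebra only). The
``u``-update eigendecomposes the current ``UE`` rather than inverting it, so
fixed singular choices (e.g. the rank-one ``c * J`` bridge to the
main-effect model) run through the same code path. ``UE``/``FE`` get
inverse-Wishart full conditionals, each ``Sigma_jj`` a scaled-inverse-
chi-square one. Empty and masked cells are data-augmented so the Kronecker
algebra stays balanced; masked phenotypes are never read.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import WideTrial
from .gibbs import McmcConfig, _scaled_inv_chi2
from .kernels import KernelMatrix

__all__ = [
    "EnvCovariance",
    "MucPriors",
    "MucResult",
    "fit_muc",
    "env_correlations",
]


@dataclass
class EnvCovariance:
    """Posterior-mean between-environment covariances of a MUC fit."""

    env_ids: list
    UE: np.ndarray                # m x m genetic covariance between environments
    Sigma: np.ndarray             # length-m diagonal residual variances
    FE: np.ndarray = None         # m x m intercept covariance (MUCf only)

    def __post_init__(self):
        m = len(self.env_ids)
        self.UE = np.asarray(self.UE, dtype=float)
        self.Sigma = np.asarray(self.Sigma, dtype=float).reshape(m)
        if self.UE.shape != (m, m):
            raise ValueError("UE shape mismatch")
        if np.max(np.abs(self.UE - self.UE.T)) > 1e-8:
            raise ValueError("UE must be symmetric")
        if np.any(self.Sigma <= 0):
            raise ValueError("Sigma diagonal must be positive")
        if self.FE is not None:
            self.FE = np.asarray(self.FE, dtype=float)
            if self.FE.shape != (m, m):
                raise ValueError("FE shape mismatch")

    def frame(self, which: str = "UE") -> pd.DataFrame:
        M = {"UE": self.UE, "FE": self.FE}.get(which)
        if which == "Sigma":
            return pd.DataFrame({"sigma2": self.Sigma}, index=self.env_ids)
        if M is None:
            raise ValueError(f"{which} not available")
        return pd.DataFrame(M, index=self.env_ids, columns=self.env_ids)


def env_correlations(E: EnvCovariance) -> np.ndarray:
    """Between-environment genetic correlation matrix ``r_jj' = UE_jj' / sqrt(UE_jj UE_j'j')``."""
    d = np.sqrt(np.diag(E.UE))
    if np.any(d <= 0):
        raise ValueError("UE diagonal must be positive to form correlations")
    R = E.UE / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return R


@dataclass
class MucPriors:
    """Priors for the Kronecker family.

    ``UE``/``FE``: inverse-Wishart (df, scale matrix); weakly informative
    defaults use df = m + 2 and scale 0.5 * diag(per-environment phenotypic
    variance). ``sigma2``: scaled-inverse-chi-square (nu, per-env scale).
    """

    ue_df: float
    ue_scale: np.ndarray
    sigma_nu: float
    sigma_scale: np.ndarray
    fe_df: float = None
    fe_scale: np.ndarray = None


def default_muc_priors(W: WideTrial, with_f: bool, obs: np.ndarray) -> MucPriors:
    m = len(W.env_ids)
    var_env = np.empty(m)
    for j in range(m):
        col = W.Y[obs[:, j], j]
        var_env[j] = np.var(col, ddof=1) if col.size > 1 else 1.0
    var_env = np.where(np.isfinite(var_env) & (var_env > 0), var_env, 1.0)
    return MucPriors(
        ue_df=m + 2.0,
        ue_scale=0.5 * np.diag(var_env),
        sigma_nu=5.0,
        sigma_scale=0.5 * var_env,
        fe_df=(m + 2.0) if with_f else None,
        fe_scale=(0.5 * np.diag(var_env)) if with_f else None,
    )


@dataclass
class MucResult:
    """Posterior summary of a MUC/MUCf fit."""

    env_cov: EnvCovariance
    mu: float
    beta_env: dict
    predictions: np.ndarray       # n x m posterior mean of eta + u (+ f)
    line_ids: list
    env_ids: list
    chains: pd.DataFrame          # per-kept-draw UE entries and Sigma
    n_kept: int
    n_jittered: int
    model: str

    def cell_predictions(self) -> pd.DataFrame:
        n, m = self.predictions.shape
        recs = [
            (self.line_ids[i], self.env_ids[j], self.predictions[i, j])
            for j in range(m)
            for i in range(n)
        ]
        return pd.DataFrame(recs, columns=["line", "env", "predicted"])


def fit_muc(
    W: WideTrial,
    K: KernelMatrix,
    with_f: bool = False,
    priors: MucPriors = None,
    cfg: McmcConfig = None,
    mask=None,
    fixed_UE: np.ndarray = None,
    fixed_Sigma: np.ndarray = None,
    _eig=None,
) -> MucResult:
    """Gibbs fit of the unstructured-covariance model on a wide trial.

    Parameters
    ----------
    W : WideTrial
        n x m phenotype matrix; NaN cells are unobserved and data-augmented.
    K : KernelMatrix
        Line kernel covering all rows of ``W``.
    with_f : bool
        Include the intercept-level covariance term ``f ~ N(0, FE ⊗ I)``.
    mask : boolean (n, m) array or iterable of (line_id, env_id), optional
        Extra cells to hold out: predicted, never read.
    fixed_UE, fixed_Sigma : optional
        Pin UE (possibly singular, e.g. ``c * J``) and/or the residual
        diagonal; their updates are skipped.

    Returns
    -------
    MucResult
    """
    n, m = W.Y.shape
    if m < 2:
        raise ValueError("unstructured covariance needs at least two environments")
    Ks = K.subset(W.line_ids)
    cfg = cfg or McmcConfig()

    obs = W.observed.copy()
    if mask is not None:
        if isinstance(mask, np.ndarray) and mask.dtype == bool:
            if mask.shape != (n, m):
                raise ValueError("boolean mask must be n x m")
            obs &= ~mask
        else:
            lpos = {s: i for i, s in enumerate(W.line_ids)}
            epos = {s: j for j, s in enumerate(W.env_ids)}
            for line, envid in mask:
                obs[lpos[str(line)], epos[str(envid)]] = False
    if np.any(obs.sum(axis=0) < 1):
        raise ValueError("every environment needs at least one observed cell")

    if priors is None:
        priors = default_muc_priors(W, with_f, obs)

    lam, V = (Ks.eigen() if _eig is None else _eig)
    keep = lam > 1e-12 * max(lam[-1], 1e-300)
    lam_r = lam[keep]
    Vr = V[:, keep]
    r = lam_r.size

    rng = np.random.default_rng(cfg.seed)
    eta = np.array([W.Y[obs[:, j], j].mean() for j in range(m)])
    Y = W.Y.copy()
    hidden = ~obs
    Y[hidden] = np.broadcast_to(eta, (n, m))[hidden]

    UE = fixed_UE if fixed_UE is not None else priors.ue_scale / max(priors.ue_df - m - 1.0, 1.0)
    UE = np.array(UE, dtype=float)
    s2 = np.array(fixed_Sigma, dtype=float) if fixed_Sigma is not None else priors.sigma_scale.copy()
    FE = (priors.fe_scale / max(priors.fe_df - m - 1.0, 1.0)) if with_f else None
    Ut = np.zeros((r, m))   # rotated u coefficients
    Umat = np.zeros((n, m))
    F = np.zeros((n, m))

    n_kept = 0
    n_jittered = 0
    pred_sum = np.zeros((n, m))
    eta_sum = np.zeros(m)
    UE_sum = np.zeros((m, m))
    FE_sum = np.zeros((m, m)) if with_f else None
    s2_sum = np.zeros(m)
    chain_rows = []
    iu = np.triu_indices(m)
    chain_cols = [f"UE[{W.env_ids[i]},{W.env_ids[j]}]" for i, j in zip(*iu)] + [
        f"sigma2[{e}]" for e in W.env_ids
    ]

    for it in range(cfg.n_iter):
        # environment means (flat prior)
        R0 = Y - Umat - F
        eta = R0.mean(axis=0) + rng.standard_normal(m) * np.sqrt(s2 / n)

        # u update in doubly rotated coordinates (rows by V, columns by eigvecs of UE)
        lu, Qu = np.linalg.eigh((UE + UE.T) / 2.0)
        lu_max = max(lu[-1], 0.0)
        keep_u = lu > 1e-12 * max(lu_max, 1e-300)
        if not np.any(keep_u):
            Ut = np.zeros((r, m))
            Umat = np.zeros((n, m))
        else:
            Qr = Qu[:, keep_u]
            lur = lu[keep_u]
            mr = lur.size
            Rt = Vr.T @ (Y - eta[None, :] - F)           # r x m
            A = (Qr.T * (1.0 / s2)[None, :]) @ Qr        # m_r x m_r, same for all rows
            prec = A[None, :, :] + np.zeros((r, mr, mr))
            idx = np.arange(mr)
            prec[:, idx, idx] += 1.0 / (lam_r[:, None] * lur[None, :])
            Cov = np.linalg.inv(prec)
            rhs = (Rt * (1.0 / s2)[None, :]) @ Qr        # r x m_r
            mean = np.einsum("rij,rj->ri", Cov, rhs)
            try:
                L = np.linalg.cholesky(Cov)
            except np.linalg.LinAlgError:
                n_jittered += 1
                Cov[:, idx, idx] += 1e-10
                L = np.linalg.cholesky(Cov)
            z = rng.standard_normal((r, mr))
            Cmat = mean + np.einsum("rij,rj->ri", L, z)
            Ut = Cmat @ Qr.T                             # r x m
            Umat = Vr @ Ut

        # UE from its inverse-Wishart full conditional
        if fixed_UE is None:
            Su = Ut.T @ (Ut / lam_r[:, None])
            scale = priors.ue_scale + Su
            scale = (scale + scale.T) / 2.0
            UE = stats.invwishart.rvs(df=priors.ue_df + r, scale=scale, random_state=rng)
            UE = np.atleast_2d(UE)
            try:
                np.linalg.cholesky((UE + UE.T) / 2.0)
            except np.linalg.LinAlgError:
                n_jittered += 1
                UE = UE + 1e-8 * np.eye(m)

        # f update: iid rows with covariance FE
        if with_f:
            Rf = Y - eta[None, :] - Umat
            prec_f = np.diag(1.0 / s2) + np.linalg.inv(FE)
            Cov_f = np.linalg.inv(prec_f)
            Cov_f = (Cov_f + Cov_f.T) / 2.0
            Lf = np.linalg.cholesky(Cov_f)
            Mean = (Rf * (1.0 / s2)[None, :]) @ Cov_f
            F = Mean + rng.standard_normal((n, m)) @ Lf.T
            scale_f = priors.fe_scale + F.T @ F
            scale_f = (scale_f + scale_f.T) / 2.0
            FE = stats.invwishart.rvs(df=priors.fe_df + n, scale=scale_f, random_state=rng)
            FE = np.atleast_2d(FE)

        # heterogeneous residual variances
        E = Y - eta[None, :] - Umat - F
        if fixed_Sigma is None:
            for j in range(m):
                nupost = priors.sigma_nu + n
                sc = (priors.sigma_nu * priors.sigma_scale[j] + float(E[:, j] @ E[:, j])) / nupost
                s2[j] = _scaled_inv_chi2(rng, nupost, sc)

        # data augmentation of empty/masked cells
        if hidden.any():
            fitted = eta[None, :] + Umat + F
            noise = rng.standard_normal((n, m)) * np.sqrt(s2)[None, :]
            Y[hidden] = (fitted + noise)[hidden]

        if not np.all(np.isfinite(UE)) or not np.all(np.isfinite(s2)):
            raise RuntimeError(f"sampler diverged at iteration {it}")

        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
            n_kept += 1
            eta_sum += eta
            pred_sum += eta[None, :] + Umat + F
            UE_sum += UE
            s2_sum += s2
            if with_f:
                FE_sum += FE
            chain_rows.append(np.concatenate([UE[iu], s2]))

    eta_mean = eta_sum / n_kept
    mu = float(eta_mean.mean())
    beta = {e: float(eta_mean[j] - mu) for j, e in enumerate(W.env_ids)}
    env_cov = EnvCovariance(
        env_ids=list(W.env_ids),
        UE=UE_sum / n_kept,
        Sigma=s2_sum / n_kept,
        FE=(FE_sum / n_kept) if with_f else None,
    )
    return MucResult(
        env_cov=env_cov,
        mu=mu,
        beta_env=beta,
        predictions=pred_sum / n_kept,
        line_ids=list(W.line_ids),
        env_ids=list(W.env_ids),
        chains=pd.DataFrame(np.array(chain_rows), columns=chain_cols),
        n_kept=n_kept,
        n_jittered=n_jittered,
        model="MUCf" if with_f else "MUC",
    )
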