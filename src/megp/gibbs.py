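"""Bayesian Gibbs sampler for the Hadamard-family multi-environment models.

Fits any of MM, MMl, MDs, MDsl, MDe, MDel:

    y = mu*1 + ZE betaE + Zg g [+ ge | gE] [+ Zg l] + eps,   eps ~ N(0, sigma2 I)

with homogeneous error variance. Each random term has covariance
``sigma_k^2 C_k`` for a known pattern ``C_k`` (see :mod:`megp.design`); the
sampler works in eigen-rotated coordinates: with ``C_k = U_k D_k U_k'``
(orthonormal ``U_k``), the effect is ``U_k b_k`` where ``b_k`` has a diagonal
normal prior ``N(0, sigma_k^2 D_k)``, so every full conditional of ``b_k``
is diagonal and a sweep costs a handful of matrix-vector products.

Fixed part: per-environment means ``eta_j = mu + betaE_j`` carry a flat prior
and are Gibbs-updated directly; ``mu`` is reported as their average and
``betaE`` as sum-to-zero deviations, which keeps ``mu`` identifiable.

Variance components carry scaled-inverse-chi-square priors (nu, S); their
full conditionals are scaled-inverse-chi-square as well. Records listed in
``mask`` are treated as missing: their phenotypes are never read, and the
sampler data-augments them (draws them from the current model) so they
contribute nothing to the posterior while still receiving predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import (
    TrialData,
    build_incidence,
    gxe_env_specific_structures,
    gxe_single_structure,
    intercept_structure,
    main_effect_structure,
)
from .kernels import KernelMatrix

__all__ = [
    "MODEL_FAMILIES",
    "HADAMARD_MODELS",
    "ModelSpec",
    "PriorSpec",
    "McmcConfig",
    "PosteriorSummary",
    "eigen_rotate",
    "build_structures",
    "default_priors",
    "prepare",
    "fit",
    "prior_sanity",
]

HADAMARD_MODELS = ("MM", "MMl", "MDs", "MDsl", "MDe", "MDel")
KRONECKER_MODELS = ("MUC", "MUCf")
MODEL_FAMILIES = HADAMARD_MODELS + KRONECKER_MODELS

_MODEL_TERMS = {
    "MM": ("g",),
    "MMl": ("g", "l"),
    "MDs": ("g", "ge"),
    "MDsl": ("g", "ge", "l"),
    "MDe": ("g", "gE"),
    "MDel": ("g", "gE", "l"),
    "MUC": ("u",),
    "MUCf": ("u", "f"),
}


@dataclass
class ModelSpec:
    """A model name (one of the eight families) plus the kernel method.

    ``components`` lists the random terms the model includes (residual always
    implied), matching the model definitions exactly.
    """

    name: str
    kernel_method: str = "GB"

    def __post_init__(self):
        if self.name not in MODEL_FAMILIES:
            raise ValueError(f"unknown model {self.name!r}; expected one of {MODEL_FAMILIES}")
        if self.kernel_method not in ("GB", "GK"):
            raise ValueError(f"unknown kernel method {self.kernel_method!r}")

    @property
    def components(self) -> tuple:
        return _MODEL_TERMS[self.name] + ("residual",)

    @property
    def label(self) -> str:
        return f"{self.name}-{self.kernel_method}"


@dataclass
class PriorSpec:
    """Scaled-inverse-chi-square (nu, S) hyperparameters per variance symbol.

    ``components`` maps a variance symbol (e.g. ``"sigma2_g"``, ``"sigma2"``)
    to a ``(nu, S)`` pair. Fixed effects carry flat priors implicitly.
    """

    components: dict

    def __post_init__(self):
        for sym, (nu, S) in self.components.items():
            if nu <= 0 or S <= 0:
                raise ValueError(f"prior for {sym} needs nu > 0 and S > 0, got ({nu}, {S})")

    def get(self, symbol: str) -> tuple:
        return self.components[symbol]


@dataclass
class McmcConfig:
    n_iter: int = 12000
    burn_in: int = 2000
    thin: int = 5
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("need 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class PosteriorSummary:
    """Posterior means/SDs of variance components, fixed effects, predictions.

    ``predictions`` holds the posterior mean of mu + ZE betaE + sum of random
    effects (residual excluded) for every record, observed and masked, aligned
    to the canonical record order of the trial. ``chains`` keeps the thinned
    post-burn-in variance-component draws for diagnostics.
    """

    variance_mean: dict
    variance_sd: dict
    mu: float
    beta_env: dict
    predictions: np.ndarray
    records: pd.DataFrame
    chains: pd.DataFrame
    n_kept: int
    model: str = ""

    def __post_init__(self):
        for sym, v in self.variance_mean.items():
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"invalid posterior mean for {sym}: {v}")

    def prediction_frame(self) -> pd.DataFrame:
        out = self.records.copy()
        out["predicted"] = self.predictions
        return out

    def summary_dict(self) -> dict:
        return {
            "model": self.model,
            "mu": self.mu,
            "beta_env": self.beta_env,
            "variance_components": {
                k: {"mean": self.variance_mean[k], "sd": self.variance_sd[k]}
                for k in self.variance_mean
            },
            "n_kept": self.n_kept,
        }


@dataclass
class Rotated:
    """Eigen-rotated representation of a covariance pattern: C = U diag(d) U'."""

    name: str
    variance_symbol: str
    U: np.ndarray
    d: np.ndarray


def eigen_rotate(structures, tol: float = 1e-10) -> list:
    """Rotate covariance patterns into orthonormal eigenbases.

    Low-rank factors ``C = B B'`` go through a thin SVD; block-diagonal
    patterns through per-block symmetric eigendecompositions (the blocks are
    disjoint in record space, so block eigenvectors embed orthonormally).
    Eigenvalues below ``tol * d_max`` are dropped; eigenvalues below
    ``-1e-8 * d_max`` raise.
    """
    rotated = []
    for s in structures:
        if s.rep == "lowrank":
            U, sv, _ = np.linalg.svd(s.B, full_matrices=False)
            d = sv * sv
            keep = d > tol * max(d[0] if d.size else 0.0, 1e-300)
            rotated.append(Rotated(s.name, s.variance_symbol, U[:, keep], d[keep]))
        elif s.rep == "blockdiag":
            cols, vals = [], []
            for idx, block in s.blocks:
                w, V = np.linalg.eigh(block)
                wmax = max(w[-1], 0.0) if w.size else 0.0
                if w.size and w[0] < -1e-8 * max(wmax, 1e-300):
                    raise ValueError(
                        f"structure {s.name!r} block is not PSD (min eig {w[0]:.3e})"
                    )
                keep = w > tol * max(wmax, 1e-300)
                Ufull = np.zeros((s.n_records, int(keep.sum())))
                Ufull[idx, :] = V[:, keep]
                cols.append(Ufull)
                vals.append(w[keep])
            U = np.concatenate(cols, axis=1) if cols else np.zeros((s.n_records, 0))
            d = np.concatenate(vals) if vals else np.zeros(0)
            rotated.append(Rotated(s.name, s.variance_symbol, U, d))
        else:
            raise ValueError(f"unknown structure representation {s.rep!r}")
    return rotated


def build_structures(model: str, D, K: KernelMatrix) -> list:
    """Covariance patterns (residual excluded) for a Hadamard-family model."""
    if model not in HADAMARD_MODELS:
        raise ValueError(f"{model!r} is not a Hadamard-family model")
    terms = _MODEL_TERMS[model]
    out = [main_effect_structure(D, K)]
    if "ge" in terms:
        out.append(gxe_single_structure(D, K))
    if "gE" in terms:
        out.extend(gxe_env_specific_structures(D, K))
    if "l" in terms:
        out.append(intercept_structure(D))
    return out


def default_priors(y_obs: np.ndarray, symbols, nu: float = 5.0, r2: float = 0.5) -> PriorSpec:
    """Weakly informative priors anchored at the phenotypic variance.

    The prior *mode* (= nu S / (nu + 2)) of each non-residual component is set
    to ``var(y) * r2 / k`` with the heritable budget ``r2`` split equally over
    the ``k`` non-residual components; the residual mode is
    ``var(y) * (1 - r2)``. Standard Bayesian-GBLUP defaults; override freely.
    """
    vy = float(np.var(y_obs, ddof=1))
    if not np.isfinite(vy) or vy <= 0:
        vy = 1.0
    non_res = [s for s in symbols if s != "sigma2"]
    k = max(len(non_res), 1)
    comps = {}
    for s in non_res:
        comps[s] = (nu, vy * r2 / k * (nu + 2.0) / nu)
    comps["sigma2"] = (nu, vy * (1.0 - r2) * (nu + 2.0) / nu)
    return PriorSpec(comps)


def _scaled_inv_chi2(rng: np.random.Generator, nu: float, scale: float) -> float:
    return nu * scale / rng.chisquare(nu)


@dataclass
class FitContext:
    """Precomputed design + rotations for one (trial, model, kernel) triple.

    Masking does not alter the covariance patterns (masked records are
    data-augmented), so one context serves every cross-validation partition.
    """

    trial: TrialData
    spec: ModelSpec
    design: object
    structures: list
    rotated: list

    @property
    def symbols(self) -> list:
        return [r.variance_symbol for r in self.rotated] + ["sigma2"]


def prepare(T: TrialData, spec: ModelSpec, K: KernelMatrix) -> FitContext:
    """Build incidence, covariance patterns, and eigen-rotations once."""
    D = build_incidence(T)
    structures = build_structures(spec.name, D, K)
    rotated = eigen_rotate(structures)
    return FitContext(trial=T, spec=spec, design=D, structures=structures, rotated=rotated)


def fit(
    T: TrialData,
    spec: ModelSpec,
    K: KernelMatrix,
    priors: PriorSpec = None,
    cfg: McmcConfig = None,
    mask=None,
    fixed_variances: dict = None,
    _ctx: FitContext = None,
) -> PosteriorSummary:
    """Gibbs fit of a Hadamard-family model.

    Parameters
    ----------
    T : TrialData
    spec : ModelSpec
        One of MM, MMl, MDs, MDsl, MDe, MDel (kernel_method is metadata here;
        pass the matching ``K``).
    K : KernelMatrix
        Line kernel covering every trial line.
    priors : PriorSpec, optional
        Defaults to :func:`default_priors` computed from the *observed*
        (unmasked) phenotypes.
    cfg : McmcConfig, optional
    mask : iterable of int, optional
        Canonical record indices treated as missing (predicted, never read).
    fixed_variances : dict, optional
        Variance symbols pinned to fixed values (their Gibbs updates are
        skipped); a value of 0 pins the whole effect at zero.

    Returns
    -------
    PosteriorSummary
    """
    ctx = _ctx if _ctx is not None else prepare(T, spec, K)
    cfg = cfg or McmcConfig()
    fixed = dict(fixed_variances or {})
    D = ctx.design
    N = D.n_records
    m = len(D.env_ids)
    y = D.y.copy()

    obs = np.ones(N, dtype=bool)
    if mask is not None:
        mask_idx = np.asarray(sorted(set(int(i) for i in mask)), dtype=int)
        if mask_idx.size and (mask_idx.min() < 0 or mask_idx.max() >= N):
            raise IndexError("mask indices out of range")
        obs[mask_idx] = False
    miss = np.where(~obs)[0]

    n_obs_env = np.bincount(D.env_index[obs], minlength=m)
    if np.any(n_obs_env == 0):
        empty = [D.env_ids[j] for j in np.where(n_obs_env == 0)[0]]
        raise ValueError(f"environments with no observed records: {empty}")

    symbols = ctx.symbols
    if priors is None:
        priors = default_priors(y[obs], symbols)

    rng = np.random.default_rng(cfg.seed)
    env = D.env_index
    n_env = np.bincount(env, minlength=m).astype(float)

    # --- initialization (independent of masked phenotype values) ---
    eta = np.array(
        [y[obs & (env == j)].mean() for j in range(m)]
    )
    y_aug = y.copy()
    if miss.size:
        y_aug[miss] = eta[env[miss]]
    rots = ctx.rotated
    ncomp = len(rots)
    b = [np.zeros(r.d.size) for r in rots]
    contrib = [np.zeros(N) for _ in rots]
    sig2 = np.empty(ncomp)
    for k, r in enumerate(rots):
        sym = r.variance_symbol
        sig2[k] = fixed[sym] if sym in fixed else priors.get(sym)[1]
    sig2_e = fixed["sigma2"] if "sigma2" in fixed else priors.get("sigma2")[1]
    resid = y_aug - eta[env]

    keep_every = cfg.thin
    n_kept = 0
    chain_rows = []
    eta_sum = np.zeros(m)
    pred_sum = np.zeros(N)

    for it in range(cfg.n_iter):
        # fixed part: per-environment means, flat prior
        partial = resid + eta[env]
        means = np.bincount(env, weights=partial, minlength=m) / n_env
        eta = means + rng.standard_normal(m) * np.sqrt(sig2_e / n_env)
        resid = partial - eta[env]

        # random effects in rotated coordinates (diagonal full conditionals)
        for k, r in enumerate(rots):
            ek = resid + contrib[k]
            if sig2[k] <= 0.0:
                bk = np.zeros(r.d.size)
                new_c = np.zeros(N)
            else:
                z = r.U.T @ ek
                v = 1.0 / (1.0 / sig2_e + 1.0 / (sig2[k] * r.d))
                bk = v * z / sig2_e + np.sqrt(v) * rng.standard_normal(r.d.size)
                new_c = r.U @ bk
            b[k] = bk
            contrib[k] = new_c
            resid = ek - new_c

            sym = r.variance_symbol
            if sym not in fixed:
                nu, S = priors.get(sym)
                q = float(np.sum(bk * bk / r.d))
                nupost = nu + bk.size
                sig2[k] = _scaled_inv_chi2(rng, nupost, (nu * S + q) / nupost)

        # residual variance
        if "sigma2" not in fixed:
            nu0, S0 = priors.get("sigma2")
            nupost = nu0 + N
            sig2_e = _scaled_inv_chi2(
                rng, nupost, (nu0 * S0 + float(resid @ resid)) / nupost
            )

        # data augmentation of masked records
        if miss.size:
            fitted_miss = y_aug[miss] - resid[miss]
            noise = rng.standard_normal(miss.size) * np.sqrt(sig2_e)
            y_aug[miss] = fitted_miss + noise
            resid[miss] = noise

        if not np.isfinite(sig2_e) or not np.all(np.isfinite(sig2)):
            raise RuntimeError(f"sampler diverged (non-finite variance) at iteration {it}")

        if it >= cfg.burn_in and (it - cfg.burn_in) % keep_every == 0:
            n_kept += 1
            chain_rows.append(np.concatenate([sig2, [sig2_e]]))
            eta_sum += eta
            pred_sum += y_aug - resid  # eta + sum of random-effect contributions

    chains = pd.DataFrame(np.array(chain_rows), columns=symbols)
    var_mean = {s: float(chains[s].mean()) for s in symbols}
    var_sd = {s: float(chains[s].std(ddof=1)) if n_kept > 1 else 0.0 for s in symbols}
    eta_mean = eta_sum / n_kept
    mu = float(eta_mean.mean())
    beta = {e: float(eta_mean[j] - mu) for j, e in enumerate(D.env_ids)}
    records = ctx.trial.df.copy()
    records["observed"] = obs
    return PosteriorSummary(
        variance_mean=var_mean,
        variance_sd=var_sd,
        mu=mu,
        beta_env=beta,
        predictions=pred_sum / n_kept,
        records=records,
        chains=chains,
        n_kept=n_kept,
        model=spec.label,
    )


def prior_sanity(priors: PriorSpec, cfg: McmcConfig = None, n_draws: int = None) -> dict:
    """Sample each variance prior with the likelihood disabled (Geweke-style).

    Draws from the scaled-inverse-chi-square prior exactly as the sampler's
    full conditional would with the data terms removed, and reports sample
    moments next to the analytic mean ``nu S / (nu - 2)`` (undefined and
    reported as None when nu <= 2).
    """
    cfg = cfg or McmcConfig()
    n = n_draws if n_draws is not None else max(cfg.n_iter, 1000)
    rng = np.random.default_rng(cfg.seed)
    out = {}
    for sym, (nu, S) in priors.components.items():
        draws = nu * S / rng.chisquare(nu, size=n)
        analytic = nu * S / (nu - 2.0) if nu > 2 else None
        out[sym] = {
            "mean": float(draws.mean()),
            "sd": float(draws.std(ddof=1)),
            "analytic_mean": analytic,
            "n": n,
        }
    return out
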