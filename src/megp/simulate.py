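"""Synthetic marker and multi-environment trial generation.

The generator draws data from exactly the statistical laws the models assume,
so fitting the matching model to its own simulation is an identifiability
check with known truth. Markers are independent binomial dosages (no linkage
disequilibrium); genetic effects are drawn in the kernel eigenbasis, which
guarantees e.g. ``Var(g) = sigma2_g * K`` by construction rather than only in
expectation over marker effects.

An optional *epistasis fraction* routes part of the genetic signal through a
component with covariance proportional to the elementwise square ``K ∘ K``
(the covariance of pairwise marker-product effects). A Gaussian kernel can
exploit this non-additive signal; the linear kernel cannot, which is how the
simulator reproduces the GK-over-GB accuracy ordering.

Scenario presets mirror the four reference trials: two maize-like settings
(positively correlated environments, unbalanced line counts) and two
wheat-like settings (negative / near-zero correlations, balanced). Preset
variance magnitudes are borrowed scales for realism, not reproduction
targets.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .design import TrialData
from .kernels import KernelMatrix, linear_kernel
from .markers import MarkerMatrix

__all__ = [
    "SimulationSpec",
    "SimTruth",
    "simulate_markers",
    "simulate_trial",
    "preset",
    "PRESETS",
]


@dataclass
class SimulationSpec:
    """Generative settings of one synthetic multi-environment trial.

    Variance components follow the generative model named in ``model``:
    ``sigma2_g`` (main genetic), ``sigma2_ge`` (single-variance GxE),
    ``sigma2_gE`` (per-environment GxE list, MDe family), ``sigma2_l``
    (iid line intercept), ``sigma2`` (residual); or, for the Kronecker
    family, ``UE``/``FE``/``Sigma``. ``env_counts`` gives per-environment
    line counts for unbalanced incidence (cells dropped at random);
    ``cell_prob`` independently thins cells instead. ``epistasis_fraction``
    is the share of each genetic variance routed through the K∘K component.
    """

    n_lines: int = 300
    n_markers: int = 1000
    maf_range: tuple = (0.05, 0.5)
    n_envs: int = 4
    model: str = "MDs"
    sigma2_g: float = 0.6
    sigma2_ge: float = 0.4
    sigma2_gE: list = None
    sigma2_l: float = 0.3
    sigma2: float = 1.0
    UE: np.ndarray = None
    FE: np.ndarray = None
    Sigma: np.ndarray = None
    env_means: list = None
    env_counts: list = None
    cell_prob: float = 1.0
    epistasis_fraction: float = 0.0
    seed: int = 0
    name: str = ""

    def __post_init__(self):
        from .gibbs import MODEL_FAMILIES

        if self.model not in MODEL_FAMILIES:
            raise ValueError(f"unknown generative model {self.model!r}")
        for v in (self.sigma2_g, self.sigma2_ge, self.sigma2_l, self.sigma2):
            if v < 0:
                raise ValueError("variance components must be nonnegative")
        if not (0.0 <= self.epistasis_fraction <= 1.0):
            raise ValueError("epistasis_fraction must lie in [0, 1]")
        if self.env_counts is not None:
            if len(self.env_counts) != self.n_envs:
                raise ValueError("env_counts length must equal n_envs")
            if any(c > self.n_lines or c < 1 for c in self.env_counts):
                raise ValueError("env_counts must lie in [1, n_lines]")
        if self.model.startswith("MUC"):
            if self.UE is None:
                raise ValueError("MUC generative model needs UE")
            self.UE = np.asarray(self.UE, dtype=float)
            if self.UE.shape != (self.n_envs, self.n_envs):
                raise ValueError("UE must be m x m")
            np.linalg.cholesky((self.UE + self.UE.T) / 2.0)  # PD check
            if self.Sigma is None:
                self.Sigma = np.full(self.n_envs, self.sigma2)
            self.Sigma = np.asarray(self.Sigma, dtype=float).reshape(self.n_envs)
            if self.model == "MUCf":
                if self.FE is None:
                    raise ValueError("MUCf generative model needs FE")
                self.FE = np.asarray(self.FE, dtype=float)
                np.linalg.cholesky(self.FE)


@dataclass
class SimTruth:
    """Ground truth of one simulation: effect vectors and parameters."""

    g: np.ndarray = None            # n main genetic effects
    ge: np.ndarray = None           # n x m GxE deviations (MDs/MDe families)
    l: np.ndarray = None            # n iid intercepts
    u: np.ndarray = None            # n x m Kronecker genetic values
    f: np.ndarray = None            # n x m intercept-level effects
    genetic_values: np.ndarray = None  # n x m total genetic value per cell
    env_means: np.ndarray = None
    params: dict = None
    K: KernelMatrix = None
    markers: MarkerMatrix = None


def simulate_markers(n: int, p: int, maf_range=(0.05, 0.5), seed: int = 0) -> MarkerMatrix:
    """Independent binomial dosage markers: x_ik ~ Binomial(2, q_k).

    Per-marker allele frequencies q_k are uniform on ``maf_range`` (a subset
    of (0, 0.5]).
    """
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
    rng = np.random.default_rng(seed)
    q = rng.uniform(lo, hi, size=p)
    X = rng.binomial(2, q[None, :], size=(n, p)).astype(float)
    return MarkerMatrix(
        line_ids=[f"L{i + 1:05d}" for i in range(n)],
        X=X,
        standardized=False,
    )


def _draw_kernel_effect(rng, lam, V, lam2, V2, variance, ef, size=None):
    """Draw N(0, variance * ((1-ef) K + ef K2)) via eigenbasis coordinates."""
    n = V.shape[0]
    cols = 1 if size is None else size
    out = np.zeros((n, cols))
    if variance <= 0:
        return out[:, 0] if size is None else out
    if ef < 1.0:
        z = rng.standard_normal((lam.size, cols))
        out += V @ (np.sqrt((1.0 - ef) * variance * lam)[:, None] * z)
    if ef > 0.0:
        z = rng.standard_normal((lam2.size, cols))
        out += V2 @ (np.sqrt(ef * variance * lam2)[:, None] * z)
    return out[:, 0] if size is None else out


def simulate_trial(spec: SimulationSpec, M: MarkerMatrix = None, seed: int = None):
    """Simulate a trial from the generative law named in ``spec.model``.

    Returns ``(TrialData, SimTruth)``. The line kernel used for the draws is
    the linear (GBLUP) kernel of the simulated markers; with a nonzero
    epistasis fraction part of the genetic covariance is ``K ∘ K``
    (normalized to unit mean diagonal).
    """
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    n, m = spec.n_lines, spec.n_envs
    if M is None:
        M = simulate_markers(n, spec.n_markers, spec.maf_range,
                             seed=int(rng.integers(2**31 - 1)))
    if M.n_lines != n:
        raise ValueError("marker matrix does not match n_lines")
    K = linear_kernel(M)
    lam, V = K.eigen()
    keep = lam > 1e-12 * max(lam[-1], 1e-300)
    lam, V = lam[keep], V[:, keep]

    ef = spec.epistasis_fraction
    lam2 = V2 = None
    if ef > 0.0:
        K2 = K.K * K.K
        K2 = K2 / np.mean(np.diag(K2))
        w2, Q2 = np.linalg.eigh(K2)
        keep2 = w2 > 1e-12 * max(w2[-1], 1e-300)
        lam2, V2 = np.clip(w2[keep2], 0, None), Q2[:, keep2]

    env_ids = [f"E{j + 1}" for j in range(m)]
    line_ids = list(M.line_ids)
    if spec.env_means is None:
        env_means = np.linspace(-0.5, 0.5, m)
    else:
        env_means = np.asarray(spec.env_means, dtype=float).reshape(m)

    truth = SimTruth(env_means=env_means, K=K, markers=M, params={})
    G = np.zeros((n, m))

    if spec.model.startswith("MUC"):
        Lu = np.linalg.cholesky(spec.UE)
        zu = rng.standard_normal((lam.size, m))
        U = V @ (np.sqrt(lam)[:, None] * zu) @ Lu.T
        truth.u = U
        G += U
        if spec.model == "MUCf":
            Lf = np.linalg.cholesky(spec.FE)
            Fm = rng.standard_normal((n, m)) @ Lf.T
            truth.f = Fm
            G += Fm
        sig_env = np.asarray(spec.Sigma, dtype=float)
        truth.params = {"UE": spec.UE, "FE": spec.FE, "Sigma": sig_env}
    else:
        g = _draw_kernel_effect(rng, lam, V, lam2, V2, spec.sigma2_g, ef)
        truth.g = g
        G += g[:, None]
        params = {"sigma2_g": spec.sigma2_g, "sigma2": spec.sigma2}
        if spec.model in ("MDs", "MDsl"):
            ge = _draw_kernel_effect(rng, lam, V, lam2, V2, spec.sigma2_ge, ef, size=m)
            truth.ge = ge
            G += ge
            params["sigma2_ge"] = spec.sigma2_ge
        elif spec.model in ("MDe", "MDel"):
            varsE = (
                [spec.sigma2_ge] * m if spec.sigma2_gE is None else list(spec.sigma2_gE)
            )
            if len(varsE) != m:
                raise ValueError("sigma2_gE must have one entry per environment")
            ge = np.zeros((n, m))
            for j in range(m):
                ge[:, j] = _draw_kernel_effect(rng, lam, V, lam2, V2, varsE[j], ef)
            truth.ge = ge
            G += ge
            for j, e in enumerate(env_ids):
                params[f"sigma2_gE[{e}]"] = varsE[j]
        if spec.model in ("MMl", "MDsl", "MDel"):
            l = rng.standard_normal(n) * np.sqrt(spec.sigma2_l)
            truth.l = l
            G += l[:, None]
            params["sigma2_l"] = spec.sigma2_l
        truth.params = params
        sig_env = np.full(m, spec.sigma2)

    truth.genetic_values = G

    # incidence: which cells are observed
    obs = np.ones((n, m), dtype=bool)
    if spec.env_counts is not None:
        for j, c in enumerate(spec.env_counts):
            if c < n:
                drop = rng.choice(n, size=n - int(c), replace=False)
                obs[drop, j] = False
    elif spec.cell_prob < 1.0:
        obs = rng.random((n, m)) < spec.cell_prob
        for j in range(m):  # keep every environment populated
            if not obs[:, j].any():
                obs[rng.integers(n), j] = True

    eps = rng.standard_normal((n, m)) * np.sqrt(sig_env)[None, :]
    Y = env_means[None, :] + G + eps
    recs = [
        (line_ids[i], env_ids[j], Y[i, j])
        for j in range(m)
        for i in range(n)
        if obs[i, j]
    ]
    T = TrialData(recs, env_order=env_ids, line_order=line_ids)
    return T, truth


def _whe1_like_UE() -> np.ndarray:
    # one environment negatively correlated with the rest, the rest positive
    R = np.array(
        [
            [1.0, -0.3, -0.3, -0.3],
            [-0.3, 1.0, 0.7, 0.7],
            [-0.3, 0.7, 1.0, 0.7],
            [-0.3, 0.7, 0.7, 1.0],
        ]
    )
    s = np.sqrt(np.array([1.0, 0.8, 0.8, 0.9]))
    return R * np.outer(s, s)


PRESETS = {
    # Maize-like: positive environment correlations, unbalanced incidence.
    "HEL_like": SimulationSpec(
        name="HEL_like", n_lines=452, n_markers=2000, n_envs=5, model="MDs",
        sigma2_g=0.938, sigma2_ge=0.525, sigma2=0.278, sigma2_l=0.0,
        env_counts=[247, 330, 452, 367, 330],
    ),
    # Maize-like: near-balanced, sizable iid line intercept.
    "USP_like": SimulationSpec(
        name="USP_like", n_lines=739, n_markers=2000, n_envs=4, model="MDsl",
        sigma2_g=0.343, sigma2_ge=0.091, sigma2_l=0.296, sigma2=0.490,
        env_counts=[731, 732, 731, 737],
    ),
    # Wheat-like: one environment negatively correlated with the others.
    "WHE1_like": SimulationSpec(
        name="WHE1_like", n_lines=599, n_markers=1447, n_envs=4, model="MUC",
        UE=_whe1_like_UE(), Sigma=np.full(4, 0.462), sigma2=0.462,
    ),
    # Wheat-like: balanced, dominant single-variance GxE.
    "WHE5_like": SimulationSpec(
        name="WHE5_like", n_lines=807, n_markers=2000, n_envs=5, model="MDs",
        sigma2_g=0.125, sigma2_ge=0.618, sigma2=0.282, sigma2_l=0.0,
    ),
}


def preset(name: str, **overrides) -> SimulationSpec:
    """Return a scenario preset, optionally overriding fields (e.g. a smaller n).

    Presets carry the reference trials' environment counts, incidence
    patterns, correlation regimes, and borrowed variance scales.
    """
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    base = PRESETS[name]
    return replace(base, **overrides) if overrides else replace(base)
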