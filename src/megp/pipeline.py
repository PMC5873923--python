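"""Configuration-driven runs tying kernels, engines, CV and simulation together.

A run is described by a :class:`RunConfig` (YAML-friendly): either file paths
for phenotypes/markers or a synthetic preset, the list of model-method
combinations (out of the 8 x 2 grid), kernel/CV/MCMC settings, an output
directory, and a mandatory seed. ``run()`` writes, into the output directory:

* ``variance_components_<model>.csv`` — posterior means/SDs per component
  from a full-data fit (the variance-component table shape);
* ``accuracy_<scheme>.csv`` — per-environment mean (SD) Pearson accuracy
  over partitions (the accuracy table shape);
* ``chains_<model>.csv`` — thinned variance-component chains;
* ``partitions.json`` — the exact partitions, reusable across engines;
* ``run_log.json`` — config echo, seed, config hash, package version.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .crossval import evaluate, make_partitions
from .design import TrialData, to_wide
from .gibbs import (
    HADAMARD_MODELS,
    McmcConfig,
    ModelSpec,
    fit,
)
from .kernels import gaussian_kernel, linear_kernel
from .kronecker import fit_muc
from .markers import filter_markers, read_markers
from .simulate import preset, simulate_trial

__all__ = ["RunConfig", "run"]

_VALID_MODELS = {
    f"{name}-{method}"
    for name in ("MM", "MMl", "MDs", "MDsl", "MDe", "MDel", "MUC", "MUCf")
    for method in ("GB", "GK")
}


@dataclass
class RunConfig:
    """Validated run configuration (see module docstring)."""

    seed: int
    out_dir: str
    models: list = field(default_factory=lambda: ["MDs-GB", "MDs-GK"])
    phenotype_path: str = None
    marker_path: str = None
    synthetic_preset: str = None
    preset_overrides: dict = field(default_factory=dict)
    maf_min: float = 0.05
    max_missing: float = 0.2
    gk_bandwidth: float = 1.0
    cv_scheme: str = "CV2"
    n_partitions: int = 10
    fraction_train: float = 0.8
    n_iter: int = 3000
    burn_in: int = 1000
    thin: int = 2
    run_cv: bool = True

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        bad = [mdl for mdl in self.models if mdl not in _VALID_MODELS]
        if bad:
            raise ValueError(
                f"invalid model names {bad}; valid combinations: {sorted(_VALID_MODELS)}"
            )
        has_files = self.phenotype_path is not None and self.marker_path is not None
        if not has_files and self.synthetic_preset is None:
            raise ValueError("provide phenotype_path+marker_path or synthetic_preset")
        if self.cv_scheme not in ("CV1", "CV2"):
            raise ValueError("cv_scheme must be CV1 or CV2")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        payload.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**payload)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _load_inputs(config: RunConfig):
    if config.synthetic_preset is not None:
        spec = preset(config.synthetic_preset, **config.preset_overrides)
        T, truth = simulate_trial(spec, seed=config.seed)
        M = None
        kernels = {"GB": truth.K}
        if any(mdl.endswith("GK") for mdl in config.models):
            from .markers import standardize

            kernels["GK"] = gaussian_kernel(standardize(truth.markers),
                                            h=config.gk_bandwidth)
        return T, kernels
    T = TrialData.from_csv(config.phenotype_path)
    M_raw = read_markers(config.marker_path)
    M, _report = filter_markers(M_raw, maf_min=config.maf_min, max_missing=config.max_missing)
    from .markers import standardize

    Ms = standardize(M)
    kernels = {}
    if any(mdl.endswith("GB") for mdl in config.models):
        kernels["GB"] = linear_kernel(Ms)
    if any(mdl.endswith("GK") for mdl in config.models):
        kernels["GK"] = gaussian_kernel(Ms, h=config.gk_bandwidth)
    return T, kernels


def run(config: RunConfig) -> Path:
    """Execute a configured run; returns the artifact directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    log = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": chash,
        "config": asdict(config),
        "stages": [],
    }

    def _fail(stage, exc):
        log["stages"].append({"stage": stage, "status": "failed", "error": str(exc)})
        with open(out / "run_log.json", "w") as fh:
            json.dump(log, fh, indent=2, default=str)
        raise RuntimeError(f"run failed at stage {stage!r}: {exc}") from exc

    try:
        T, kernels = _load_inputs(config)
        log["stages"].append({"stage": "inputs", "status": "ok",
                              "n_records": T.n_records, "n_lines": T.n_lines,
                              "n_envs": T.n_envs})
    except Exception as exc:  # noqa: BLE001 - stage boundary
        _fail("inputs", exc)

    cfg = McmcConfig(config.n_iter, config.burn_in, config.thin, config.seed)
    specs = []
    for mdl in config.models:
        name, method = mdl.rsplit("-", 1)
        specs.append(ModelSpec(name, method))

    # full-data variance-component fits
    try:
        for spec in specs:
            K = kernels[spec.kernel_method]
            if spec.name in HADAMARD_MODELS:
                res = fit(T, spec, K, cfg=cfg)
                rows = [
                    {"component": sym,
                     "mean": res.variance_mean[sym],
                     "sd": res.variance_sd[sym]}
                    for sym in res.variance_mean
                ]
                pd.DataFrame(rows).to_csv(
                    out / f"variance_components_{spec.label}_seed{config.seed}_{chash}.csv",
                    index=False,
                )
                res.chains.to_csv(
                    out / f"chains_{spec.label}_seed{config.seed}_{chash}.csv", index=False
                )
            else:
                W = to_wide(T)
                res = fit_muc(W, K, with_f=(spec.name == "MUCf"), cfg=cfg)
                res.env_cov.frame("UE").to_csv(
                    out / f"UE_{spec.label}_seed{config.seed}_{chash}.csv"
                )
                res.env_cov.frame("Sigma").to_csv(
                    out / f"Sigma_{spec.label}_seed{config.seed}_{chash}.csv"
                )
                if spec.name == "MUCf":
                    res.env_cov.frame("FE").to_csv(
                        out / f"FE_{spec.label}_seed{config.seed}_{chash}.csv"
                    )
                res.chains.to_csv(
                    out / f"chains_{spec.label}_seed{config.seed}_{chash}.csv", index=False
                )
        log["stages"].append({"stage": "variance_components", "status": "ok"})
    except Exception as exc:  # noqa: BLE001
        _fail("variance_components", exc)

    if config.run_cv:
        try:
            parts = make_partitions(
                T, config.cv_scheme, n_partitions=config.n_partitions,
                fraction_train=config.fraction_train, seed=config.seed,
            )
            parts.to_json(out / f"partitions_seed{config.seed}_{chash}.json")
            table = evaluate(T, specs, kernels, parts, cfg=cfg)
            table.to_csv(out / f"accuracy_{config.cv_scheme}_seed{config.seed}_{chash}.csv")
            log["stages"].append({
                "stage": "cross_validation", "status": "ok",
                "skipped": {f"{k[0]}|{k[1]}": v for k, v in table.skipped.items()},
            })
        except Exception as exc:  # noqa: BLE001
            _fail("cross_validation", exc)

    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, default=str)
    return out
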