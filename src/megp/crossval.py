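"""CV1/CV2 partition generation and prediction-accuracy evaluation.

Two random cross-validation schemes are standard for multi-environment
genomic prediction:

* **CV1** — untested lines: a fraction of *lines* goes to the test set with
  all their records jointly, mimicking newly developed lines never evaluated
  anywhere.
* **CV2** — sparse testing: individual *records* (line-environment cells) go
  to the test set, so a line can be observed in some environments and
  predicted in others, letting models borrow information across environments.

Default protocol: repeated random sub-sampling, 80% train / 20% test,
``n_partitions`` replicates; disjoint k-fold assignment is available behind a
flag. Accuracy is the Pearson correlation between observed and predicted
phenotypes of the test records, computed per environment, reported as mean
(SD) over partitions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import TrialData, to_wide
from .gibbs import HADAMARD_MODELS, McmcConfig, ModelSpec, fit, prepare
from .kronecker import fit_muc

__all__ = [
    "PartitionSet",
    "AccuracyTable",
    "make_partitions",
    "evaluate",
    "pearson_by_env",
]


@dataclass
class PartitionSet:
    """Train/test index partitions over canonical trial records."""

    scheme: str
    partitions: list  # list of (train indices, test indices) as int arrays
    n_partitions: int
    fraction_train: float
    seed: int
    n_resampled: int = 0

    def __post_init__(self):
        if self.scheme not in ("CV1", "CV2"):
            raise ValueError("scheme must be 'CV1' or 'CV2'")

    def to_json(self, path=None):
        payload = {
            "scheme": self.scheme,
            "n_partitions": self.n_partitions,
            "fraction_train": self.fraction_train,
            "seed": self.seed,
            "n_resampled": self.n_resampled,
            "partitions": [
                {"train": np.asarray(tr).tolist(), "test": np.asarray(te).tolist()}
                for tr, te in self.partitions
            ],
        }
        if path is None:
            return json.dumps(payload)
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, src) -> "PartitionSet":
        if isinstance(src, (str, bytes)) and str(src).lstrip().startswith("{"):
            payload = json.loads(src)
        else:
            with open(src) as fh:
                payload = json.load(fh)
        parts = [
            (np.array(p["train"], dtype=int), np.array(p["test"], dtype=int))
            for p in payload["partitions"]
        ]
        return cls(
            scheme=payload["scheme"],
            partitions=parts,
            n_partitions=payload["n_partitions"],
            fraction_train=payload["fraction_train"],
            seed=payload["seed"],
            n_resampled=payload.get("n_resampled", 0),
        )


def _valid_partition(T: TrialData, test: np.ndarray, min_test_per_env: int = 2) -> bool:
    m = T.n_envs
    test_mask = np.zeros(T.n_records, dtype=bool)
    test_mask[test] = True
    test_per_env = np.bincount(T.env_index[test_mask], minlength=m)
    train_per_env = np.bincount(T.env_index[~test_mask], minlength=m)
    return bool(np.all(test_per_env >= min_test_per_env) and np.all(train_per_env >= 1))


def make_partitions(
    T: TrialData,
    scheme: str,
    n_partitions: int = 50,
    fraction_train: float = 0.8,
    seed: int = 0,
    stratify_env: bool = False,
    kfold: bool = False,
    max_resample: int = 500,
) -> PartitionSet:
    """Draw random train/test partitions of a trial.

    CV1 samples ``1 - fraction_train`` of the *lines* into test (with all
    their records); CV2 samples *records* independently of line. Partitions
    violating the per-environment floor (>= 2 test records and >= 1 training
    record in every environment) are resampled, with the count logged on the
    returned set. ``kfold=True`` switches to disjoint folds
    (``round(1 / (1 - fraction_train))`` of them) instead of repeated
    sub-sampling; ``stratify_env=True`` makes CV2 sample the test fraction
    within each environment.
    """
    if not (0 < fraction_train < 1):
        raise ValueError("fraction_train must be in (0, 1)")
    rng = np.random.default_rng(seed)
    N, n = T.n_records, T.n_lines
    all_idx = np.arange(N)
    n_resampled = 0
    parts = []

    if kfold:
        k = int(round(1.0 / (1.0 - fraction_train)))
        for attempt in range(max_resample + 1):
            units = rng.permutation(n if scheme == "CV1" else N)
            folds = np.array_split(units, k)
            cand = []
            for fold in folds:
                if scheme == "CV1":
                    test = all_idx[np.isin(T.line_index, fold)]
                else:
                    test = np.sort(fold)
                train = np.setdiff1d(all_idx, test)
                cand.append((train, test))
            if all(_valid_partition(T, te) for _, te in cand):
                parts = cand
                break
            n_resampled += 1
        else:
            raise ValueError(
                "k-fold assignment cannot keep >= 2 test records per environment"
            )
        return PartitionSet(scheme, parts, len(parts), fraction_train, seed, n_resampled)

    if scheme == "CV1":
        n_test_lines = int(round((1.0 - fraction_train) * n))
        if n_test_lines < 1 or n_test_lines >= n:
            raise ValueError("too few lines for the requested split")
    else:
        n_test_rec = int(round((1.0 - fraction_train) * N))
        if n_test_rec < T.n_envs * 2 and not stratify_env:
            if n_test_rec < 1:
                raise ValueError("too few records for the requested split")

    for _ in range(n_partitions):
        for attempt in range(max_resample + 1):
            if scheme == "CV1":
                test_lines = rng.choice(n, size=n_test_lines, replace=False)
                test = all_idx[np.isin(T.line_index, test_lines)]
            elif stratify_env:
                chunks = []
                for j in range(T.n_envs):
                    env_idx = all_idx[T.env_index == j]
                    k = max(int(round((1.0 - fraction_train) * env_idx.size)), 1)
                    chunks.append(rng.choice(env_idx, size=k, replace=False))
                test = np.sort(np.concatenate(chunks))
            else:
                test = np.sort(rng.choice(N, size=n_test_rec, replace=False))
            if _valid_partition(T, test):
                break
            n_resampled += 1
        else:
            raise ValueError(
                "could not draw a partition with >= 2 test records per environment"
            )
        train = np.setdiff1d(all_idx, test)
        parts.append((train, np.asarray(test, dtype=int)))

    return PartitionSet(scheme, parts, n_partitions, fraction_train, seed, n_resampled)


def pearson_by_env(T: TrialData, predictions: np.ndarray, test: np.ndarray) -> dict:
    """Pearson r between observed and predicted test phenotypes, per environment.

    Environments with fewer than two test records, or with zero variance in
    either vector, yield None (skipped upstream with a logged count).
    """
    out = {}
    y = T.y
    for j, env in enumerate(T.env_ids):
        sel = test[T.env_index[test] == j]
        if sel.size < 2:
            out[env] = None
            continue
        yo, yp = y[sel], predictions[sel]
        if np.std(yo) == 0 or np.std(yp) == 0:
            out[env] = None
            continue
        out[env] = float(np.corrcoef(yo, yp)[0, 1])
    return out


@dataclass
class AccuracyTable:
    """Per-(model, environment) mean and SD of Pearson r over partitions."""

    mean: pd.DataFrame   # rows environments, columns model labels
    sd: pd.DataFrame
    n_partitions: int
    scheme: str
    skipped: dict = field(default_factory=dict)  # (model, env) -> partitions skipped

    def formatted(self, digits: int = 3) -> pd.DataFrame:
        out = self.mean.copy().astype(object)
        for env in self.mean.index:
            for mod in self.mean.columns:
                mval, sval = self.mean.loc[env, mod], self.sd.loc[env, mod]
                out.loc[env, mod] = f"{mval:.{digits}f} ({sval:.{digits}f})"
        return out

    def to_csv(self, path, digits: int = 3) -> None:
        df = self.formatted(digits)
        df.index.name = "environment"
        df.to_csv(path)


def _muc_mask_cells(T: TrialData, test: np.ndarray) -> list:
    df = T.df
    return [(df.iloc[i]["line"], df.iloc[i]["env"]) for i in test]


def evaluate(
    T: TrialData,
    specs,
    kernels: dict,
    partitions: PartitionSet,
    cfg: McmcConfig = None,
    muc_cfg: McmcConfig = None,
    priors=None,
) -> AccuracyTable:
    """Fit each model on each partition's training set and score the test set.

    All models share the same partitions (identical masks), making the
    per-environment accuracies directly comparable. For Hadamard-family
    models the covariance rotations are prepared once and reused across
    partitions (masking does not change the covariance patterns).

    Parameters
    ----------
    T : TrialData
    specs : list of ModelSpec
    kernels : dict
        ``{"GB": KernelMatrix, "GK": KernelMatrix}`` (only the methods used
        by ``specs`` are required).
    partitions : PartitionSet
    cfg, muc_cfg : McmcConfig
        Chain settings for the Hadamard and Kronecker engines; ``muc_cfg``
        falls back to ``cfg``.
    """
    cfg = cfg or McmcConfig()
    muc_cfg = muc_cfg or cfg
    specs = [s if isinstance(s, ModelSpec) else ModelSpec(*s) for s in specs]
    env_ids = list(T.env_ids)
    labels = [s.label for s in specs]
    acc = {lab: {e: [] for e in env_ids} for lab in labels}
    skipped = {}
    W = to_wide(T)
    lpos = {s: i for i, s in enumerate(W.line_ids)}
    epos = {s: j for j, s in enumerate(W.env_ids)}
    rec_cell = np.array(
        [[lpos[r.line], epos[r.env]] for r in T.df.itertuples()], dtype=int
    )

    for spec in specs:
        if spec.kernel_method not in kernels:
            raise KeyError(f"no kernel provided for method {spec.kernel_method!r}")
        K = kernels[spec.kernel_method]
        if spec.name in HADAMARD_MODELS:
            ctx = prepare(T, spec, K)
            for p, (train, test) in enumerate(partitions.partitions):
                run_cfg = McmcConfig(cfg.n_iter, cfg.burn_in, cfg.thin, cfg.seed + p)
                res = fit(T, spec, K, priors=priors, cfg=run_cfg, mask=test, _ctx=ctx)
                r_env = pearson_by_env(T, res.predictions, np.asarray(test))
                for e, r in r_env.items():
                    if r is None:
                        skipped[(spec.label, e)] = skipped.get((spec.label, e), 0) + 1
                    else:
                        acc[spec.label][e].append(r)
        else:
            Keig = K.subset(W.line_ids).eigen()
            for p, (train, test) in enumerate(partitions.partitions):
                mask_bool = np.zeros(W.Y.shape, dtype=bool)
                mask_bool[rec_cell[test, 0], rec_cell[test, 1]] = True
                run_cfg = McmcConfig(muc_cfg.n_iter, muc_cfg.burn_in, muc_cfg.thin, muc_cfg.seed + p)
                res = fit_muc(
                    W, K, with_f=(spec.name == "MUCf"), cfg=run_cfg,
                    mask=mask_bool, _eig=Keig,
                )
                preds = res.predictions[rec_cell[:, 0], rec_cell[:, 1]]
                r_env = pearson_by_env(T, preds, np.asarray(test))
                for e, r in r_env.items():
                    if r is None:
                        skipped[(spec.label, e)] = skipped.get((spec.label, e), 0) + 1
                    else:
                        acc[spec.label][e].append(r)

    mean = pd.DataFrame(index=env_ids, columns=labels, dtype=float)
    sd = pd.DataFrame(index=env_ids, columns=labels, dtype=float)
    for lab in labels:
        for e in env_ids:
            vals = acc[lab][e]
            mean.loc[e, lab] = float(np.mean(vals)) if vals else np.nan
            sd.loc[e, lab] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return AccuracyTable(
        mean=mean, sd=sd, n_partitions=partitions.n_partitions,
        scheme=partitions.scheme, skipped=skipped,
    )
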