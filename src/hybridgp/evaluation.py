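"""Cross-validation schemes and predictive metrics.

Two evaluation designs are provided:

* repeated k-fold over genotypes for single-environment models (5-fold
  repeated 4 times, or 2-fold repeated 10 times — 20 training/testing
  splits either way);
* environment-masking for multi-environment models: a fraction of one
  target environment's records (20% or 5%) is kept observed, the rest
  of that environment is masked and predicted while all other
  environments stay fully observed; repeated with fresh random subsets.

Accuracy is the Pearson correlation between predictions and held-out
values, complemented by the predictive mean squared error (PMSE).
Aggregates report the mean correlation (AVG), its standard error
(SE = sd over folds / sqrt(#folds)), and percent differences against a
baseline model.  Fold assignments depend only on the scheme and its
seed, never on the model, so model comparisons are paired.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from hybridgp.gp_multi import MultiEnvModelSpec, fit_multi_env
from hybridgp.gp_single import SingleEnvModelSpec, fit_single_env
from hybridgp.phenotypes import PhenotypeTable
from hybridgp.relation_kernels import RelationshipKernel

__all__ = [
    "CVScheme",
    "CVResult",
    "make_kfold_scheme",
    "make_env_mask_scheme",
    "pearson",
    "pmse",
    "summarize_cv",
    "run_experiment",
]


@dataclass(frozen=True)
class CVScheme:
    """Cross-validation design.

    ``kind='kfold'`` uses ``k`` and ``repeats``; ``kind='env_mask'``
    uses ``target_env``, ``known_fraction`` (0.20 or 0.05 in the
    standard scenarios) and ``repeats``.  ``seed`` fixes the random
    fold/mask assignments.
    """

    kind: str
    k: int = 5
    repeats: int = 1
    known_fraction: float = 0.2
    target_env: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("kfold", "env_mask"):
            raise ValueError(f"unknown scheme kind {self.kind!r}")
        if self.kind == "kfold" and self.k < 2:
            raise ValueError("k must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if not 0 < self.known_fraction < 1:
            raise ValueError("known_fraction must lie in (0, 1)")


@dataclass
class CVResult:
    """Per-fold records of a CV experiment (one row per model x fold)."""

    records: pd.DataFrame
    scheme: CVScheme

    def for_model(self, model: str) -> pd.DataFrame:
        return self.records[self.records["model"] == model].reset_index(drop=True)


def make_kfold_scheme(
    n: int, k: int, repeats: int, seed: int
) -> list[list[np.ndarray]]:
    """Random k-fold partitions, one list of k test-index arrays per replicate.

    Fold sizes differ by at most one (remainders spread one per fold);
    within a replicate the test sets are disjoint and cover ``range(n)``.
    """
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    rng = np.random.default_rng(seed)
    out: list[list[np.ndarray]] = []
    for _ in range(repeats):
        perm = rng.permutation(n)
        out.append([np.sort(part) for part in np.array_split(perm, k)])
    return out


def make_env_mask_scheme(
    phenotypes: PhenotypeTable,
    target_env: str,
    known_fraction: float,
    repeats: int,
    seed: int,
) -> list[list[tuple[str, str]]]:
    """Masked-cell sets for the environment-masking scenarios.

    Per replicate, ``round(known_fraction * n_env)`` of the target
    environment's records stay observed and the remaining cells are
    returned as the masked (genotype, environment) test set.
    """
    target_env = str(target_env)
    env_df = phenotypes.df[phenotypes.df["environment"] == target_env]
    n_env = len(env_df)
    if n_env == 0:
        raise KeyError(f"environment {target_env!r} not present")
    n_known = int(round(known_fraction * n_env))
    if n_known < 1:
        raise ValueError("known_fraction leaves no observed records")
    genos = env_df["genotype"].to_numpy()
    rng = np.random.default_rng(seed)
    out: list[list[tuple[str, str]]] = []
    for _ in range(repeats):
        keep = rng.choice(n_env, size=n_known, replace=False)
        masked = np.setdiff1d(np.arange(n_env), keep)
        out.append([(genos[i], target_env) for i in masked])
    return out


def pearson(pred, obs) -> float:
    """Sample Pearson correlation; NaN when either input is constant."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError("pred and obs lengths differ")
    if pred.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(pred) == 0 or np.std(obs) == 0:
        return float("nan")
    return float(np.corrcoef(pred, obs)[0, 1])


def pmse(pred, obs) -> float:
    """Predictive mean squared error: mean of (pred - obs)^2."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError("pred and obs lengths differ")
    return float(np.mean((pred - obs) ** 2))


def summarize_cv(result: CVResult, baseline_model: str | None = None) -> pd.DataFrame:
    """Aggregate per-fold records into AVG/SE tables.

    AVG is the mean of per-fold Pearson correlations (raw, no Fisher-z),
    SE is their sd over folds divided by sqrt(#folds), and the 95%
    interval is AVG +/- 1.96 SE.  With ``baseline_model`` a percent
    difference column ``100 (AVG - AVG_base) / AVG_base`` is added.
    """
    rec = result.records
    grouped = rec.groupby(["model", "environment"], as_index=False).agg(
        avg_pearson=("pearson", "mean"),
        sd_pearson=("pearson", lambda x: x.std(ddof=1)),
        n_folds=("pearson", "size"),
        avg_pmse=("pmse", "mean"),
        sd_pmse=("pmse", lambda x: x.std(ddof=1)),
    )
    if (grouped["n_folds"] < 2).any():
        raise ValueError("need >= 2 replicate records per (model, environment)")
    grouped["se_pearson"] = grouped["sd_pearson"] / np.sqrt(grouped["n_folds"])
    grouped["ci_low"] = grouped["avg_pearson"] - 1.96 * grouped["se_pearson"]
    grouped["ci_high"] = grouped["avg_pearson"] + 1.96 * grouped["se_pearson"]
    if baseline_model is not None:
        base = grouped[grouped["model"] == baseline_model][
            ["environment", "avg_pearson"]
        ].rename(columns={"avg_pearson": "avg_baseline"})
        if base.empty:
            raise ValueError(f"baseline model {baseline_model!r} absent from results")
        grouped = grouped.merge(base, on="environment", how="left")
        if grouped["avg_baseline"].isna().any():
            raise ValueError("baseline missing for some environment")
        grouped["pct_diff_vs_baseline"] = (
            100.0
            * (grouped["avg_pearson"] - grouped["avg_baseline"])
            / grouped["avg_baseline"]
        )
    return grouped


def _derive_seed(base: int, *parts: int) -> int:
    s = int(base)
    for p in parts:
        s = (s * 1_000_003 + int(p) + 1) % (2**31 - 1)
    return s


def run_experiment(
    phenotypes: PhenotypeTable,
    kernels: dict[str, RelationshipKernel],
    models: dict[str, SingleEnvModelSpec | MultiEnvModelSpec],
    scheme: CVScheme,
) -> CVResult:
    """Run a paired CV experiment over several models.

    ``kernels`` maps kernel kind (A/G/K/C/P) to an aligned, validated
    kernel; each model's ``kernel_set`` selects its subset.  Fold/mask
    assignments are generated once from the scheme seed and reused for
    every model, making per-fold model comparisons paired.  MCMC seeds
    are derived deterministically from (scheme seed, replicate, fold,
    model), so the whole experiment is reproducible bit-for-bit.
    """
    if scheme.kind == "kfold":
        return _run_kfold(phenotypes, kernels, models, scheme)
    return _run_env_mask(phenotypes, kernels, models, scheme)


def _select(kernels: dict[str, RelationshipKernel], kernel_set) -> list:
    missing = [k for k in kernel_set if k not in kernels]
    if missing:
        raise KeyError(f"kernels missing for kinds {missing}")
    return [kernels[k] for k in kernel_set]


def _run_kfold(phenotypes, kernels, models, scheme) -> CVResult:
    if phenotypes.n_environments != 1:
        raise ValueError("kfold scheme expects single-environment phenotypes")
    env = phenotypes.environment_ids[0]
    first = next(iter(kernels.values()))
    ids = first.ids
    for k in kernels.values():
        if k.ids != ids:
            raise ValueError("kernels are not mutually aligned")
    y = phenotypes.single_env_vector(ids)
    observed_idx = np.where(~np.isnan(y))[0]
    folds = make_kfold_scheme(len(observed_idx), scheme.k, scheme.repeats, scheme.seed)
    rows = []
    for rep, rep_folds in enumerate(folds):
        for fold, test_local in enumerate(rep_folds):
            test_idx = observed_idx[test_local]
            y_train = y.copy()
            y_train[test_idx] = np.nan
            for mi, (mname, mspec) in enumerate(models.items()):
                seed = _derive_seed(scheme.seed, rep, fold, mi)
                spec = _reseed_single(mspec, seed)
                fit = fit_single_env(y_train, _select(kernels, spec.kernel_set), spec)
                pred = fit.yhat[test_idx]
                rows.append(
                    {
                        "model": mname,
                        "environment": env,
                        "replicate": rep,
                        "fold": fold,
                        "n_test": len(test_idx),
                        "test_ids": ",".join(ids[i] for i in test_idx),
                        "pearson": pearson(pred, y[test_idx]),
                        "pmse": pmse(pred, y[test_idx]),
                    }
                )
    return CVResult(records=pd.DataFrame(rows), scheme=scheme)


def _run_env_mask(phenotypes, kernels, models, scheme) -> CVResult:
    if scheme.target_env is None:
        raise ValueError("env_mask scheme needs a target_env")
    masks = make_env_mask_scheme(
        phenotypes, scheme.target_env, scheme.known_fraction, scheme.repeats, scheme.seed
    )
    truth = {
        (g, e): v
        for g, e, v in zip(
            phenotypes.df["genotype"], phenotypes.df["environment"], phenotypes.df["value"]
        )
    }
    rows = []
    for rep, masked_cells in enumerate(masks):
        ph_masked = phenotypes.mask_cells(masked_cells)
        obs_cells = [c for c in masked_cells if np.isfinite(truth[c])]
        for mi, (mname, mspec) in enumerate(models.items()):
            seed = _derive_seed(scheme.seed, rep, 0, mi)
            spec = _reseed_multi(mspec, seed)
            fit = fit_multi_env(ph_masked, _select(kernels, spec.kernel_set), spec)
            pred = fit.predict(obs_cells)
            obs = np.array([truth[c] for c in obs_cells])
            rows.append(
                {
                    "model": mname,
                    "environment": str(scheme.target_env),
                    "replicate": rep,
                    "fold": 0,
                    "n_test": len(obs_cells),
                    "test_ids": ",".join(g for g, _ in obs_cells[:50]),
                    "pearson": pearson(pred, obs),
                    "pmse": pmse(pred, obs),
                }
            )
    return CVResult(records=pd.DataFrame(rows), scheme=scheme)


def _reseed_single(spec: SingleEnvModelSpec, seed: int) -> SingleEnvModelSpec:
    from dataclasses import replace

    return replace(spec, mcmc=replace(spec.mcmc, seed=seed))


def _reseed_multi(spec: MultiEnvModelSpec, seed: int) -> MultiEnvModelSpec:
    from dataclasses import replace

    return replace(spec, mcmc=replace(spec.mcmc, seed=seed))
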