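"""Multi-environment genotype-by-environment models (M1-M5).

Each single-environment kernel set has a multi-environment counterpart in
which the genetic effects acquire an environment dimension:

* balanced data (every genotype observed in every environment): effects
  for kernel ``K_k`` are matrix-normal with covariance ``U_k (x) K_k``
  (Kronecker product), ``U_k`` an unstructured m x m environment
  covariance estimated from the data, residuals ``R (x) I`` with an
  unstructured m x m residual covariance R — the multi-trait
  formulation, fitted by a multi-trait Gibbs sampler with
  inverse-Wishart updates.
* unbalanced data: effects carry a single variance and covariance
  ``sigma2_k (Z1 K_k Z1') o (Z2 E Z2')`` (Hadamard product), with ``Z1``
  and ``Z2`` the record-to-genotype and record-to-environment incidence
  matrices and ``E`` a known or estimated environment covariance; the
  residual is homogeneous.  Under complete balanced incidence with
  ``E = U`` the Hadamard form reproduces the Kronecker covariance up to
  record ordering.

Records are always ordered by (environment, genotype); masked cells are
imputed by data augmentation in both modes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from hybridgp._mcmc import (
    MCMCSettings,
    draw_scaled_inv_chi2,
    slice_sample_1d,
    effective_sample_size,
    mcse,
    scaled_inv_chi2_scale,
    split_rhat,
    truncated_eigh,
)
from hybridgp.phenotypes import PhenotypeTable
from hybridgp.relation_kernels import RelationshipKernel, align_kernels, validate_kernel

__all__ = [
    "MULTI_ENV_MODELS",
    "MultiEnvModelSpec",
    "MultiEnvFit",
    "detect_balance",
    "build_hadamard_covariance",
    "estimate_E",
    "fit_multi_env",
]

MULTI_ENV_MODELS: dict[str, tuple[str, ...]] = {
    "M1": ("A",),
    "M2": ("G",),
    "M3": ("K",),
    "M4": ("A", "K"),
    "M5": ("A", "K", "C", "P"),
}


@dataclass(frozen=True)
class MultiEnvModelSpec:
    """Kernel set, covariance mode, priors and MCMC settings.

    ``mode='auto'`` selects the balanced Kronecker formulation iff every
    genotype appears in every environment, otherwise the Hadamard
    formulation.  ``env_cov_E`` optionally supplies the environment
    covariance for the Hadamard mode as a DataFrame indexed by
    environment id; when absent it is estimated from the observed
    phenotypes (pairwise correlations shrunk toward compound symmetry,
    see :func:`estimate_E`).
    """

    kernel_set: tuple[str, ...]
    mode: str = "auto"
    env_cov_E: pd.DataFrame | None = None
    prior_df: float = 5.0
    prior_R2: float = 0.5
    e_shrink: float = 0.5
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)

    def __post_init__(self) -> None:
        if not self.kernel_set:
            raise ValueError("kernel_set must be non-empty")
        if self.mode not in ("balanced_kron", "unbalanced_hadamard", "auto"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0 < self.prior_R2 < 1:
            raise ValueError("prior_R2 must lie in (0, 1)")

    @classmethod
    def from_name(cls, name: str, **kwargs) -> "MultiEnvModelSpec":
        if name not in MULTI_ENV_MODELS:
            raise ValueError(f"unknown multi-environment model {name!r}")
        return cls(kernel_set=MULTI_ENV_MODELS[name], **kwargs)


@dataclass
class MultiEnvFit:
    """Posterior summaries of a multi-environment fit.

    Balanced mode stores per-kernel environment covariances ``U_k`` and
    the residual covariance ``R`` (posterior means with elementwise
    sds); unbalanced mode stores scalar variance components.  ``yhat``
    is a tidy table of posterior-mean predictions for every modelled
    (genotype, environment) cell, masked cells included.
    """

    mode: str
    ids: list[str]
    env_ids: list[str]
    kernel_kinds: list[str]
    mu_posterior: dict[str, tuple[float, float]]
    U_posterior: dict[str, tuple[np.ndarray, np.ndarray]] | None
    R_posterior: tuple[np.ndarray, np.ndarray] | None
    varcomp_posterior: dict[str, tuple[float, float]] | None
    yhat: pd.DataFrame
    chains: dict[str, np.ndarray]
    diagnostics: dict[str, dict[str, float]] = field(default_factory=dict)

    def predict(self, cells) -> np.ndarray:
        """Posterior-mean predictions for (genotype, environment) pairs."""
        lookup = {
            (g, e): v
            for g, e, v in zip(
                self.yhat["genotype"], self.yhat["environment"], self.yhat["yhat"]
            )
        }
        try:
            return np.array([lookup[(str(g), str(e))] for g, e in cells])
        except KeyError as exc:
            raise KeyError(f"cell {exc.args[0]!r} not modelled") from exc

    def mcse_of(self, name: str) -> float:
        return mcse(self.chains[name])


def detect_balance(phenotypes: PhenotypeTable):
    """Classify the genotype-by-environment incidence as balanced or not.

    Returns ``(label, summary)`` where summary carries per-environment
    counts and the pairwise genotype-overlap matrix.
    """
    envs = phenotypes.environment_ids
    if len(envs) < 2:
        raise ValueError("need >= 2 environments (use the single-environment model)")
    sets = {
        e: set(phenotypes.df.loc[phenotypes.df["environment"] == e, "genotype"])
        for e in envs
    }
    all_geno = phenotypes.genotype_ids
    balanced = all(len(sets[e]) == len(all_geno) for e in envs)
    overlap = pd.DataFrame(
        [[len(sets[a] & sets[b]) for b in envs] for a in envs],
        index=envs,
        columns=envs,
    )
    summary = {
        "n_genotypes": len(all_geno),
        "per_env_counts": {e: len(sets[e]) for e in envs},
        "overlap": overlap,
    }
    return ("balanced" if balanced else "unbalanced"), summary


def _record_indices(phenotypes: PhenotypeTable, ids: list[str], envs: list[str]):
    gpos = {g: i for i, g in enumerate(ids)}
    epos = {e: j for j, e in enumerate(envs)}
    gidx = phenotypes.df["genotype"].map(gpos).to_numpy()
    eidx = phenotypes.df["environment"].map(epos).to_numpy()
    return gidx.astype(int), eidx.astype(int)


def build_hadamard_covariance(
    kernel: RelationshipKernel,
    phenotypes: PhenotypeTable,
    E: pd.DataFrame,
) -> np.ndarray:
    """Record-level covariance ``(Z1 K Z1') o (Z2 E Z2')``.

    ``Z1`` and ``Z2`` map phenotype records (ordered by environment,
    then genotype) to genotypes and environments.  Being a Hadamard
    product of two PSD matrices, the result is PSD whenever K and E
    are.  Under complete balanced incidence with ``E = U`` it equals
    the Kronecker covariance ``U (x) K``.
    """
    envs = phenotypes.environment_ids
    missing = [e for e in envs if e not in E.index or e not in E.columns]
    if missing:
        raise KeyError(f"environments absent from E: {missing}")
    Emat = E.loc[envs, envs].to_numpy(dtype=float)
    gidx, eidx = _record_indices(phenotypes, kernel.ids, envs)
    return kernel.matrix[np.ix_(gidx, gidx)] * Emat[np.ix_(eidx, eidx)]


def estimate_E(phenotypes: PhenotypeTable, shrink: float = 0.5) -> pd.DataFrame:
    """Estimate the environment covariance E from phenotype overlap.

    Pairwise Pearson correlations over genotypes shared by each pair of
    environments, shrunk toward compound symmetry:
    ``E = (1-shrink) Ehat + shrink (rbar J + (1-rbar) I)``.  Pairs with
    fewer than 3 shared observed genotypes get the mean off-diagonal
    correlation (with a warning).  The result is PSD-repaired by
    eigenvalue clipping if needed.
    """
    if not 0 <= shrink <= 1:
        raise ValueError("shrink must lie in [0, 1]")
    envs = phenotypes.environment_ids
    m = len(envs)
    if m < 2:
        raise ValueError("need >= 2 environments to estimate E")
    df = phenotypes.df.dropna(subset=["value"])
    wide = df.pivot(index="genotype", columns="environment", values="value")
    Ehat = np.eye(m)
    weak: list[tuple[int, int]] = []
    offdiag: list[float] = []
    for a in range(m):
        for b in range(a + 1, m):
            pair = wide[[envs[a], envs[b]]].dropna()
            if len(pair) < 3:
                weak.append((a, b))
                continue
            va, vb = pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy()
            if np.std(va) == 0 or np.std(vb) == 0:
                weak.append((a, b))
                continue
            r = float(np.corrcoef(va, vb)[0, 1])
            Ehat[a, b] = Ehat[b, a] = r
            offdiag.append(r)
    fill = float(np.mean(offdiag)) if offdiag else 0.0
    if weak:
        warnings.warn(
            f"{len(weak)} environment pair(s) with insufficient overlap; "
            "using the mean off-diagonal correlation",
            stacklevel=2,
        )
        for a, b in weak:
            Ehat[a, b] = Ehat[b, a] = fill
    rbar = fill
    cs = rbar * np.ones((m, m)) + (1.0 - rbar) * np.eye(m)
    E = (1.0 - shrink) * Ehat + shrink * cs
    kern = RelationshipKernel(ids=envs, matrix=E, kind="custom")
    repaired, report = validate_kernel(kern, repair="eigen_clip")
    if report.repaired:
        warnings.warn("estimated E was indefinite; eigenvalue-clipped", stacklevel=2)
        E = repaired.matrix
    return pd.DataFrame(E, index=envs, columns=envs)


# ---------------------------------------------------------------------------
# fitting


def _kernel_kinds(kernels: list[RelationshipKernel]) -> list[str]:
    kinds, seen = [], {}
    for k in kernels:
        kind = k.kind
        if kind in seen:
            seen[kind] += 1
            kind = f"{kind}{seen[kind]}"
        else:
            seen[kind] = 1
        kinds.append(kind)
    return kinds


def fit_multi_env(
    phenotypes: PhenotypeTable,
    kernels: list[RelationshipKernel],
    spec: MultiEnvModelSpec,
) -> MultiEnvFit:
    """Fit a multi-environment G-by-E model by Gibbs sampling.

    Kernels and phenotypes are aligned internally (exact id match).
    NaN phenotype values are masked cells to be predicted; rows absent
    from the table are cells that are neither observed nor predicted.
    """
    if len(kernels) != len(spec.kernel_set):
        raise ValueError(
            f"spec lists {len(spec.kernel_set)} kernels but {len(kernels)} given"
        )
    kernels, phenotypes = align_kernels(kernels, phenotypes)
    envs = phenotypes.environment_ids
    if len(envs) < 2 and spec.mode == "auto":
        raise ValueError("single environment data: use fit_single_env")
    if len(envs) >= 2:
        balance, _ = detect_balance(phenotypes)
    else:
        balance = "balanced"
    mode = spec.mode
    if mode == "auto":
        mode = "balanced_kron" if balance == "balanced" else "unbalanced_hadamard"
    if mode == "balanced_kron" and balance == "unbalanced":
        raise ValueError("balanced_kron mode forced on unbalanced incidence")
    if mode == "balanced_kron":
        return _fit_balanced(phenotypes, kernels, spec)
    return _fit_unbalanced(phenotypes, kernels, spec)


def _fit_balanced(
    phenotypes: PhenotypeTable,
    kernels: list[RelationshipKernel],
    spec: MultiEnvModelSpec,
) -> MultiEnvFit:
    """Multi-trait sampler: environments as traits, U_k (x) K_k covariances."""
    ids = kernels[0].ids
    envs = phenotypes.environment_ids
    n, m = len(ids), len(envs)
    kinds = _kernel_kinds(kernels)
    nk = len(kernels)
    wide = phenotypes.df.pivot(index="genotype", columns="environment", values="value")
    Y = wide.loc[ids, envs].to_numpy(dtype=float)
    obs = ~np.isnan(Y)
    if obs.sum() < 2:
        raise ValueError("need at least 2 observed phenotypes")

    eigs = [truncated_eigh(k.matrix) for k in kernels]
    var_env = np.array(
        [np.nanvar(Y[:, j], ddof=1) if obs[:, j].sum() > 1 else 1.0 for j in range(m)]
    )
    var_env = np.where(var_env > 0, var_env, 1e-6)

    # inverse-Wishart priors: df = m + 4 with the scale set so the prior
    # MODE of each U_k is prior_R2 * diag(var_env) / n_kernels (IW mode =
    # S/(df+m+1)).  At m = 1 this is identical to the single-environment
    # scaled-inverse-chi-square prior (df 5, mode-matched), so the
    # multi-trait machinery reduces exactly to the single-environment
    # model, prior included.
    df_U = m + 4.0
    S_U = (spec.prior_R2 * np.diag(var_env) / nk) * (df_U + m + 1.0)
    df_R = m + 4.0
    S_R = (1.0 - spec.prior_R2) * np.diag(var_env) * (df_R + m + 1.0)

    rng = np.random.default_rng(spec.mcmc.seed)
    mu = np.nanmean(np.where(obs, Y, np.nan), axis=0)
    mu = np.where(np.isnan(mu), 0.0, mu)
    U = [spec.prior_R2 * np.diag(var_env) / nk for _ in range(nk)]
    R = (1.0 - spec.prior_R2) * np.diag(var_env)
    G = [np.zeros((n, m)) for _ in range(nk)]
    total = np.zeros((n, m))
    Y_full = Y.copy()
    Y_full[~obs] = np.broadcast_to(mu, (n, m))[~obs]

    # group genotypes by missingness pattern for vectorized augmentation
    patterns: dict[tuple[bool, ...], np.ndarray] = {}
    for i in range(n):
        key = tuple(obs[i])
        patterns.setdefault(key, []).append(i)  # type: ignore[arg-type]
    patterns = {k: np.array(v) for k, v in patterns.items() if not all(k)}

    n_samples = spec.mcmc.n_samples
    chains: dict[str, np.ndarray] = {}
    for j, e in enumerate(envs):
        chains[f"mu_{e}"] = np.empty(n_samples)
    for kind in kinds:
        for j, e in enumerate(envs):
            chains[f"U_{kind}_{e}_{e}"] = np.empty(n_samples)
    for j, e in enumerate(envs):
        chains[f"R_{e}_{e}"] = np.empty(n_samples)
    U_sum = [np.zeros((m, m)) for _ in range(nk)]
    U_sq = [np.zeros((m, m)) for _ in range(nk)]
    R_sum = np.zeros((m, m))
    R_sq = np.zeros((m, m))
    # Rao-Blackwellized effect means (conditional means instead of draws)
    G_rb = [np.zeros((n, m)) for _ in range(nk)]
    yhat_sum = np.zeros((n, m))
    s = 0

    eye_m = np.eye(m)
    ones_rot = [eigs[k][1].T @ np.ones(n) for k in range(nk)]
    for it in range(spec.mcmc.n_iter):
        Rinv = np.linalg.inv(R)
        Ls = np.linalg.cholesky(Rinv)
        for k in range(nk):
            # Joint block update of (W_k, mu): the per-environment
            # intercepts are integrated out of the effect draw (rank-m
            # Woodbury correction through the residual covariance) and
            # redrawn afterwards; see gp_single for why one-at-a-time
            # updates mix too slowly here.
            lam, Q, rank = eigs[k]
            q1 = ones_rot[k]
            Resid = Y_full - (total - G[k])
            T = Q.T @ Resid  # rank x m
            s_col = Resid.sum(axis=0)  # m
            Uinv = np.linalg.inv(U[k])
            P = Rinv[None, :, :] + Uinv[None, :, :] / lam[:, None, None]
            L = np.linalg.cholesky(P)
            Btil = (T - np.outer(q1, s_col / n)) @ Rinv  # rank x m
            mean0 = np.linalg.solve(P, Btil[:, :, None])[:, :, 0]
            # S_i = P_i^{-1} Ls, batched; correction M = (I - F'D^{-1}F)^{-1}
            S_blk = np.linalg.solve(P, np.broadcast_to(Ls, (rank, m, m)))
            G1 = np.einsum("i,mj,imk->jk", q1**2, Ls, S_blk) / n
            Mcorr = np.linalg.inv(eye_m - G1)
            Lm = np.linalg.cholesky((Mcorr + Mcorr.T) / 2.0)
            fb = np.einsum("i,mj,im->j", q1, Ls, mean0) / np.sqrt(n)
            corr_vec = Mcorr @ fb
            mean = mean0 + np.einsum("i,imj,j->im", q1, S_blk, corr_vec) / np.sqrt(n)
            z = rng.standard_normal((rank, m))
            noise = np.linalg.solve(np.transpose(L, (0, 2, 1)), z[:, :, None])[:, :, 0]
            z2 = Lm @ rng.standard_normal(m)
            noise += np.einsum("i,imj,j->im", q1, S_blk, z2) / np.sqrt(n)
            W = mean + noise
            G_rb[k] = Q @ mean
            G_new = Q @ W
            total += G_new - G[k]
            G[k] = G_new
            # mu | W_k, rest ~ N((colsum(Resid) - W'q)/n, R/n)
            Lr = np.linalg.cholesky(R / n)
            mu = (s_col - W.T @ q1) / n + Lr @ rng.standard_normal(m)
            # U_k | W ~ IW(df + rank, S + W' diag(1/lam) W)
            SW = (W / lam[:, None]).T @ W
            U[k] = stats.invwishart.rvs(
                df=df_U + rank, scale=S_U + SW, random_state=rng
            ).reshape(m, m)
        # residual covariance
        E = Y_full - mu[None, :] - total
        R = stats.invwishart.rvs(
            df=df_R + n, scale=S_R + E.T @ E, random_state=rng
        ).reshape(m, m)
        # augmentation of masked cells, grouped by missingness pattern
        if patterns:
            F = mu[None, :] + total
            for key, rows in patterns.items():
                o = np.array(key)
                mis = ~o
                if o.any():
                    Roo = R[np.ix_(o, o)]
                    Rmo = R[np.ix_(mis, o)]
                    gain = Rmo @ np.linalg.inv(Roo)
                    cond_cov = R[np.ix_(mis, mis)] - gain @ Rmo.T
                    cond_mean = (
                        F[np.ix_(rows, mis)]
                        + (Y_full[np.ix_(rows, o)] - F[np.ix_(rows, o)]) @ gain.T
                    )
                else:
                    cond_cov = R
                    cond_mean = F[rows]
                cond_cov = (cond_cov + cond_cov.T) / 2.0
                w_c, Q_c = np.linalg.eigh(cond_cov)
                Lc = Q_c * np.sqrt(np.clip(w_c, 0.0, None))
                draw = cond_mean + rng.standard_normal(cond_mean.shape) @ Lc.T
                Y_full[np.ix_(rows, mis)] = draw
        if it >= spec.mcmc.burn_in and (it - spec.mcmc.burn_in) % spec.mcmc.thin == 0:
            for j, e in enumerate(envs):
                chains[f"mu_{e}"][s] = mu[j]
                chains[f"R_{e}_{e}"][s] = R[j, j]
            for k, kind in enumerate(kinds):
                for j, e in enumerate(envs):
                    chains[f"U_{kind}_{e}_{e}"][s] = U[k][j, j]
                U_sum[k] += U[k]
                U_sq[k] += U[k] ** 2
            R_sum += R
            R_sq += R**2
            yhat_sum += mu[None, :] + sum(G_rb)
            s += 1

    U_post = {}
    for k, kind in enumerate(kinds):
        mean_U = U_sum[k] / n_samples
        sd_U = np.sqrt(np.maximum(U_sq[k] / n_samples - mean_U**2, 0.0))
        U_post[kind] = (mean_U, sd_U)
    mean_R = R_sum / n_samples
    sd_R = np.sqrt(np.maximum(R_sq / n_samples - mean_R**2, 0.0))
    yhat_mean = yhat_sum / n_samples
    yhat_df = pd.DataFrame(
        {
            "genotype": np.repeat(ids, m),
            "environment": np.tile(envs, n),
            "yhat": yhat_mean.ravel(),
        }
    )
    mu_post = {
        e: (float(chains[f"mu_{e}"].mean()), float(chains[f"mu_{e}"].std(ddof=1)))
        for e in envs
    }
    diagnostics = {
        name: {
            "ess": effective_sample_size(chain),
            "rhat": split_rhat(chain),
            "mcse": mcse(chain),
        }
        for name, chain in chains.items()
    }
    return MultiEnvFit(
        mode="balanced_kron",
        ids=list(ids),
        env_ids=envs,
        kernel_kinds=kinds,
        mu_posterior=mu_post,
        U_posterior=U_post,
        R_posterior=(mean_R, sd_R),
        varcomp_posterior=None,
        yhat=yhat_df,
        chains=chains,
        diagnostics=diagnostics,
    )


def _fit_unbalanced(
    phenotypes: PhenotypeTable,
    kernels: list[RelationshipKernel],
    spec: MultiEnvModelSpec,
) -> MultiEnvFit:
    """Hadamard-covariance sampler over phenotype records."""
    ids = kernels[0].ids
    envs = phenotypes.environment_ids
    kinds = _kernel_kinds(kernels)
    nk = len(kernels)
    df = phenotypes.df
    y = df["value"].to_numpy(dtype=float).copy()
    N = y.size
    obs = ~np.isnan(y)
    if obs.sum() < 2:
        raise ValueError("need at least 2 observed phenotypes")
    gidx, eidx = _record_indices(phenotypes, ids, envs)

    if spec.env_cov_E is not None:
        E = spec.env_cov_E
    else:
        E = estimate_E(phenotypes, shrink=spec.e_shrink)
    omegas = [build_hadamard_covariance(k, phenotypes, E) for k in kernels]
    eigs = [truncated_eigh(om) for om in omegas]

    var_y = float(np.nanvar(y, ddof=1))
    var_y = var_y if var_y > 0 else 1e-6
    df0 = spec.prior_df
    S_g = scaled_inv_chi2_scale(spec.prior_R2 * var_y / nk, df0)
    S_e = scaled_inv_chi2_scale((1.0 - spec.prior_R2) * var_y, df0)

    rng = np.random.default_rng(spec.mcmc.seed)
    mu = np.zeros(len(envs))
    for j in range(len(envs)):
        sel = (eidx == j) & obs
        mu[j] = y[sel].mean() if sel.any() else 0.0
    sig2 = np.full(nk, spec.prior_R2 * var_y / nk)
    sig2_e = (1.0 - spec.prior_R2) * var_y
    f = np.zeros((nk, N))
    total = np.zeros(N)
    y_full = y.copy()
    y_full[~obs] = mu[eidx[~obs]]

    env_counts = np.bincount(eidx, minlength=len(envs)).astype(float)
    n_samples = spec.mcmc.n_samples
    chains: dict[str, np.ndarray] = {}
    for e in envs:
        chains[f"mu_{e}"] = np.empty(n_samples)
    for kind in kinds:
        chains[f"sigma2_{kind}"] = np.empty(n_samples)
    chains["sigma2_eps"] = np.empty(n_samples)
    f_rb = np.zeros((nk, N))
    f_sum = np.zeros((nk, N))
    yhat_sum = np.zeros(N)
    s = 0

    m_env = len(envs)
    Z2 = np.zeros((N, m_env))
    Z2[np.arange(N), eidx] = 1.0
    # Q'Z2 per kernel, for the joint (mu, f_k) block updates
    B_rot = [eigs[k][1].T @ Z2 for k in range(nk)]
    for it in range(spec.mcmc.n_iter):
        for k in range(nk):
            # Joint block update of (f_k, mu): per-environment intercepts
            # are integrated out of the effect's full conditional (rank-m
            # Woodbury correction) and redrawn afterwards; see gp_single
            # for the rationale.
            lam, Q, rank = eigs[k]
            B = B_rot[k]
            r = y_full - (total - f[k])
            t = Q.T @ r
            # slice-sample sigma2_k from its marginal with the effect
            # vector and all intercepts integrated out (see gp_single)
            rr = float(r @ r)
            env_sums = np.bincount(eidx, weights=r, minlength=m_env)
            se = sig2_e

            def logpost(x):
                s2 = np.exp(x)
                denom = s2 * lam + se
                c = s2 * lam / denom
                Zvz = (np.diag(env_counts) - B.T @ (c[:, None] * B)) / se
                Zvr = (env_sums - B.T @ (c * t)) / se
                sol = np.linalg.solve(Zvz, Zvr)
                sign, logdet_z = np.linalg.slogdet(Zvz)
                quad = (rr - t @ (c * t)) / se - float(Zvr @ sol)
                return (
                    -0.5 * float(np.sum(np.log(denom)))
                    - 0.5 * logdet_z
                    - 0.5 * quad
                    - 0.5 * df0 * x
                    - df0 * S_g / (2.0 * s2)
                )

            sig2[k] = float(np.exp(slice_sample_1d(logpost, np.log(sig2[k]), rng)))
            v = 1.0 / (1.0 / sig2_e + 1.0 / (sig2[k] * lam))
            env_means = env_sums / env_counts
            b_tilde = (t - B @ env_means) / sig2_e
            A_tilde = B / (np.sqrt(env_counts)[None, :] * np.sqrt(sig2_e))
            W = v[:, None] * A_tilde
            Mcorr = np.linalg.inv(np.eye(m_env) - A_tilde.T @ W)
            u_mean = v * b_tilde + W @ (Mcorr @ (A_tilde.T @ (v * b_tilde)))
            Lc = np.linalg.cholesky((Mcorr + Mcorr.T) / 2.0)
            u = (
                u_mean
                + np.sqrt(v) * rng.standard_normal(lam.size)
                + W @ (Lc @ rng.standard_normal(m_env))
            )
            f_rb[k] = Q @ u_mean
            f_new = Q @ u
            total += f_new - f[k]
            f[k] = f_new
            res = r - f_new
            means = np.bincount(eidx, weights=res, minlength=m_env) / env_counts
            mu = means + np.sqrt(sig2_e / env_counts) * rng.standard_normal(m_env)
        mu_rec = mu[eidx]
        e = y_full - mu_rec - total
        sig2_e = draw_scaled_inv_chi2(rng, df0 + N, df0 * S_e + float(e @ e))
        n_mis = N - int(obs.sum())
        if n_mis:
            y_full[~obs] = (
                mu_rec[~obs] + total[~obs] + np.sqrt(sig2_e) * rng.standard_normal(n_mis)
            )
        if it >= spec.mcmc.burn_in and (it - spec.mcmc.burn_in) % spec.mcmc.thin == 0:
            for j, env in enumerate(envs):
                chains[f"mu_{env}"][s] = mu[j]
            for k, kind in enumerate(kinds):
                chains[f"sigma2_{kind}"][s] = sig2[k]
            chains["sigma2_eps"][s] = sig2_e
            f_sum += f_rb
            yhat_sum += mu_rec + f_rb.sum(axis=0)
            s += 1

    varpost = {
        kind: (
            float(chains[f"sigma2_{kind}"].mean()),
            float(chains[f"sigma2_{kind}"].std(ddof=1)),
        )
        for kind in kinds
    }
    varpost["eps"] = (
        float(chains["sigma2_eps"].mean()),
        float(chains["sigma2_eps"].std(ddof=1)),
    )
    yhat_df = pd.DataFrame(
        {
            "genotype": df["genotype"].to_numpy(),
            "environment": df["environment"].to_numpy(),
            "yhat": yhat_sum / n_samples,
        }
    )
    mu_post = {
        e: (float(chains[f"mu_{e}"].mean()), float(chains[f"mu_{e}"].std(ddof=1)))
        for e in envs
    }
    diagnostics = {
        name: {
            "ess": effective_sample_size(chain),
            "rhat": split_rhat(chain),
            "mcse": mcse(chain),
        }
        for name, chain in chains.items()
    }
    return MultiEnvFit(
        mode="unbalanced_hadamard",
        ids=list(ids),
        env_ids=envs,
        kernel_kinds=kinds,
        mu_posterior=mu_post,
        U_posterior=None,
        R_posterior=None,
        varcomp_posterior=varpost,
        yhat=yhat_df,
        chains=chains,
        diagnostics=diagnostics,
    )
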