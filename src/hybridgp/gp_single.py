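"""Single-environment multi-kernel Bayesian mixed models (S1-S5).

The model is

    y = 1 mu + sum_k g_k + eps,
    g_k ~ N(0, sigma2_k K_k),   eps ~ N(0, sigma2_eps I),

with one random effect vector per relationship kernel.  The named model
variants differ only in the kernel set: S1 uses the pedigree matrix A,
S2 the linear genomic matrix G (GBLUP), S3 the Gaussian kernel K, S4
A+K, and S5 adds the hybrid kernels C and P built from the product KA.

Fitting is by Gibbs sampling.  Each kernel is eigendecomposed once,
K_k = Q_k L_k Q_k', and effects are sampled in the rotated basis where
the full conditional is diagonal, giving O(n^2) cost per kernel per
iteration.  Variance components carry scaled-inverse-chi-square priors
whose scales partition a prior R^2 of the phenotypic variance equally
across kernels; the intercept has a flat prior.  Missing phenotype
entries are treated as latent and redrawn from their predictive
distribution each iteration (data augmentation), so masked genotypes
acquire genuine posterior predictive means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from hybridgp._mcmc import (
    MCMCSettings,
    draw_scaled_inv_chi2,
    effective_sample_size,
    mcse,
    scaled_inv_chi2_scale,
    slice_sample_1d,
    split_rhat,
    truncated_eigh,
)
from hybridgp.relation_kernels import RelationshipKernel

__all__ = [
    "MCMCSettings",
    "SingleEnvModelSpec",
    "SingleEnvFit",
    "SINGLE_ENV_MODELS",
    "fit_single_env",
    "predict_single_env",
    "effect_vector_correlations",
]

SINGLE_ENV_MODELS: dict[str, tuple[str, ...]] = {
    "S1": ("A",),
    "S2": ("G",),
    "S3": ("K",),
    "S4": ("A", "K"),
    "S5": ("A", "K", "C", "P"),
}


@dataclass(frozen=True)
class SingleEnvModelSpec:
    """Model definition: which kernels enter, priors, and MCMC settings.

    ``prior_R2`` is the prior proportion of phenotypic variance assigned
    to the genetic terms jointly (split equally across kernels); the
    remainder sets the residual prior scale.  ``prior_df`` is the
    scaled-inverse-chi-square degrees of freedom for every variance
    component.
    """

    kernel_set: tuple[str, ...]
    prior_df: float = 5.0
    prior_R2: float = 0.5
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)

    def __post_init__(self) -> None:
        if not self.kernel_set:
            raise ValueError("kernel_set must be non-empty")
        if not 0 < self.prior_R2 < 1:
            raise ValueError("prior_R2 must lie in (0, 1)")
        if self.prior_df <= 0:
            raise ValueError("prior_df must be positive")

    @classmethod
    def from_name(cls, name: str, **kwargs) -> "SingleEnvModelSpec":
        """Model definition for a named variant S1..S5."""
        if name not in SINGLE_ENV_MODELS:
            raise ValueError(f"unknown single-environment model {name!r}")
        return cls(kernel_set=SINGLE_ENV_MODELS[name], **kwargs)


@dataclass
class SingleEnvFit:
    """Posterior summaries of a single-environment fit.

    ``varcomp_posterior`` maps each kernel kind (plus ``'eps'``) to
    (posterior mean, posterior sd); ``effects_posterior`` holds the
    posterior-mean effect vector per kernel; ``yhat`` is the
    posterior-mean prediction mu + sum_k g_k for every genotype,
    training and masked alike.  ``chains`` keeps the thinned draws of
    the intercept and variance components for diagnostics.
    """

    ids: list[str]
    kernel_kinds: list[str]
    mu_posterior: tuple[float, float]
    varcomp_posterior: dict[str, tuple[float, float]]
    effects_posterior: dict[str, np.ndarray]
    yhat: np.ndarray
    observed: np.ndarray
    chains: dict[str, np.ndarray]
    diagnostics: dict[str, dict[str, float]] = field(default_factory=dict)

    def mcse_of(self, name: str) -> float:
        """Monte Carlo standard error of a stored chain's mean."""
        return mcse(self.chains[name])


def _prepare_kernels(kernels: list[RelationshipKernel]):
    kinds: list[str] = []
    seen: dict[str, int] = {}
    for k in kernels:
        kind = k.kind
        if kind in seen:
            seen[kind] += 1
            kind = f"{kind}{seen[kind]}"
        else:
            seen[kind] = 1
        kinds.append(kind)
    eigs = [truncated_eigh(k.matrix) for k in kernels]
    return kinds, eigs


def fit_single_env(
    y: np.ndarray,
    kernels: list[RelationshipKernel],
    spec: SingleEnvModelSpec,
    fixed_varcomps: dict[str, float] | None = None,
    deterministic: bool = False,
) -> SingleEnvFit:
    """Fit the multi-kernel model by Gibbs sampling.

    Parameters
    ----------
    y
        Phenotype vector aligned to the kernels' shared id order; NaN
        entries are masked genotypes to be predicted.
    kernels
        Relationship kernels, all with identical id order, validated
        (and PSD-repaired) beforehand.
    spec
        Kernel set, priors and MCMC settings.
    fixed_varcomps
        Optional mapping kind -> value (include ``'eps'``) that pins
        variance components instead of sampling them; used for BLUP
        cross-checks.
    deterministic
        With ``fixed_varcomps``, iterate conditional means instead of
        sampling; the result converges to the exact joint conditional
        mean (the mixed-model-equation / BLUP solution).

    Notes
    -----
    The number of kernels must match ``spec.kernel_set``; kernels are
    taken in the given order.  Identical seeds and inputs give
    bit-identical chains.
    """
    y = np.asarray(y, dtype=float).copy()
    n = y.size
    if len(kernels) != len(spec.kernel_set):
        raise ValueError(
            f"spec lists {len(spec.kernel_set)} kernels but {len(kernels)} given"
        )
    ids = kernels[0].ids
    for k in kernels[1:]:
        if k.ids != ids:
            raise ValueError("kernels are not aligned to a common id order")
    if n != len(ids):
        raise ValueError("phenotype length does not match kernel dimension")
    obs = ~np.isnan(y)
    n_obs = int(obs.sum())
    if n_obs < 2:
        raise ValueError("need at least 2 observed phenotypes")
    if deterministic and fixed_varcomps is None:
        raise ValueError("deterministic mode requires fixed_varcomps")

    kinds, eigs = _prepare_kernels(kernels)
    nk = len(kernels)
    var_y = float(np.var(y[obs], ddof=1)) if n_obs > 1 else 1.0
    if var_y <= 0:
        var_y = 1e-6

    df0 = spec.prior_df
    S_g = scaled_inv_chi2_scale(spec.prior_R2 * var_y / nk, df0)
    S_e = scaled_inv_chi2_scale((1.0 - spec.prior_R2) * var_y, df0)

    rng = np.random.default_rng(spec.mcmc.seed)

    # state
    mu = float(np.mean(y[obs]))
    sig2 = np.full(nk, spec.prior_R2 * var_y / nk)
    sig2_e = (1.0 - spec.prior_R2) * var_y
    if fixed_varcomps is not None:
        for j, kind in enumerate(kinds):
            base = kernels[j].kind
            if kind in fixed_varcomps:
                sig2[j] = fixed_varcomps[kind]
            elif base in fixed_varcomps:
                sig2[j] = fixed_varcomps[base]
            else:
                raise KeyError(f"fixed_varcomps missing component {kind!r}")
        if "eps" not in fixed_varcomps:
            raise KeyError("fixed_varcomps missing residual component 'eps'")
        sig2_e = fixed_varcomps["eps"]
    g = np.zeros((nk, n))
    total = np.zeros(n)
    y_full = y.copy()
    y_full[~obs] = mu

    if deterministic:
        # Gauss-Seidel on the conditional means; converges to the joint
        # conditional mean of (mu, g_1..g_K) given fixed variances.
        for _ in range(2000):
            max_delta = 0.0
            for j in range(nk):
                lam, Q, _ = eigs[j]
                r = y_full - mu - (total - g[j])
                t = Q.T @ r
                v = 1.0 / (1.0 / sig2_e + 1.0 / (sig2[j] * lam))
                u = v * t / sig2_e
                g_new = Q @ u
                max_delta = max(max_delta, float(np.max(np.abs(g_new - g[j]))))
                total += g_new - g[j]
                g[j] = g_new
            mu_new = float(np.mean((y_full - total)[obs]))
            max_delta = max(max_delta, abs(mu_new - mu))
            mu = mu_new
            y_mis = mu + total[~obs]
            y_full[~obs] = y_mis
            if max_delta < 1e-13:
                break
        yhat = mu + total
        varpost = {kind: (float(s), 0.0) for kind, s in zip(kinds, sig2)}
        varpost["eps"] = (float(sig2_e), 0.0)
        return SingleEnvFit(
            ids=list(ids),
            kernel_kinds=kinds,
            mu_posterior=(mu, 0.0),
            varcomp_posterior=varpost,
            effects_posterior={kind: g[j].copy() for j, kind in enumerate(kinds)},
            yhat=yhat,
            observed=obs,
            chains={},
        )

    n_samples = spec.mcmc.n_samples
    chains: dict[str, np.ndarray] = {"mu": np.empty(n_samples)}
    for kind in kinds:
        chains[f"sigma2_{kind}"] = np.empty(n_samples)
    chains["sigma2_eps"] = np.empty(n_samples)
    # Effect posterior means are Rao-Blackwellized: we average the full
    # conditional means E[g_k | rest] (available for free during each scan)
    # instead of the draws, which sharply reduces Monte Carlo error.
    g_rb = np.zeros((nk, n))
    g_sum = np.zeros((nk, n))
    yhat_sum = np.zeros(n)
    s = 0

    sample_vars = fixed_varcomps is None
    # Q'1 per kernel, for the joint (mu, g_k) block updates below
    ones_rot = [eigs[j][1].T @ np.ones(n) for j in range(nk)]
    for it in range(spec.mcmc.n_iter):
        for j in range(nk):
            # Blocked update of (sigma2_j, g_j, mu).  The variance is
            # slice-sampled from its marginal with BOTH the effect vector
            # and the intercept integrated out analytically (O(rank) per
            # evaluation in the eigenbasis); the effect and intercept are
            # then redrawn jointly, with the intercept collapsed out of
            # the effect draw via a rank-one Woodbury correction.
            # Conditional one-at-a-time updates mix pathologically slowly
            # here because the kernels are collinear and their leading
            # eigenvectors are nearly parallel to 1.
            lam, Q, rank = eigs[j]
            a = ones_rot[j]
            r = y_full - (total - g[j])
            t = Q.T @ r
            if sample_vars:
                rr = float(r @ r)
                sr = float(np.sum(r))
                se = sig2_e

                def logpost(x):
                    s2 = np.exp(x)
                    denom = s2 * lam + se
                    c = s2 * lam / denom
                    A11 = (n - a @ (c * a)) / se
                    A1r = (sr - a @ (c * t)) / se
                    quad = (rr - t @ (c * t)) / se - A1r * A1r / A11
                    return (
                        -0.5 * float(np.sum(np.log(denom)))
                        - 0.5 * np.log(A11)
                        - 0.5 * quad
                        - 0.5 * df0 * x
                        - df0 * S_g / (2.0 * s2)
                    )

                sig2[j] = float(
                    np.exp(slice_sample_1d(logpost, np.log(sig2[j]), rng))
                )
            v = 1.0 / (1.0 / sig2_e + 1.0 / (sig2[j] * lam))
            b_u = t / sig2_e
            b_tilde = b_u - a * (np.sum(r) / (n * sig2_e))
            a_tilde = a / np.sqrt(n * sig2_e)
            w = v * a_tilde
            gamma = 1.0 - float(a_tilde @ w)
            u_mean = v * b_tilde + w * (float(w @ b_tilde) / gamma)
            u = (
                u_mean
                + np.sqrt(v) * rng.standard_normal(lam.size)
                + w * (rng.standard_normal() / np.sqrt(gamma))
            )
            g_rb[j] = Q @ u_mean
            g_new = Q @ u
            total += g_new - g[j]
            g[j] = g_new
            mu = float(
                rng.normal(np.mean(r - g_new), np.sqrt(sig2_e / n))
            )
        if sample_vars:
            e = y_full - mu - total
            sig2_e = draw_scaled_inv_chi2(
                rng, df0 + n, df0 * S_e + float(e @ e)
            )
        # data augmentation of masked phenotypes
        n_mis = n - n_obs
        if n_mis:
            y_full[~obs] = (
                mu
                + total[~obs]
                + np.sqrt(sig2_e) * rng.standard_normal(n_mis)
            )
        if it >= spec.mcmc.burn_in and (it - spec.mcmc.burn_in) % spec.mcmc.thin == 0:
            chains["mu"][s] = mu
            for j, kind in enumerate(kinds):
                chains[f"sigma2_{kind}"][s] = sig2[j]
            chains["sigma2_eps"][s] = sig2_e
            g_sum += g_rb
            yhat_sum += mu + g_rb.sum(axis=0)
            s += 1

    varpost: dict[str, tuple[float, float]] = {}
    for kind in kinds:
        c = chains[f"sigma2_{kind}"]
        varpost[kind] = (float(c.mean()), float(c.std(ddof=1)))
    ce = chains["sigma2_eps"]
    varpost["eps"] = (float(ce.mean()), float(ce.std(ddof=1)))
    diagnostics = {
        name: {
            "ess": effective_sample_size(chain),
            "rhat": split_rhat(chain),
            "mcse": mcse(chain),
        }
        for name, chain in chains.items()
    }
    return SingleEnvFit(
        ids=list(ids),
        kernel_kinds=kinds,
        mu_posterior=(float(chains["mu"].mean()), float(chains["mu"].std(ddof=1))),
        varcomp_posterior=varpost,
        effects_posterior={
            kind: g_sum[j] / n_samples for j, kind in enumerate(kinds)
        },
        yhat=yhat_sum / n_samples,
        observed=obs,
        chains=chains,
        diagnostics=diagnostics,
    )


def predict_single_env(fit: SingleEnvFit, target_ids) -> np.ndarray:
    """Posterior-mean predictions for the requested genotypes.

    Works identically for training genotypes (fitted values) and masked
    genotypes (posterior predictive means).
    """
    pos = {g: i for i, g in enumerate(fit.ids)}
    try:
        idx = [pos[str(g)] for g in target_ids]
    except KeyError as exc:
        raise KeyError(f"unknown genotype id {exc.args[0]!r}") from exc
    return fit.yhat[idx]


def effect_vector_correlations(fit: SingleEnvFit) -> np.ndarray:
    """Pairwise Pearson correlations among posterior-mean effect vectors.

    Low off-diagonal correlations indicate the kernels contribute
    non-redundant genetic signal.  A constant effect vector has
    undefined correlations, reported as NaN.
    """
    if len(fit.kernel_kinds) < 2:
        raise ValueError("need a fit with at least 2 kernels")
    vecs = [fit.effects_posterior[k] for k in fit.kernel_kinds]
    m = len(vecs)
    out = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            vi, vj = vecs[i], vecs[j]
            if np.std(vi) == 0 or np.std(vj) == 0:
                out[i, j] = out[j, i] = np.nan
            else:
                out[i, j] = out[j, i] = float(np.corrcoef(vi, vj)[0, 1])
    return out
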