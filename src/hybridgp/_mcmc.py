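"""Shared MCMC helpers: priors, chain diagnostics, eigendecompositions."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EIG_TRUNC = 1e-10  # eigenvalues below this are treated as structural zeros


@dataclass(frozen=True)
class MCMCSettings:
    """Gibbs-sampler run length: iterations, burn-in, thinning, seed.

    Defaults follow the long-run convention used for the real trial
    analyses (50,000 iterations, 5,000 burn-in, thinning 5); tests and
    the acceptance checks use much shorter chains.
    """

    n_iter: int = 50_000
    burn_in: int = 5_000
    thin: int = 5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_samples(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


def scaled_inv_chi2_scale(mode: float, df: float) -> float:
    """Scale S of a scaled-inverse-chi-square prior with the given mode.

    Parameterization: sigma^2 ~ df*S / chi2_df, whose mode is
    df*S/(df+2).
    """
    return mode * (df + 2.0) / df


def draw_scaled_inv_chi2(
    rng: np.random.Generator, df: float, df_scale_sum: float
) -> float:
    """Draw sigma^2 = df_scale_sum / chi2_df (full-conditional form)."""
    return df_scale_sum / rng.chisquare(df)


def truncated_eigh(M: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Eigendecomposition keeping only eigenvalues above ``EIG_TRUNC``.

    Returns (eigenvalues, eigenvectors, rank); coordinates along dropped
    eigenvectors are fixed at zero by the samplers.
    """
    w, Q = np.linalg.eigh((M + M.T) / 2.0)
    keep = w > EIG_TRUNC
    return w[keep], Q[:, keep], int(keep.sum())


def slice_sample_1d(
    logf,
    x0: float,
    rng: np.random.Generator,
    w: float = 1.0,
    max_steps: int = 20,
) -> float:
    """One univariate slice-sampling update (stepping out + shrinkage)."""
    logy = logf(x0) + np.log(rng.random())
    lo = x0 - w * rng.random()
    hi = lo + w
    for _ in range(max_steps):
        if logf(lo) <= logy:
            break
        lo -= w
    for _ in range(max_steps):
        if logf(hi) <= logy:
            break
        hi += w
    for _ in range(100):
        x1 = lo + (hi - lo) * rng.random()
        if logf(x1) > logy:
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1
    return x0


def effective_sample_size(chain: np.ndarray) -> float:
    """ESS via the initial-positive-sequence autocorrelation estimator."""
    x = np.asarray(chain, dtype=float)
    n = x.size
    if n < 4 or np.var(x) == 0:
        return float(n)
    x = x - x.mean()
    acov = np.correlate(x, x, mode="full")[n - 1 :] / n
    rho = acov / acov[0]
    s = 0.0
    for t in range(1, n - 1, 2):
        pair = rho[t] + rho[t + 1] if t + 1 < n else rho[t]
        if pair < 0:
            break
        s += pair
    ess = n / (1.0 + 2.0 * s)
    return float(min(max(ess, 1.0), n))


def mcse(chain: np.ndarray) -> float:
    """Monte Carlo standard error of the chain mean (ESS-adjusted)."""
    x = np.asarray(chain, dtype=float)
    if x.size < 2:
        return float("nan")
    return float(np.std(x, ddof=1) / np.sqrt(effective_sample_size(x)))


def split_rhat(chain: np.ndarray) -> float:
    """Split-chain potential scale reduction factor on a single chain."""
    x = np.asarray(chain, dtype=float)
    n = x.size // 2
    if n < 2:
        return float("nan")
    halves = np.stack([x[:n], x[-n:]])
    within = halves.var(axis=1, ddof=1).mean()
    between = n * halves.mean(axis=1).var(ddof=1)
    if within == 0:
        return 1.0 if between == 0 else float("inf")
    return float(np.sqrt((n - 1) / n + between / (n * within)))
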