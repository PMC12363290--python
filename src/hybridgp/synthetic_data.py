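"""Synthetic markers, pedigrees, kernels and phenotypes with known truth.

The generator emulates the structure of elite wheat yield-trial data:
a few hundred to ~1200 related genotypes, a few thousand SNP dosages,
4-6 environments with partially overlapping genotype sets, and
phenotypes drawn from the same additive multi-kernel generative models
the fitters assume (effects g_k ~ N(0, sigma2_k K_k) in one
environment, vec covariance U_k (x) K_k across environments).  Because
the truth (variance components, effect vectors) is returned alongside
the data, every fitting module can be tested for parameter recovery
without external downloads.

The default preset is "EYT-like": n=600 genotypes, p=2000 markers, 5
environments, genetic variance components in the 0.05-0.8 range and
residual variances in 0.15-0.7 — inspired by, not equal to, estimates
published for real elite yield trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from hybridgp.phenotypes import PhenotypeTable
from hybridgp.relation_kernels import (
    MarkerMatrix,
    PedigreeTable,
    RelationshipKernel,
    build_C,
    build_P,
    compute_G,
    compute_KA,
    compute_gaussian_kernel,
    pedigree_to_A,
    standardize_markers,
    validate_kernel,
)

__all__ = [
    "SimConfig",
    "eyt_like",
    "simulate_markers",
    "simulate_pedigree",
    "simulate_phenotypes_single",
    "simulate_phenotypes_multi",
    "simulate_kernel_set",
    "simulate_study",
]


@dataclass
class SimConfig:
    """Simulation settings; defaults give the EYT-like preset."""

    n_genotypes: int = 600
    n_markers: int = 2000
    allele_freq_range: tuple[float, float] = (0.05, 0.95)
    n_founders: int = 40
    generations: int = 3
    variance_components: dict[str, float] = field(
        default_factory=lambda: {"A": 0.20, "K": 0.45, "C": 0.35, "P": 0.25}
    )
    residual: float = 0.20
    m_environments: int = 5
    env_genetic_correlation: float = 0.5
    missing_pattern: float = 0.0  # fraction of cells absent (unbalanced)
    seed: int | None = None

    def __post_init__(self) -> None:
        lo, hi = self.allele_freq_range
        if not (0 < lo <= hi < 1):
            raise ValueError("allele frequencies must lie in (0, 1)")
        if any(v < 0 for v in self.variance_components.values()):
            raise ValueError("variance components must be >= 0")
        if self.n_founders < 2:
            raise ValueError("need at least 2 founders")


def eyt_like(**overrides) -> SimConfig:
    """The default elite-yield-trial-like preset (n=600, p=2000, m=5)."""
    return SimConfig(**overrides)


def simulate_pedigree(config: SimConfig, rng: np.random.Generator | None = None) -> PedigreeTable:
    """Random-mating pedigree: founders plus ``generations`` offspring waves.

    Offspring counts are balanced across generations so that the total
    number of individuals equals ``n_genotypes``.  With
    ``generations=0`` all individuals are unrelated founders and the
    numerator relationship matrix is the identity.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    records: list[tuple[str, str | None, str | None]] = [
        (f"g{i:04d}", None, None) for i in range(config.n_founders)
    ]
    if config.generations == 0:
        extra = config.n_genotypes - config.n_founders
        records += [
            (f"g{config.n_founders + i:04d}", None, None) for i in range(max(extra, 0))
        ]
        return PedigreeTable(records[: config.n_genotypes])
    n_offspring = config.n_genotypes - config.n_founders
    per_gen = [n_offspring // config.generations] * config.generations
    for i in range(n_offspring % config.generations):
        per_gen[i] += 1
    next_id = config.n_founders
    pool = [r[0] for r in records]
    for count in per_gen:
        new_ids = []
        for _ in range(count):
            p1, p2 = rng.choice(len(pool), size=2, replace=False)
            records.append((f"g{next_id:04d}", pool[p1], pool[p2]))
            new_ids.append(f"g{next_id:04d}")
            next_id += 1
        pool = pool + new_ids
    return PedigreeTable(records)


def simulate_markers(
    config: SimConfig,
    pedigree: PedigreeTable | None = None,
    rng: np.random.Generator | None = None,
) -> MarkerMatrix:
    """SNP dosages in {0, 1, 2}.

    Without a pedigree, dosages are binomial(2, q_m) with per-marker
    allele frequency q_m uniform on ``allele_freq_range``.  With a
    pedigree, founder haplotypes are Bernoulli(q_m) and descendants
    receive one gamete per parent (gene dropping), so marker-derived
    kernels reflect the pedigree's family structure.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    lo, hi = config.allele_freq_range
    p = config.n_markers
    freqs = rng.uniform(lo, hi, size=p)
    if pedigree is None:
        ids = [f"g{i:04d}" for i in range(config.n_genotypes)]
        X = rng.binomial(2, freqs[None, :], size=(config.n_genotypes, p)).astype(float)
        return MarkerMatrix(ids=ids, values=X)
    pos = {g: i for i, g in enumerate(pedigree.ids)}
    n = len(pedigree.ids)
    hap = np.zeros((n, 2, p), dtype=np.int8)
    for ind, p1, p2 in pedigree.records:
        i = pos[ind]
        for slot, parent in enumerate((p1, p2)):
            if parent is None:
                hap[i, slot] = rng.random(p) < freqs
            else:
                pick = rng.integers(0, 2, size=p)
                hap[i, slot] = hap[pos[parent], pick, np.arange(p)]
    X = hap.sum(axis=1).astype(float)
    return MarkerMatrix(ids=list(pedigree.ids), values=X)


def _psd_sqrt(M: np.ndarray) -> np.ndarray:
    w, Q = np.linalg.eigh((M + M.T) / 2.0)
    return Q * np.sqrt(np.clip(w, 0.0, None))


def simulate_phenotypes_single(
    kernels: dict[str, RelationshipKernel],
    variance_components: dict[str, float],
    residual: float,
    seed: int | None = None,
    mu: float = 0.0,
):
    """Draw y = mu + sum_k g_k + eps with g_k ~ N(0, sigma2_k K_k).

    Kernel square roots use eigendecomposition with negative eigenvalues
    clipped at zero.  Returns ``(y, truths)`` where truths holds mu, the
    variance components, the residual variance, and every effect vector.
    """
    rng = np.random.default_rng(seed)
    kinds = list(variance_components)
    missing = [k for k in kinds if k not in kernels]
    if missing:
        raise KeyError(f"no kernel supplied for components {missing}")
    ids = kernels[kinds[0]].ids
    n = len(ids)
    effects: dict[str, np.ndarray] = {}
    y = np.full(n, mu, dtype=float)
    for kind in kinds:
        K = kernels[kind]
        if K.ids != ids:
            raise ValueError("kernels are not aligned")
        s2 = variance_components[kind]
        g = _psd_sqrt(K.matrix) @ rng.standard_normal(n) * np.sqrt(s2)
        effects[kind] = g
        y = y + g
    eps = np.sqrt(residual) * rng.standard_normal(n)
    y = y + eps
    truths = {
        "mu": mu,
        "variance_components": dict(variance_components),
        "residual": residual,
        "effects": effects,
        "eps": eps,
        "ids": list(ids),
    }
    return y, truths


def simulate_phenotypes_multi(
    kernels: dict[str, RelationshipKernel],
    U: dict[str, np.ndarray],
    R: np.ndarray,
    env_ids: list[str],
    seed: int | None = None,
    mu: np.ndarray | None = None,
    incidence: np.ndarray | None = None,
):
    """Draw multi-environment phenotypes with vec covariance U_k (x) K_k.

    Effects for kernel k are the matrix normal ``L_K Z L_U'`` whose
    vectorization has covariance ``U_k (x) K_k``; residual rows are
    N(0, R) per genotype.  ``incidence`` is an optional boolean
    n x m mask of cells to keep (False rows are dropped entirely,
    producing unbalanced data).  Returns ``(PhenotypeTable, truths)``.
    """
    rng = np.random.default_rng(seed)
    kinds = list(U)
    ids = kernels[kinds[0]].ids
    n, m = len(ids), len(env_ids)
    if mu is None:
        mu = np.zeros(m)
    Y = np.tile(np.asarray(mu, dtype=float), (n, 1))
    effects: dict[str, np.ndarray] = {}
    for kind in kinds:
        K = kernels[kind]
        if K.ids != ids:
            raise ValueError("kernels are not aligned")
        Uk = np.asarray(U[kind], dtype=float)
        G = _psd_sqrt(K.matrix) @ rng.standard_normal((n, m)) @ _psd_sqrt(Uk).T
        effects[kind] = G
        Y = Y + G
    Eps = rng.standard_normal((n, m)) @ _psd_sqrt(np.asarray(R, dtype=float)).T
    Y = Y + Eps
    if incidence is None:
        incidence = np.ones((n, m), dtype=bool)
    rows = []
    for j, e in enumerate(env_ids):
        for i, g in enumerate(ids):
            if incidence[i, j]:
                rows.append((g, e, Y[i, j]))
    table = PhenotypeTable(pd.DataFrame(rows, columns=["genotype", "environment", "value"]))
    truths = {
        "mu": np.asarray(mu, dtype=float),
        "U": {k: np.asarray(v, dtype=float) for k, v in U.items()},
        "R": np.asarray(R, dtype=float),
        "effects": effects,
        "Y": Y,
        "ids": list(ids),
        "env_ids": list(env_ids),
    }
    return table, truths


def simulate_kernel_set(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, RelationshipKernel], PedigreeTable, MarkerMatrix]:
    """Simulate pedigree + markers and build aligned A, G, K, C, P kernels.

    Markers are gene-dropped down the pedigree so that G and K share
    family structure with A.  C and P come from the product KA and are
    PSD-repaired by eigenvalue clipping (the raw symmetrized products
    are typically indefinite).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    pedigree = simulate_pedigree(config, rng)
    markers = simulate_markers(config, pedigree, rng)
    A = pedigree_to_A(pedigree)
    std = standardize_markers(markers)
    G = compute_G(std)
    K = compute_gaussian_kernel(std)
    KA = compute_KA(K, A)
    C, _ = validate_kernel(build_C(KA, ids=A.ids), repair="eigen_clip")
    P, _ = validate_kernel(build_P(KA, ids=A.ids), repair="eigen_clip")
    kernels = {"A": A, "G": G, "K": K, "C": C, "P": P}
    return kernels, pedigree, markers


def simulate_study(config: SimConfig, kind: str = "single"):
    """End-to-end dataset: kernels plus phenotypes from the generative model.

    ``kind='single'`` draws one environment from the additive
    multi-kernel model using ``config.variance_components``;
    ``kind='multi'`` draws ``m_environments`` environments with
    compound-symmetry environment covariances
    ``U_k = sigma2_k [(1-rho) I + rho J]`` (rho =
    ``env_genetic_correlation``) and diagonal residual covariance.
    ``missing_pattern`` removes that fraction of cells at random for
    unbalanced designs.  Returns a dict with kernels, pedigree,
    markers, phenotypes and truths.
    """
    rng = np.random.default_rng(config.seed)
    kernels, pedigree, markers = simulate_kernel_set(config, rng)
    sub_seed = int(rng.integers(0, 2**31 - 1))
    out = {"kernels": kernels, "pedigree": pedigree, "markers": markers}
    if kind == "single":
        y, truths = simulate_phenotypes_single(
            kernels, config.variance_components, config.residual, seed=sub_seed
        )
        out["phenotypes"] = PhenotypeTable.from_vector(kernels["A"].ids, y)
        out["y"] = y
        out["truths"] = truths
        return out
    if kind != "multi":
        raise ValueError("kind must be 'single' or 'multi'")
    m = config.m_environments
    rho = config.env_genetic_correlation
    cs = (1.0 - rho) * np.eye(m) + rho * np.ones((m, m))
    U = {k: v * cs for k, v in config.variance_components.items()}
    R = config.residual * np.eye(m)
    env_ids = [f"env{j + 1}" for j in range(m)]
    incidence = None
    if config.missing_pattern > 0:
        incidence = rng.random((config.n_genotypes, m)) >= config.missing_pattern
        incidence[:, 0] |= ~incidence.any(axis=1)  # keep every genotype somewhere
    table, truths = simulate_phenotypes_multi(
        kernels, U, R, env_ids, seed=sub_seed, incidence=incidence
    )
    out["phenotypes"] = table
    out["truths"] = truths
    return out
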