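"""Relationship kernels for genomic prediction.

This module constructs the covariance kernels used throughout the package:

* ``A``  — pedigree numerator relationship matrix (tabular method),
* ``G``  — linear genomic relationship matrix ``XX'/p`` on standardized
  markers (GBLUP),
* ``K``  — Gaussian kernel ``exp(-d_ij^2 / median(d_ij^2))`` on Euclidean
  marker distances,
* ``C``/``P`` — hybrid kernels built by symmetrizing the strictly upper
  (C) or strictly lower (P) triangular part of the matrix product ``KA``,
  restoring the KA diagonal and scaling by its mean.

The product ``KA`` of two symmetric kernels is generally non-symmetric and
therefore not itself a valid covariance kernel; C and P are the two
symmetric kernels that jointly carry all of its information (their scaled
sum reconstructs ``KA + (KA)'``).  ``validate_kernel`` checks symmetry and
positive semi-definiteness and can repair numerically indefinite matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "MarkerMatrix",
    "RelationshipKernel",
    "PedigreeTable",
    "KernelValidityReport",
    "standardize_markers",
    "compute_G",
    "squared_distance_matrix",
    "compute_gaussian_kernel",
    "pedigree_to_A",
    "compute_KA",
    "build_C",
    "build_P",
    "validate_kernel",
    "align_kernels",
]

KERNEL_KINDS = ("A", "G", "K", "C", "P", "custom")

SYMMETRY_TOL = 1e-8


@dataclass
class MarkerMatrix:
    """Genotype-by-marker dosage matrix.

    Parameters
    ----------
    ids
        Genotype identifiers, one per row; must be unique.
    values
        ``n x p`` numeric matrix of marker dosages (any numeric coding).
    marker_ids
        Optional marker (column) identifiers; generated as ``m0..m{p-1}``
        when omitted.
    standardized
        True once every column has mean 0 and sample standard deviation 1.
    dropped_markers
        Identifiers of zero-variance columns removed by
        :func:`standardize_markers`.
    """

    ids: list[str]
    values: np.ndarray
    marker_ids: list[str] | None = None
    standardized: bool = False
    dropped_markers: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("marker values must be a 2-D array")
        self.ids = [str(i) for i in self.ids]
        if len(self.ids) != self.values.shape[0]:
            raise ValueError(
                f"{len(self.ids)} ids but {self.values.shape[0]} rows"
            )
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("genotype ids must be unique")
        if self.marker_ids is None:
            self.marker_ids = [f"m{j}" for j in range(self.values.shape[1])]
        elif len(self.marker_ids) != self.values.shape[1]:
            raise ValueError("marker_ids length does not match column count")
        if np.isnan(self.values).any():
            raise ValueError(
                "marker matrix contains missing values; impute upstream"
            )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


@dataclass
class RelationshipKernel:
    """Labelled symmetric n x n relationship matrix.

    ``kind`` is one of ``A, G, K, C, P, custom``.  ``bandwidth_info`` holds
    the median squared distance for Gaussian kernels, ``scaling_info`` the
    mean-diagonal divisor for C/P kernels, and ``min_eigenvalue`` is cached
    by :func:`validate_kernel`.
    """

    ids: list[str]
    matrix: np.ndarray
    kind: str = "custom"
    bandwidth_info: float | None = None
    scaling_info: float | None = None
    min_eigenvalue: float | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.ids = [str(i) for i in self.ids]
        if self.kind not in KERNEL_KINDS:
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match {n} ids"
            )
        if len(set(self.ids)) != n:
            raise ValueError("genotype ids must be unique")
        dev = np.max(np.abs(self.matrix - self.matrix.T)) if n else 0.0
        if dev > 1e-10:
            raise ValueError(f"kernel asymmetric: max deviation {dev:.3e}")

    @property
    def n(self) -> int:
        return len(self.ids)

    def reorder(self, ids: list[str]) -> "RelationshipKernel":
        """Restrict/reorder the kernel to the given id list."""
        pos = {g: i for i, g in enumerate(self.ids)}
        try:
            idx = np.array([pos[g] for g in ids])
        except KeyError as exc:
            raise KeyError(f"id {exc.args[0]!r} not present in kernel") from exc
        return replace(
            self,
            ids=list(ids),
            matrix=self.matrix[np.ix_(idx, idx)],
            min_eigenvalue=None,
        )


@dataclass
class PedigreeTable:
    """Ordered pedigree records ``(individual, parent1, parent2)``.

    Missing parents are ``None``.  Records are topologically sorted on
    construction so that parents precede offspring; a cyclic pedigree or a
    parent id that never appears as an individual raises ``ValueError``.
    """

    records: list[tuple[str, str | None, str | None]]

    def __post_init__(self) -> None:
        norm: list[tuple[str, str | None, str | None]] = []
        for ind, p1, p2 in self.records:
            norm.append((str(ind), _norm_parent(p1), _norm_parent(p2)))
        ids = [r[0] for r in norm]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate individual ids in pedigree")
        known = set(ids)
        for ind, p1, p2 in norm:
            for p in (p1, p2):
                if p is not None and p not in known:
                    raise ValueError(f"unknown parent id {p!r} for {ind!r}")
        self.records = _toposort(norm)

    @property
    def ids(self) -> list[str]:
        return [r[0] for r in self.records]


def _norm_parent(p: object) -> str | None:
    if p is None:
        return None
    s = str(p).strip()
    if s == "" or s.upper() in {"NA", "NAN", "0", "."}:
        return None
    return s


def _toposort(
    records: list[tuple[str, str | None, str | None]]
) -> list[tuple[str, str | None, str | None]]:
    by_id = {r[0]: r for r in records}
    order: list[tuple[str, str | None, str | None]] = []
    state: dict[str, int] = {}  # 0 visiting, 1 done

    def visit(ind: str) -> None:
        st = state.get(ind)
        if st == 1:
            return
        if st == 0:
            raise ValueError(f"cyclic pedigree involving {ind!r}")
        state[ind] = 0
        for p in by_id[ind][1:]:
            if p is not None:
                visit(p)
        state[ind] = 1
        order.append(by_id[ind])

    for r in records:
        visit(r[0])
    return order


# ---------------------------------------------------------------------------
# marker operations


def standardize_markers(
    markers: MarkerMatrix, zero_variance_policy: str = "drop"
) -> MarkerMatrix:
    """Center and scale each marker column to sample standard deviation 1.

    Uses the n-1 denominator.  Zero-variance columns are dropped (recorded
    in ``dropped_markers``, with a warning) or raise, per
    ``zero_variance_policy`` in ``{"drop", "error"}``.
    """
    if zero_variance_policy not in ("drop", "error"):
        raise ValueError("zero_variance_policy must be 'drop' or 'error'")
    if markers.n < 2:
        raise ValueError("need at least 2 genotypes to standardize")
    X = markers.values
    sd = X.std(axis=0, ddof=1)
    zero = sd < 1e-12
    if zero.any():
        names = [m for m, z in zip(markers.marker_ids, zero) if z]
        if zero_variance_policy == "error":
            raise ValueError(f"zero-variance markers: {names[:10]}")
        warnings.warn(
            f"dropping {len(names)} zero-variance marker(s)", stacklevel=2
        )
    keep = ~zero
    Xs = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    return MarkerMatrix(
        ids=list(markers.ids),
        values=Xs,
        marker_ids=[m for m, k in zip(markers.marker_ids, keep) if k],
        standardized=True,
        dropped_markers=markers.dropped_markers
        + [m for m, z in zip(markers.marker_ids, zero) if z],
    )


def compute_G(markers: MarkerMatrix) -> RelationshipKernel:
    """Linear genomic relationship matrix ``G = XX'/p`` (GBLUP kernel).

    Requires standardized markers; ``p`` is the retained marker count.
    """
    if not markers.standardized:
        raise ValueError("compute_G requires standardized markers")
    if markers.p < 1:
        raise ValueError("no markers left after zero-variance drops")
    X = markers.values
    G = (X @ X.T) / markers.p
    G = (G + G.T) / 2.0  # wash out float asymmetry from BLAS
    return RelationshipKernel(ids=list(markers.ids), matrix=G, kind="G")


def squared_distance_matrix(markers: MarkerMatrix) -> np.ndarray:
    """Pairwise squared Euclidean distances between genotype rows.

    Exact diagonal zeros and symmetry are enforced.
    """
    if markers.n < 2:
        raise ValueError("need at least 2 genotypes")
    X = markers.values
    sq = np.einsum("ij,ij->i", X, X)
    D = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    D = np.maximum(D, 0.0)
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return D


def compute_gaussian_kernel(
    markers: MarkerMatrix, bandwidth_scale: float = 1.0
) -> RelationshipKernel:
    """Gaussian kernel ``K_ij = exp(-d_ij^2 / (h * med))``.

    ``med`` is the median of the strictly-upper-triangular squared
    Euclidean distances (structural diagonal zeros excluded) and ``h`` is
    ``bandwidth_scale`` (default 1, the canonical median heuristic).
    Raises on degenerate input where all genotypes coincide (``med = 0``).
    """
    if bandwidth_scale <= 0:
        raise ValueError("bandwidth_scale must be positive")
    D = squared_distance_matrix(markers)
    iu = np.triu_indices(markers.n, k=1)
    med = float(np.median(D[iu]))
    if med <= 0:
        raise ValueError("all genotypes identical: median distance is zero")
    K = np.exp(-D / (bandwidth_scale * med))
    np.fill_diagonal(K, 1.0)
    return RelationshipKernel(
        ids=list(markers.ids), matrix=K, kind="K", bandwidth_info=med
    )


# ---------------------------------------------------------------------------
# pedigree


def pedigree_to_A(pedigree: PedigreeTable) -> RelationshipKernel:
    """Numerator relationship matrix by the tabular method.

    ``A_ii = 1 + 0.5 A_{p1,p2}`` and ``A_ij = 0.5 (A_{j,p1} + A_{j,p2})``
    for ``j`` earlier in the (topologically sorted) order; a missing parent
    contributes 0.  Used when no precomputed pedigree matrix (for example
    a coefficient-of-parentage matrix) is supplied.
    """
    ids = pedigree.ids
    n = len(ids)
    pos = {g: i for i, g in enumerate(ids)}
    A = np.zeros((n, n))
    for i, (ind, p1, p2) in enumerate(pedigree.records):
        i1 = pos[p1] if p1 is not None else None
        i2 = pos[p2] if p2 is not None else None
        for j in range(i):
            a = 0.0
            if i1 is not None:
                a += A[j, i1]
            if i2 is not None:
                a += A[j, i2]
            A[i, j] = A[j, i] = 0.5 * a
        A[i, i] = 1.0 + (0.5 * A[i1, i2] if i1 is not None and i2 is not None else 0.0)
    return RelationshipKernel(ids=ids, matrix=A, kind="A")


# ---------------------------------------------------------------------------
# hybrid kernels


def compute_KA(K: RelationshipKernel, A: RelationshipKernel) -> np.ndarray:
    """Matrix (dot) product ``K x A``.

    The result is generally non-symmetric and is not itself a valid
    kernel; it is the raw material for :func:`build_C` and :func:`build_P`.
    Both kernels must share an identical id order (see
    :func:`align_kernels`).
    """
    if K.ids != A.ids:
        raise ValueError("K and A id orders differ; align_kernels first")
    return K.matrix @ A.matrix


def _build_hybrid(KA: np.ndarray, part: str) -> tuple[np.ndarray, float]:
    KA = np.asarray(KA, dtype=float)
    if KA.ndim != 2 or KA.shape[0] != KA.shape[1]:
        raise ValueError("KA must be square")
    d = np.diag(KA).copy()
    divisor = float(d.mean())
    if divisor <= 0:
        raise ValueError("mean diagonal of KA is not positive")
    tri = np.triu(KA, k=1) if part == "upper" else np.tril(KA, k=-1)
    M = tri + tri.T + np.diag(d)
    return M / divisor, divisor


def build_C(KA: np.ndarray, ids: list[str] | None = None) -> RelationshipKernel:
    """Hybrid kernel C from the strictly upper triangular part of KA.

    ``C0 = strictUpper(KA) + strictUpper(KA)' + Diag(diag(KA))``, then
    ``C = C0 / mean(diag(KA))`` so that the mean diagonal is exactly 1.
    """
    M, divisor = _build_hybrid(KA, "upper")
    if ids is None:
        ids = [str(i) for i in range(M.shape[0])]
    return RelationshipKernel(ids=ids, matrix=M, kind="C", scaling_info=divisor)


def build_P(KA: np.ndarray, ids: list[str] | None = None) -> RelationshipKernel:
    """Hybrid kernel P from the strictly lower triangular part of KA.

    Construction mirrors :func:`build_C`; together C and P satisfy
    ``mean(diag(KA)) * (C + P) = KA + (KA)'``.
    """
    M, divisor = _build_hybrid(KA, "lower")
    if ids is None:
        ids = [str(i) for i in range(M.shape[0])]
    return RelationshipKernel(ids=ids, matrix=M, kind="P", scaling_info=divisor)


# ---------------------------------------------------------------------------
# validation / alignment


@dataclass
class KernelValidityReport:
    kind: str
    n: int
    min_eigenvalue: float
    symmetry_deviation: float
    psd: bool
    repair: str
    repaired: bool
    min_eigenvalue_after: float | None = None


def validate_kernel(
    kernel: RelationshipKernel,
    repair: str = "none",
    tol: float = 1e-8,
) -> tuple[RelationshipKernel, KernelValidityReport]:
    """Check symmetry and positive semi-definiteness; optionally repair.

    ``repair='jitter'`` adds ``(|lambda_min| + tol) I`` when the smallest
    eigenvalue is below ``-tol``; ``repair='eigen_clip'`` reconstructs the
    matrix with negative eigenvalues set to zero.  Either repair is
    followed by rescaling so the mean diagonal is preserved.  Returns the
    (possibly repaired) kernel and a report.
    """
    if repair not in ("none", "jitter", "eigen_clip"):
        raise ValueError("repair must be 'none', 'jitter' or 'eigen_clip'")
    M = kernel.matrix
    sym_dev = float(np.max(np.abs(M - M.T))) if kernel.n else 0.0
    if sym_dev > SYMMETRY_TOL:
        raise ValueError(f"kernel asymmetric beyond tolerance: {sym_dev:.3e}")
    eigvals = np.linalg.eigvalsh((M + M.T) / 2.0)
    lam_min = float(eigvals[0])
    psd = lam_min >= -tol
    repaired = False
    out = kernel
    lam_after: float | None = None
    if not psd and repair != "none":
        mean_diag = float(np.mean(np.diag(M)))
        if repair == "jitter":
            R = M + (abs(lam_min) + tol) * np.eye(kernel.n)
        else:
            w, Q = np.linalg.eigh((M + M.T) / 2.0)
            R = (Q * np.clip(w, 0.0, None)) @ Q.T
            R = (R + R.T) / 2.0
        new_mean = float(np.mean(np.diag(R)))
        if mean_diag > 0 and new_mean > 0:
            R *= mean_diag / new_mean
        lam_after = float(np.linalg.eigvalsh(R)[0])
        out = replace(kernel, matrix=R, min_eigenvalue=lam_after)
        repaired = True
    else:
        out = replace(kernel, min_eigenvalue=lam_min)
    report = KernelValidityReport(
        kind=kernel.kind,
        n=kernel.n,
        min_eigenvalue=lam_min,
        symmetry_deviation=sym_dev,
        psd=psd,
        repair=repair,
        repaired=repaired,
        min_eigenvalue_after=lam_after,
    )
    return out, report


def align_kernels(kernels, phenotypes=None):
    """Restrict all kernels (and optionally phenotypes) to common ids.

    Ids are matched by exact string comparison.  All kernels are reordered
    to the same id list (order of appearance in the first kernel).  When a
    phenotype table is given, its genotypes join the intersection and rows
    whose genotype is absent from any kernel are dropped with a warning.

    Returns ``aligned_kernels`` or ``(aligned_kernels, aligned_phenotypes)``.
    """
    if not kernels:
        raise ValueError("no kernels to align")
    common = set(kernels[0].ids)
    for k in kernels[1:]:
        common &= set(k.ids)
    if phenotypes is not None:
        common &= set(phenotypes.genotype_ids)
    if not common:
        raise ValueError("empty genotype-id intersection across inputs")
    order = [g for g in kernels[0].ids if g in common]
    aligned = [k.reorder(order) for k in kernels]
    if phenotypes is None:
        return aligned
    n_before = len(phenotypes.df)
    ph = phenotypes.restrict_genotypes(order)
    dropped = n_before - len(ph.df)
    if dropped:
        warnings.warn(
            f"dropped {dropped} phenotype record(s) with genotypes absent "
            "from the kernels",
            stacklevel=2,
        )
    return aligned, ph
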