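# Methods

## Model

Phenotypes are stage-1 adjusted genotype means (BLUEs). The
single-environment model is an additive multi-kernel mixed model

    y = 1 mu + sum_k g_k + eps,
    g_k ~ N(0, sigma2_k K_k),  eps ~ N(0, sigma2_eps I),

with one random vector per relationship kernel and a flat prior on the
intercept. The named variants S1–S5 differ only in the kernel set
(A; G; K; A+K; A+K+C+P). Phenotypes are not re-standardized internally:
`y` is taken as supplied (typically already standardized upstream), and
prior scales are set from its sample variance.

Multi-environment models treat environments as correlated traits. With
complete genotype-by-environment incidence ("balanced"), effects for
kernel `K_k` are matrix-normal with vec-covariance `U_k ⊗ K_k`, where
`U_k` is an unstructured m×m environment covariance estimated from the
data; residual rows are `N(0, R)` per genotype with unstructured `R`.
With incomplete incidence ("unbalanced"), each effect carries one
variance and the record-level covariance
`sigma2_k (Z1 K_k Z1') ∘ (Z2 E Z2')`, with incidence matrices `Z1`
(records→genotypes), `Z2` (records→environments) and an environment
covariance `E`; the residual is a single homogeneous variance, since the
Hadamard form carries one scalar variance per term. Under complete
incidence and `E = U` the Hadamard covariance equals the Kronecker one
exactly (record order: environment-major, genotype within environment) —
this identity is verified in the test suite and acceptance script.

## Kernels

* **A** — numerator relationship matrix from a 3-column pedigree by the
  tabular method (`A_ii = 1 + 0.5 A_{p1,p2}`, `A_ij = 0.5(A_{j,p1} +
  A_{j,p2})`, missing parents contribute 0). A precomputed relationship
  matrix (e.g. coefficient of parentage) is accepted verbatim instead.
* **G** — `XX'/p` on markers centered and scaled column-wise to sample
  (n−1) standard deviation 1. Zero-variance markers are dropped with a
  warning by default (policy `error` available).
* **K** — Gaussian kernel `exp(−d²_ij / (h·med))`, `d²` the squared
  Euclidean marker distance, `med` the median of the strictly
  upper-triangular squared distances. The diagonal's structural zeros are
  excluded from the median: including the n zeros would shrink the
  bandwidth as n grows for no statistical reason. `h` (`bandwidth_scale`,
  default 1) generalizes the median heuristic without changing it.
* **C / P** — from `KA = K × A`: C symmetrizes the strictly upper
  triangular part, P the strictly lower; both take the original KA
  diagonal and divide by its mean. "Triangular part" is strict because
  the diagonal is handled separately — including it would double it.
  The two satisfy `mean(diag(KA))·(C+P) = KA + (KA)'` exactly.

### PSD repair

C and P are not PSD by construction. On family-structured data they are
strongly indefinite — we observe smallest eigenvalues around −12 against
a mean diagonal of 1 at n=300, because K's dominant eigenvector (close to
the all-ones direction, with eigenvalue of order 0.3·n) interacts with
A's different leading structure, and symmetrizing one triangle of a
nearly-rank-one non-symmetric matrix produces large negative curvature.
Two repairs are provided. *Jitter* adds `(|λ_min|+tol)·I`; with λ_min of
this magnitude it turns C into ≈0.93·I + 0.07·C after rescaling — an
almost-white kernel whose effect is statistically indistinguishable from
the residual. *Eigenvalue clipping* (reconstruct with negative
eigenvalues at 0, rescale to preserve the mean diagonal) keeps the
kernel's structure and is therefore the default everywhere; jitter
remains available for mildly indefinite matrices. Validity reports
(smallest eigenvalue, symmetry deviation, repair applied) are always
produced.

## Priors

Every scalar variance component has a scaled-inverse-χ² prior with
df = 5. Scales are mode-matched: the prior mode of each genetic variance
is `prior_R2 · var(y) / (number of kernels)` and the residual mode is
`(1 − prior_R2) · var(y)`, with `prior_R2 = 0.5` — the documented
convention of standard Bayesian genomic-prediction software, splitting a
prior heritability equally across kernels.

Balanced multi-environment fits use inverse-Wishart priors for `U_k` and
`R` with df = m+4 and the scale set so the prior **mode** is
`prior_R2 · diag(var(y_j)) / (number of kernels)` (mode of IW(ν,S) is
S/(ν+m+1)). Mode-matching with df = m+4 was chosen over mean-matching
with df = m+2 because at m = 1 it reduces *exactly* to the
single-environment prior, so the multi-trait machinery on one
environment reproduces the single-environment posterior, prior included —
with mean-matched df = m+2 the two posteriors differ by ~15% in the
variance components at n=200, an artifact of prior disagreement rather
than of either sampler.

## Samplers

Each kernel is eigendecomposed once (`K = QΛQ'`, eigenvalues below 1e-10
truncated, the corresponding coordinates pinned at 0) and effects are
updated in the rotated basis where the full conditional is diagonal:
O(n²) per kernel per iteration.

Naive one-at-a-time Gibbs (effects, then variances, then intercept)
mixes pathologically slowly here, for two reasons: the kernels' leading
eigenvectors are nearly parallel to the all-ones vector, confounding
each effect with the intercept; and collinear kernels make the variance
split a long flat ridge that conditional variance updates traverse in
tiny steps (chains need >100k iterations just to leave their
initialization basin). Two blocked updates fix this:

1. **Collapsed variance updates.** Each `sigma2_k` is slice-sampled from
   its marginal posterior with the effect vector *and* the intercept(s)
   integrated out analytically — all terms are O(rank) in the eigenbasis
   (plus an m×m solve for per-environment intercepts). The effect block
   is then redrawn given the new variance, making the pair a valid joint
   Gibbs block.
2. **Intercept-collapsed effect draws.** Effects are drawn from their
   conditional with the intercept(s) marginalized (rank-one Woodbury
   correction; rank-m for per-environment intercepts, including through
   the residual covariance in the balanced multi-trait sampler), and the
   intercept redrawn afterwards.

Effect posterior means (and predictions) are Rao-Blackwellized: the
conditional means computed during each scan are averaged instead of the
draws. With fixed variance components and complete data this makes the
posterior-mean effects match the closed-form mixed-model (BLUP) solution
essentially to machine precision; a `deterministic` mode replaces draws
by conditional means and converges to the exact joint conditional mean,
which the tests verify against a direct linear solve. Both samplers were
additionally cross-checked against an independent random-walk Metropolis
sampler on the marginal likelihood (effects integrated out by dense
Cholesky): posterior means agree within Monte Carlo error.

Balanced-mode `U_k` and `R` keep conjugate inverse-Wishart conditional
updates (a matrix-variate collapsed update has no comparable closed
form); their chains mix more slowly than the scalar-variance chains, and
reported Monte Carlo standard errors account for this through the
effective sample size. Missing phenotypes are latent variables redrawn
each iteration from their predictive distribution (data augmentation) —
in the balanced sampler from the residual conditional normal within each
genotype's row, grouped by missingness pattern — so masked cells acquire
genuine posterior predictive means. Convergence diagnostics (ESS,
split-chain R-hat, MCSE) are computed for every stored chain and logged,
not enforced.

Default run length is 50,000 iterations, 5,000 burn-in, thinning 5 — the
convention for the real-trial analyses this package targets. The test
suite and acceptance script use 6,000/1,000/5, which the collapsed
sampler makes sufficient (ESS ≈ 400–600 per variance chain at n=300).
Identical seeds and inputs give bit-identical chains.

## Environment covariance E

The unbalanced Hadamard form needs an `E`. When not supplied by file, it
is estimated as pairwise Pearson correlations of phenotypes over shared
genotypes, shrunk halfway toward compound symmetry
(`E = (1−s)·Ê + s·(r̄J + (1−r̄)I)`, default s = 0.5), with
insufficient-overlap pairs filled by the mean off-diagonal correlation
and a final PSD repair by eigenvalue clipping. In cross-validation, E is
re-estimated per replicate from the unmasked portion. This default is
logged prominently; a user-supplied E overrides it.

## Evaluation

Repeated k-fold CV over genotypes for S-models (5-fold × 4 or 2-fold ×
10 — twenty training/testing splits either way; remainders spread one
per fold) and environment-masking scenarios for M-models (keep
`round(f·n_env)` records of a target environment, predict the rest, all
other environments observed; f = 0.20 or 0.05, repeated with fresh
subsets). Metrics are the per-fold Pearson correlation and PMSE; AVG is
the mean of per-fold correlations (raw — no Fisher-z, matching the
field's reporting convention), SE their sd over folds divided by
√(#folds), intervals AVG ± 1.96·SE, and percent difference
`100·(AVG − AVG_base)/AVG_base` against a baseline model. Fold and mask
assignments depend only on the scheme seed, never on the model, so all
model comparisons are paired; MCMC seeds derive deterministically from
(scheme seed, replicate, fold, model), making whole experiments
bit-reproducible.

## Synthetic data

The generator emulates elite-yield-trial structure: a random-mating
pedigree over a small founder pool (default 40 founders, 3 offspring
generations, 600 genotypes), SNP dosages gene-dropped down that pedigree
(founder haplotypes Bernoulli(q_m), q_m uniform on 0.05–0.95), kernels
A/G/K/C/P built from those markers and pedigree, and phenotypes drawn
from the fitted models' own generative forms with known variance
components. The default components (A 0.20, K 0.45, C 0.35, P 0.25,
residual 0.20) sit in the ranges estimated on real elite yield trials —
inspired by, not equal to, any published estimates. Multi-environment
phenotypes use compound-symmetry `U_k = sigma2_k[(1−ρ)I + ρJ]` (ρ = 0.5
by default) and a diagonal residual covariance; a `missing_pattern`
fraction of cells is deleted at random for unbalanced designs (keeping
every genotype in at least one environment).

What the generator does **not** emulate: linkage disequilibrium, marker
ascertainment, selection, genotyping error, and spatial/field trends in
the phenotypes. Passing tests therefore demonstrate correctness of the
algorithms and calibration under the model's own assumptions, not
robustness to real-data artifacts.

Test and acceptance problem sizes (n = 200–300 genotypes, p = 2000
markers, founder pool n/15, chains 6,000/1,000/5, 10–20 replicates) are
the package's working scale for simulation studies; the API handles the
full trial scale (n ≈ 1200, p ≈ 18k, 50k iterations) with the same code
paths.

## Identifiability of the S5 variance split

The Gaussian kernel decomposes into a few large structured eigenvalues
plus a near-flat bulk; that bulk acts like a multiple of the identity,
so part of `sigma2_K` is statistically confounded with `sigma2_eps` (and
similarly, to a lesser degree, for the other kernels). Consequences,
verified with an independent marginal-likelihood sampler:

* predictions and the *total* genetic signal are well identified — the
  S5-vs-GBLUP accuracy comparison is stable;
* the individual variance components of S5 have a flat ridge: on data
  simulated from S5's own generative model at n=300, the exact posterior
  places the true `sigma2_K` / `sigma2_eps` more than 2 posterior sd
  from the truth in roughly a third of replicates (the prior decides the
  split along the ridge), while the two-component S2 model recovers its
  variances at the nominal ~95% rate.

This is a property of the model class under family-structured kernels,
not of the sampler; S5 variance components should be read as a
decomposition under the model's prior, not as separately estimable
quantities.

## Degenerate inputs and numerical choices

Zero-variance markers: dropped (default) or error. All genotypes
identical: the Gaussian kernel bandwidth is undefined — error. Kernel
asymmetry beyond 1e-8: error. Constant phenotypes: variance posteriors
collapse toward the prior scale and predictions stay flat. Constant
effect vectors in the correlation report: NaN. Genotype ids are matched
by exact string comparison across all inputs (no fuzzy matching); kernel
files round-trip bit-stably at 17 significant digits.
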