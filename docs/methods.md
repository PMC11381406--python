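# Methods

## Input model and trait summary

The pipeline consumes a long-format table of replicated single-trait
measurements: one row per (genotype, condition, replicate), conditions
`control` and `stress`, trait values finite and non-negative (dry weight in
mg by convention, but any positive trait in consistent units works).  Every
genotype must be observed under both conditions; missing cells are dropped,
never imputed, and a genotype is excluded only if a whole condition is
empty.  No outlier rejection is performed among replicates.

Per-genotype condition means C and T are replicate means; population means
C̄ and T̄ are **unweighted** means of the genotype means, even when
replicate counts differ, because the index definitions treat each genotype
as one unit.  The coefficient of variation is computed over genotype means
(sample SD, n−1 denominator), i.e. between-genotype variation — published
screens report CV "among germplasms", and the replicate-level CV would
conflate measurement noise with genetic variation.  The control/stress
comparison is a paired two-sided t-test on (C_g, T_g); a zero-variance
difference vector is flagged degenerate with p = 1 by convention.

## Classical stress indices

DC = T/C, GMP = √(TC), MP = (T+C)/2, SSI = (1 − T/C)/(1 − T̄/C̄),
STI = CT/C̄², TOL = C − T, all computed from genotype means, never per
replicate.  Useful identities follow directly and are enforced as tested
invariants at 1e-9 relative tolerance: STI = (GMP/C̄)², TOL = C(1 − DC),
SSI = (1 − DC)/(1 − T̄/C̄), GMP ≤ MP (AM–GM), mean(MP) = (C̄ + T̄)/2 and
mean(TOL) = C̄ − T̄.

T = 0 is legal (DC = GMP = STI = 0).  C = 0 leaves DC and SSI undefined;
the policy is configurable: abort (default) or exclude the genotype with a
logged warning.  DC > 1 (weight gain under stress) is mathematically fine —
SSI and TOL simply go negative — and flows through normalization naturally.
A population with T̄ = C̄ makes SSI undefined and aborts.

## Normalization and the PI/EI composites

Positively oriented indices use xₙ = (x − x_min)/(x_max − x_min); SSI and
TOL use the reversing map yₙ = (y_max − y)/(y_max − y_min), so that after
scaling 1 always means most drought-adapted.  Bounds are the observed
extremes of the analysed population, recomputed per run and written to a
sidecar JSON so separate runs can be compared.  A constant column aborts by
default (an index with no variation cannot grade a population); an
`on_degenerate="zeros"` escape hatch exists for exploratory use.

PI = mean(DCₙ, GMPₙ, MPₙ, STIₙ) and EI = mean(SSIₙ, TOLₙ) are unweighted —
no defensible weighting exists without external validation data.  A useful
algebraic fact (and regression test): because SSI is affine-decreasing in
DC for fixed population means in the drought regime (T̄ < C̄), the reversed
scaling cancels the affine map and SSIₙ = DCₙ exactly.  If T̄ > C̄ the
orientation flips (SSIₙ = 1 − DCₙ); the package computes both correctly but
the identity test is restricted to the drought regime.

## PCA-derived SI and II

The six indices are z-scored (sample SD) and the 6×6 **correlation** matrix
is eigen-decomposed (symmetric `eigh`, deterministic — no randomized
solvers).  Correlation rather than covariance is a deliberate choice: the
indices mix unitless ratios (DC, SSI, STI) with trait-unit quantities (GMP,
MP, TOL), and a covariance PCA would be dominated by the large-magnitude
columns.  Scores are projections onto unit-norm eigenvectors, not rescaled
to unit variance; downstream grading uses the observed score range, so this
choice does not affect levels.

Eigenvector signs are fixed semantically: PC1 is flipped so its correlation
with the stress means T is ≥ 0 and becomes SI; PC2 is flipped toward the
control means C and becomes II.  An exactly-zero correlation is resolved by
forcing the largest-magnitude loading positive.  Exactly two components
become indices regardless of eigenvalue magnitudes; all six eigenvalues are
reported as explained-variance percentages (λ/6 × 100).  On synthetic
populations with default settings the intended pattern emerges: SI explains
stress-side trait means far better than II does (R² ≈ 0.99 in the seeded
runs of the test suite), and II explains control-side means better than SI.

OLS diagnostics (slope, intercept, R² = squared Pearson r, p) are computed
for all eight indices against both condition means.  A zero-variance
response yields R² = 0 with a degenerate flag; a zero-variance predictor is
an error.

## Grading, clustering, typing

PI and EI live on [0, 1] and use the fixed bins [0, 0.2) → 1 … [0.8, 1] → 5
(right-open, last bin closed).  SI and II are unbounded scores and use five
equal-width bins over the observed [min, max]; the same boundary convention
is reused for consistency, so the column minimum grades 1 and the maximum
5.  Values are validated against [0, 1] with a 1e-12 slack for floating
round-off from the normalization arithmetic.

Clustering runs on the 4-vector of **levels** (si, ii, pi, ei), not raw
scores — the levels are the published evaluation scale, and clustering on
them makes classes interpretable in the same units as the grades.
Agglomerative hierarchical clustering with Euclidean distance and Ward
linkage is the default (complete/average are configurable); the tree is cut
at k = 2 and classes are relabelled deterministically so class 1 has the
higher mean SI level.  The dendrogram can be exported as newick.

Types use a transparent threshold at level 3 ("medium" or better) on SI and
II: A = both ≥ 3, C = only SI ≥ 3, B = only II ≥ 3, D = neither.  The rule
reproduces every published (SI, II) → type example and makes the partition
exhaustive and exclusive by construction.  Published per-type PI/EI ranges
are data observations, not assignment rules, and are deliberately not
enforced.  Elite lists rank type-A genotypes two ways — production-first by
(si, ii, pi) descending and stability-first by (pi, ei, si) descending —
with genotype-id tie-breaks for determinism.

## Synthetic populations

The generator emulates a 206-genotype screen: per genotype,
C_g ~ LogNormal(mean 746.90 mg, CV 31.54%), DC_g ~ dc_min + (dc_max −
dc_min)·Beta(a, b) on [0.006, 0.962] with mean 0.394, T_g = C_g·DC_g, and
multiplicative log-normal replicate noise (default CV 5%, a typical
balance-and-drying measurement error).  DC is simulated directly rather
than T independently of C because the screening logic is built on the
C → T ratio; this makes the drought effect interpretable and calibratable.
Log-normal rather than Gaussian trait values guarantee positivity — at a
31.5% CV a Gaussian would produce negative weights.

The Beta shapes are a = mκ, b = (1 − m)κ with m the mean mapped to the unit
interval.  The default concentration κ = 4.69 is solved in closed form from
the published CVs: for independent C and DC,
CV_T² = (1 + CV_C²)(1 + CV_DC²) − 1, so matching CV_T = 61.14% given
CV_C = 31.54% and mean DC 0.394 requires sd(DC) ≈ 0.197, i.e.
κ = m(1 − m)/var_unit − 1 ≈ 4.69.  With this default the stress-side CV of
generated populations lands in the 52–71% range across seeds and the
simulated DC min/max approach (without exactly attaining) the configured
bounds.  An optional Gaussian copula correlates C_g and DC_g (default 0:
the model treats productive potential and drought response as independent
axes unless told otherwise).

What the generator does **not** emulate: genotype pedigree structure,
shared-environment (box/batch) effects, heteroscedastic or non-log-normal
measurement error, and any genotype-specific stress mechanism.  Passing
tests therefore demonstrate correctness of the computation and internal
calibration of the model, not biological validity on a particular real
screen.

## Problem sizes and numerics

The test suite exercises ~1000 small random populations (4–25 genotypes)
for the algebraic invariants, 100 seeded 206-genotype populations for
generator calibration, and toy matrices (n ≤ 12) for the brute-force
eigen/clustering oracles — sizes chosen so the full suite runs in seconds
while still covering the asymptotic behaviour the larger published screen
relies on.  All floating outputs are written at 6 significant digits; CSV
is the interchange contract.  Determinism throughout: a single integer seed
drives the generator, and no randomized numerical paths exist elsewhere.

## Known limitations

* Data-dependent published quantities (exact PCA contribution rates, exact
  R², per-level genotype counts, cluster memberships) depend on the
  undeposited raw data and are emulated only qualitatively on synthetic
  populations.
* Min-max bounds and PCA loadings are population-relative: adding or
  removing genotypes changes every normalized value and score.  Bounds and
  loadings are reported per run for this reason.
* The level-3 typing threshold is a transparent rule consistent with every
  published example, but other dendrogram-derived partitions of the same
  data could differ near the boundary.
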