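# Methods

This note documents the statistical machinery implemented in `tpdiv`, the
defaults it ships with, and what the synthetic benchmarks do and do not
demonstrate.

## Functional space

Traits must be strictly positive (masses, lengths, durations, counts);
zero or negative values are rejected rather than offset-shifted, since
the quantities the workflow is designed for are positive by definition.
Each trait is natural-log-transformed, centred, and scaled to unit
standard deviation (ddof = 1), which makes the PCA equivalent to an
eigendecomposition of the log-trait correlation matrix. The base of the
logarithm is irrelevant after scaling. The first D axes are retained;
D defaults to 2 and is a configuration parameter (4 is the appropriate
choice for trait sets with higher intrinsic dimensionality, e.g. fish
morphometrics). No automatic dimensionality selection is attempted.

Axis signs are fixed by making the largest-magnitude loading of each axis
positive, so fitted spaces are reproducible across platforms. The
standardization constants and loadings are frozen in the
`FunctionalSpace` object; later species (e.g. imputed ones) are projected
with `project`, never by refitting.

## Trait probability densities

An assemblage's TPD is the equal-weight mixture of multivariate Gaussian
kernels centred on its species. Two conventions matter for cross-realm
comparability and are enforced by construction:

* **one kernel, one grid.** The bandwidth matrix is fitted once on the
  global species cloud and reused for every realm, subset and null draw;
  the grid is likewise built once (per-dimension bounds = data range
  padded by 5% per side, equal cell widths). Padding fraction 5% is a
  pragmatic default: wide enough that kernels of edge species keep most
  of their mass on the grid at typical bandwidths.
* **midpoint discretization.** A cell's mass is the kernel density at the
  cell centre times the cell volume. Each species' cell-mass vector is
  renormalized to sum to 1 (absorbing edge truncation) *before*
  averaging, so an assemblage TPD is exactly the average of its members'
  single-species TPDs and mixtures are linear. This matches the standard
  practice of the field's reference implementation.

Bandwidth selectors: `normal_reference` (default, exact:
H = n^(−2/(D+4)) Σ̂) and `plugin`, a two-stage direct plug-in applied per
whitened coordinate and rotated back through the Cholesky factor of Σ̂ —
an approximation of the unconstrained multivariate plug-in family. The
selector used is recorded in every run manifest; results in the test
suite use the exact selector so that they cannot hinge on plug-in
numerics.

Grid sizes follow the field's convention: 200 cells per dimension in 2-D
(40,000 cells) and 30 per dimension in 4-D (810,000 cells). The
benchmarks and the acceptance script run at 100 cells per dimension,
which keeps every statistic well within its tolerance at a fraction of
the cost; the pipeline default remains 200.

### Thresholding and quantiles

Raw kernel mixtures are positive almost everywhere, so occupied volume is
only meaningful after outlier trimming. `threshold_tpd` keeps the
smallest set of densest cells whose cumulative mass reaches q (default
0.99 — the 99% highest-density region) and renormalizes. Equal-mass
cells are kept or dropped as whole blocks, so the result does not depend
on sort stability. After renormalization, masses below 1e-15 are zeroed
to keep occupancy masks clean. `quantile_field` re-expresses cell
probabilities as the cumulative mass of all cells at least as dense;
tie blocks share their final cumulative value, dense cells get small
quantiles, and the maximum occupied quantile is 1.

On a 300×300 grid the measured 99% HDR area of a standard bivariate
normal kernel is 28.9378 against the analytic π·χ²₂(0.99) = 28.935 —
a 0.01% discretization error.

## Diversity indices

FRic = occupied cells × cell volume of a *thresholded* TPD (calling it on
an unthresholded density is an error). FRic is reported both in grid
units and as a fraction of the world (all-species) FRic on the same grid.
Functional dissimilarity = 1 − Σ min of two TPDs on the same grid; it is
symmetric, zero iff the mass vectors are equal, and no triangle
inequality is claimed. By default dissimilarities and overlap QA are
computed on thresholded, renormalized spectra (the displayed objects);
both accept raw spectra if passed. Jaccard dissimilarity and endemicity
are the usual set-based quantities; species are weighted equally
throughout (no abundances).

## Null models

Random-assembly nulls draw the observed number of species uniformly
without replacement from the pool and rebuild FRic with the identical
kernel/grid/threshold. SES = (obs − null mean)/null SD. The rank p-value
uses the mid-rank of the observation within {nulls ∪ obs} divided by
(reps + 1); mid-ranking makes the 0.975/0.025 significance rule
attainable and symmetric, which a bare "count of nulls below" would not.
With the observation itself drawn from the pool, replicate p-values are
uniform (KS test) and |SES| ≤ 2 in ≈95–96% of replicates on the default
synthetic benchmark.

Realm-level SES distributions for pairwise comparison are obtained by
bootstrap: 99 SES values, each against a without-replacement subsample of
99 of the 999 null values (both counts configurable). All-pairs Welch t
tests with Holm correction feed an insert-absorb compact letter display;
by construction, two realms share a letter exactly when their difference
is not significant at the chosen level (5% default). The choice of Welch
t with Holm is recorded in output metadata and pluggable; no particular
test is canonical for this step.

## Extinction scenarios

The baseline pool is all IUCN-assessed species (everything except NE; DD
species are part of the baseline and removed only by −DD). Scenarios
remove whole categories cumulatively: −CR ⊂ −EN ⊂ −VU ⊂ −NT ⊂ −DD.
Before/after spectra use the shared kernel and grid and the same
threshold; loss % = 100·(FRic_before − FRic_after)/FRic_before. Because
thresholding is applied to both spectra, removing an extreme species can
occasionally *enlarge* the survivor HDR and produce a marginally negative
loss; the raw value is reported, never clamped. δT = n_removed/n_assessed
exactly; δF = lost cells / cells occupied before.

Shift maps subtract quantile values (before − after) on cells occupied in
either spectrum; a cell unoccupied on one side takes quantile 1 there
(the limit of the least-dense occupied cell), so lost cells are always
negative and separately flagged. The mean absolute quantile change is
averaged over the cells occupied before extinction (the "across cells"
averaging set is ambiguous in principle; occupied-before is the adopted
convention and the lost-cell mask preserves the alternative reading).

The randomized-identity null removes the same number of species uniformly
from the assessed pool and recomputes the loss 999 times (199 in the
fast benchmarks); the 95% interval is the empirical 2.5–97.5 percentile
band, with SES/p as above. The hot loop reuses cached per-species cell
masses; caching is exact (averaging cached rows), not an approximation.

## Imputation

Iterative random-forest imputation: initialize missing cells with column
means; sweep traits in order of increasing missingness, regressing each
trait's observed cells on all other columns and re-predicting its missing
cells; stop when the standardized change between successive imputations
(Σ(new − old)²/Σnew² over imputed cells) first increases, returning the
previous iterate. Forests use 100 trees and mtry = ⌈p/3⌉ (the canonical
defaults for this procedure), both configurable. Observed cells pass
through bit-identically.

Phylogenetic position enters as the first k = 10 eigenvectors of
−½ J D² J, where D is the patristic distance matrix — a principal
coordinates embedding of the tree, scaled by √eigenvalue and sign-fixed.
With several candidate trees, per-tree eigenvectors are sign-aligned to
the first tree and averaged. Species absent from the tree are an error
by default (silently giving them mean eigenvector rows is opt-in by
passing a completed eigenvector table); grafting onto genus roots is out
of scope.

Validation is in *position* space, because the goal is placing species in
the functional space rather than recovering raw trait values: a fraction
(default 10%) of the complete species get missingness patterns copied
from genuinely incomplete rows, are pooled with those rows, imputed, and
projected; NRMSE per dimension = RMSE of the position error / occupied
range of the dimension, averaged over (default 100) repetitions with its
standard error. On Brownian-motion traits over a 200-tip birth-death
tree with 20% of species masked, true eigenvectors beat row-shuffled
eigenvectors in ≥95/100 repetitions and the NRMSE standard error is
under 5% of its mean — phylogenetic signal is both present and
exploitable. On uniform positions, mean-imputation gives the closed-form
NRMSE 1/√12 ≈ 0.289, a useful floor for judging imputers.

## Synthetic worlds

The generator emulates the statistical structure the analyses assume:
log-normal trait clouds clustered around a few archetype strategies
(centres standard normal per log-trait; within-cluster log-SD 0.4 by
default — visibly clumped hotspots), realm memberships with a tunable
expected sharing fraction, and IUCN categories whose threatened block
(CR/EN/VU/NT) can be tilted toward large values of the first trait with
a logistic link (log-odds `threat_bias` per SD of the log trait; the
body-size/pace-of-life axis of real threat patterns). With zero bias the
marginal category frequencies equal the configured probabilities exactly.
The default category mix (CR .05, EN .08, VU .12, NT .08, LC .47, DD
.12, NE .08) approximates the global Red List composition for
vertebrates, with non-trivial DD and NE shares so the coverage-QA paths
are exercised. Brownian traits on birth-death trees provide known
phylogenetic signal for the imputation benchmarks.

What the synthetic worlds do *not* emulate: spatially explicit ranges,
realistic trait covariance structure within groups, category-specific
threat geographies, taxonomic error, or observation effort gradients.
Passing benchmarks therefore demonstrates the correctness and calibration
of the machinery under its own assumptions, not the field accuracy of any
particular empirical estimate.

Benchmark problem sizes (chosen as the smallest at which the measured
statistics are stable): calibration uses a 300-species pool, draws of 80,
199 null repetitions, 200 replicates on a 100² grid; scenario recovery
uses 100 worlds of 250 species with 2 traits (so the threat axis lies
fully inside the analyzed plane) and `threat_bias = 8` as the "strong
association" condition; imputation uses one 200-tip world with 100
masking repetitions.

## Numerical conventions and edge cases

* Ties in mass are processed as atomic blocks everywhere (threshold,
  quantiles), making results independent of sort order.
* Coordinate cleaning uses strict float equality for the
  latitude == longitude filter (it targets data-entry artefacts;
  pre-round coordinates if that is too strict for your data). Museum
  (preserved), captive (living) and unknown-provenance records are
  dropped — deliberately conservative relative to common practice.
* IUCN categories outside CR/EN/VU/NT/LC/DD/NE (e.g. EX/EW) are rejected
  at read time; the category set is closed by design.
* Degenerate nulls (zero spread, e.g. drawing the whole pool) are flagged
  and SES is refused rather than returned as ±inf.
* A single global seed is fanned out to per-stage child seeds via
  `SeedSequence.spawn` in a fixed stage order; the run manifest records
  the seed, all parameters, the bandwidth selector and a kernel checksum,
  and reruns are byte-identical.

## Known limitations

* The plug-in bandwidth is an approximation of the unconstrained
  multivariate plug-in, not a re-derivation of any specific
  implementation; analyses that must match a particular selector should
  fit H externally and pass it in via `KernelConfig`.
* Memory for cached per-species masses scales as n_species × n_cells;
  at the 4-D default (810,000 cells) cache only the pools you need.
* Occurrence handling consumes realm labels; polygon overlay of
  coordinates onto realm shapefiles is out of scope (a rectangular-box
  helper exists for tests).
* Categorical traits are not supported in imputation.
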