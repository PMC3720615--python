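# Methods

This note records the modelling conventions, defaults and numerical
choices behind `latgrad`, and what the synthetic tests do and do not
demonstrate about real data.

## Root distance convention

Root distance (RD) is the count of internal nodes on the path from the
root to a tip, counting the root and excluding the tip; equivalently the
tip's edge depth. Both tips of `(A,B);` have RD 1. The alternative
convention (excluding the root) differs by a constant, and because cell
MRD is an arithmetic mean, any constant offset shifts every defined MRD
by exactly that constant — correlations, smooth-model shapes and quartile
membership are all invariant. The convention is therefore documented and
tested rather than configurable. Branch lengths present in a Newick
input are parsed but ignored: RD is deliberately a topology-only metric,
usable when divergence times are absent or unreliable.

Species matching between occurrence data and tree tips normalizes case
and space/underscore separators only. No fuzzy matching: a genuinely
different spelling surfaces in the drop report (with counts), never as a
silent pairing.

## Quartile decomposition

Basal = species with RD ≤ Q1, derived = species with RD ≥ Q3, where Q1
and Q3 are linear-interpolation empirical quartiles (index h = p(n−1) on
the sorted sample, numpy's default). The estimator matters because RD
values are small integers with heavy ties; with ties included on both
sides each set holds at least 25% of species, and when every RD is equal
both sets are the whole fauna. This degenerate case is accepted, not an
error.

## Grid and projection

The analysis grid is built in a Lambert cylindrical equal-area projection
on a spherical Earth (R = 6371.0088 km), standard parallel 30°, central
meridian defaulting to the domain's longitude center. Equal area holds
exactly on the sphere, so every 100 × 100 km projected cell samples the
same geographic area; the residual shape distortion away from 30° is
irrelevant to counts and planar distances. The projection is a plain
closed form (x = R cosφₛ Δλ, y = R sinφ / cosφₛ) implemented directly.
Grid origins are snapped down to multiples of the cell size in projected
coordinates, so grids over nested bounding boxes (same projection) share
cell boundaries.

Occupancy uses the positive-area rule: a species is present in a cell iff
its projected range intersects the cell square with positive area. This
is the common convention for gridding expert range maps and is the
default; a center-in-polygon rule is available (`rule="center"`).
Polygons are projected vertex-wise; for lon/lat-aligned rectangles the
cylindrical projection maps edges to straight lines, so no densification
is needed. Cells with zero total richness are written but flagged and
excluded from every statistical stage. No coastline mask is applied by
default (the synthetic domain has none); all cells are weighted equally.

## Smooth latitude models

The smoother is a P-spline: cubic B-spline basis of dimension k = 10 on
equally spaced knots extended (not clamped) beyond the data range, with a
second-order difference penalty on the coefficients. Unclamped equal
spacing makes the Greville abscissae equally spaced, so the penalty null
space is exactly the linear functions: λ → ∞ recovers the OLS line
(verified to 1e−6 on the deviance-explained scale), and effective degrees
of freedom run from 2 to k. The predictor is signed latitude in degrees;
because the basis depends only on the affinely standardized predictor,
fits are exactly invariant to affine rescalings of latitude.

λ is selected by generalized cross-validation over a 49-point log grid
(1e−6 … 1e10), with the df term inflated: GCV(λ) = n·Dev/(n − γ·edf)²
with γ = 2.5. Plain GCV (γ = 1) occasionally undersmooths pure noise
severely, which makes the downstream smooth-term test anticonservative
(type-I error ≈ 0.12 at nominal 0.05 in our null simulations at n = 500);
df-cost inflation is the standard remedy, and γ = 2.5 brings the
empirical type-I error to ≈ 0.065–0.07 while leaving strong-signal fits
(exact linear data, sine recovery) unchanged.

Families: gaussian/identity is the default for both richness and MRD;
poisson/log is available for counts via configuration (penalized IRLS,
same basis and penalty). The smooth-term p-value is an approximate test
against the intercept-only model: an F statistic with df₁ = edf − 1 and
df₂ = n − edf for gaussian, and a deviance-difference χ² with df = edf − 1
for poisson. Constant responses define deviance explained as 0 and p = 1.
Fit quality is summarized as deviance explained, 1 − D/D₀.

Numerical details: penalized normal equations are solved by Cholesky with
a tiny ridge jitter scaled to the *data* block only (a jitter scaled to
the penalty would bias the unpenalized linear directions at large λ);
edf = tr[(BᵀWB + λP)⁻¹BᵀWB]. GCV ties prefer the smaller λ.

## Moran's I correlograms

Distance classes default to 10 equal-width bins from 0 to the maximum
pairwise distance between cell centers (planar distances in the
equal-area projection, km); an equal-pair-count quantile binning is
available. Intervals are half-open except the last, which is closed so
the extreme pair is binned. Weights are binary and symmetric within a
class, with no row standardization — the classical distance-class
correlogram. Per class,

  I = (n/S₀) Σᵢ≠ⱼ wᵢⱼ zᵢ zⱼ / Σᵢ zᵢ² ,  z = x − x̄ .

Significance is Monte-Carlo: values are randomly reassigned to cells
(default 200 permutations), two-sided p = (1 + #{|I_perm| ≥ |I_obs|}) /
(n_perm + 1). The +1 correction keeps p > 0 and makes the smallest
attainable p equal to 1/201 at the default; one-sided alternatives are
exposed. Under this null E[I] = −1/(n−1), verified by simulation.
Zero-variance inputs (e.g. residuals of an exact fit) flag every class
undefined rather than erroring the pipeline.

Pair storage is O(n²), so correlograms subsample to at most 3000 cells
(seeded, recorded in the output metadata) when the occupied-cell count
exceeds that.

## Model-II comparison of richness surfaces

The correlograms entering the total-vs-basal/derived comparison are
computed on richness values, not residuals. The regression takes
x = total's Moran's I per class, y = the subset's, so a slope near 1
with high R² means the subset reproduces the total's spatial structure;
a direction swap is exposed (for RMA only the slope's reciprocal
changes). Both reduced-major-axis (slope = sign(r)·sd(y)/sd(x), default)
and major-axis (principal eigenvector of the 2×2 covariance) estimators
are implemented, because the two names denote different estimators and
published usage conflates them; outputs record which was used. With
r = 0 the RMA sign convention is positive, flagged. Standard errors of
slope and R² are one-delete jackknife over the distance classes,
SE = sqrt(((n−1)/n)·Σ(θ₍ᵢ₎ − θ̄)²); degenerate leave-one-out replicates
are excluded and counted. Per-cell Pearson correlations are computed
over occupied cells (total richness ≥ 1), so cells lacking the subset
contribute zeros.

## Synthetic scenarios

The generator emulates the statistical structure the analysis assumes,
not the geography:

- **Trees**: Yule (pure-birth) topologies — starting from two tips, a
  uniformly chosen extant tip splits until n tips. Each non-root internal
  node is then collapsed into its parent with probability
  `polytomy_prob` (default 0.1), producing supertree-like polytomies.
  Branch lengths are not simulated; nothing downstream uses them.
- **Ranges**: one axis-aligned rectangle per species, centroid ±
  half-width, clipped to the bounding box (default −120…−35°E,
  −55…55°N, a New World-like extent). Half-widths are log-normal
  (log-mean 1.5, log-sd 0.8: median ≈ 4.5°, i.e. ~500 km, spanning
  orders of magnitude in area — the scale of widespread continental
  species). The truth table records the pre-clipping centroid.
- **Richness gradient**: centroid latitudes are drawn with density
  ∝ exp(−g·(lat/halfspan)²) — exactly uniform at g = 0, increasingly
  equator-concentrated as g grows (default g = 2).
- **RD–latitude coupling**: the pairing between species and |centroid
  latitude| is rank-matched through a Gaussian copula with normal-score
  correlation 2·sin(πc/6), so the realized corr(RD, |lat|) approaches
  the requested coupling c for any marginals (verified to ±0.1 over 20
  seeds at n = 300 for c ∈ {−0.8, 0, 0.8}). Negative c concentrates
  derived species near the equator. Default c = −0.8.

All randomness flows from one scenario seed; identical scenarios produce
byte-identical files. In the pipeline, a master seed is split per stage
via `numpy.random.SeedSequence`.

What the rectangles do not emulate: coastlines and continental shape,
range cohesion and fragmentation, richness levels driven by massive
range overlap, and environmental covariates. Consequently the synthetic
comparison stage reproduces the regime typical of real faunas
(subset-vs-total RMA slopes near 1, strong positive Pearson
correlations) only when the shared latitudinal structure dominates
subset-specific noise — the tests use a strongly
structured variant (gradient 6, log-mean half-width 2.2) for that
property, and under a strong negative RD–latitude coupling the basal
surface genuinely decouples from the total. Passing tests demonstrate
that the machinery recovers known structure under the generator's
assumptions, not that any empirical fauna satisfies them.

## Problem sizes used in the checks

End-to-end checks run at the design scale: 305 (or 300) species on the
full domain (~10 000 cells, ~9 700 occupied), correlograms on a seeded
3000-cell subsample with 200 permutations. Calibration simulations use
1000 replicates (smooth-term test at n = 500; permutation test on a
15 × 15 grid). Unit fixtures are far smaller (40–50 species on a narrow
strip) to keep the suite fast.

## Known limitations

- MRD averages only RD-matched species; cells whose entire fauna lacks
  tree placements are undefined and excluded (with reported drop counts).
- The smooth-term p-value is approximate (selection-then-test); it is
  calibrated by simulation at the defaults, not exact.
- The poisson family's GCV uses the deviance-based score; no
  quasi-likelihood overdispersion correction is offered.
- Model-II comparisons across distance classes treat classes as
  independent observations in the jackknife, as is conventional, though
  neighbouring classes share cells.
- Projected planar distances, not great-circle distances, define the
  distance classes; consistent with the grid's construction but
  increasingly distorted for domains far wider than the default.
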