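# Methods

## The niche model

The core estimator is a presence-background maximum-entropy model of
the Maxent family. Let C be the set of landscape cells available to a
modelling unit (its target-group background plus its presence cells),
and f(x) a vector of features of the environmental values at cell x.
The model is the Gibbs density

    p_w(x) = exp(w · f(x)) / Z(w),    Z(w) = Σ_{c ∈ C} exp(w · f(c)),

fitted by maximizing the penalized average presence log-likelihood

    (1/m) Σ_presences w · f(x_i) − log Z(w) − Σ_j λ_j |w_j|.

Features are the classic repertoire: per variable a linear and a
quadratic term (on internally standardized values, which makes
prediction invariant to affine rescaling of any input), pairwise
products of standardized values, and forward/reverse hinge ramps at 10
evenly spaced knots per variable per direction, normalized to [0, 1]
over the training range. Product features are suppressed for units
that are both data-sparse (< 80 records) and range-restricted
(background buffer at the 1000 km minimum clamp) to curb overfitting;
"range-restricted" is interpreted as buffer-at-minimum because a buffer
below the minimum cannot occur by construction.

The per-feature penalty is λ_j = β · sd(f_j) / √m with β = 1 (features
are standardized internally, so λ_j = β/√m on the fitted scale). This
mirrors the spirit of Maxent's default regularization without
reproducing its feature-class-specific β tables. Optimization uses
L-BFGS-B on the split w = w⁺ − w⁻ (bounds ≥ 0, making the L1 term
smooth), tolerance 1e-8 on the objective, at most 500 iterations;
non-convergence raises an error carrying the iteration count.

Output is the Maxent logistic transform with default prevalence 0.5:
`c·p/(1 + c·p)` where c = e^H and H is the entropy of the fitted density
over the training cells. Projection clamps every variable to its
training [min, max] before computing features, so projections (current
or future) never extrapolate; nodata cells propagate as nodata.

Evaluation uses 10 repeated random 70/30 presence splits (the
"10-fold cross validation using 70% training and 30% test" design is
internally contradictory; repeated 70/30 splits match the stated
percentages), with the background shared across replicates. Permutation
importance is the drop in training AUC when a variable's column is
permuted across presence and background rows jointly, averaged over
permutations and over the 10 CV replicates, clipped at zero and
normalized to sum to 100%.

## Variable screening

Candidate variables are screened on background-sample values (not full
rasters): pairs with |Pearson r| > 0.8 lose their lower-priority member
(priority = column order unless given), except pairs explicitly named
in `keep_overrides`; zero-variance columns are dropped with a warning.
After the starting model, the reduced variable set keeps the top five
by importance unconditionally, plus any variable with importance ≥ 1%
and rank ≤ floor(n_records/20). Ties in importance break by variable
name; rank caps use floor. With five or fewer candidates everything is
kept.

## Thresholding

The "balance training omission, predicted area and threshold" rule is
implemented with the published Maxent objective: t* minimizes

    6·trainingOmission(t) + 0.04·cumulative(t) + 1.6·fractionalArea(t)

over all observed training scores, where cumulative(t) is the
percentage of fitted raw density below t (the cumulative output
format). Cells below t* are set to 0 and the grid is min-max rescaled
over the thresholded values, so the maximum is exactly 1 and outputs of
models with different thresholds are comparable. Change metrics between
time steps are computed on thresholded grids *before* rescaling, so
that totals at different time steps share one scale; the rescaled
version is what gets written per species.

## Cost-distance restriction and MU splitting

Accumulated cost distance is a multi-source shortest path on the
8-connected cell lattice: per-cell resistance r = 1/max(suitability,
floor) with floor 1e-6, edge cost = step length (1 rook, √2 diagonal) ×
(r_i + r_j)/2, zero at occurrence cells. One cost-distance unit (CDU)
is therefore one rook step through perfect habitat; the 500-CDU cut
scales with grid resolution and its default is meant for 0.01° cells.
The phrase "cost proportionate to habitat suitability" is read as
resistance inverse to suitability — taking it literally would make good
habitat costly to traverse, contradicting the purpose of the
restriction. Costs are computed on the raw (pre-threshold) surface
restricted to the background extent: thresholding first would create
infinite-resistance barriers.

Cells with cost > 500 CDU are zeroed (the cell at exactly 500 is kept);
the unrestricted raster is retained alongside, since both versions are
published. Multi-species MUs are split by assigning each cell to the
species with the lowest cost distance, with an overlap allowance of
500 CDU: where the two nearest species both fall inside the allowance,
species s is weighted w_s = cd_other/(cd_s + cd_other) (both 50% at
equal cost distances; the nearest species keeps weight 1 when no other
is within the allowance). When more than two species fall inside the
allowance the rule applies to the two nearest and the rest are
excluded — the published rule only defines the two-species case, and
this generalization preserves its pairwise weight conservation.
Downweighted cells that drop below the original threshold are re-set
to 0 (with rescaled grids the threshold is carried over as t*/max).

## SHOI and summaries

SHOI = suitability × ln(1 + population per cell). The +1 shift is a
deliberate deviation from a bare log: ln(pop) is undefined at zero and
negative below one person per cell, whereas ln(1+pop) preserves both
the zero-population null (SHOI = 0) and monotonicity. Group rasters
take the cellwise maximum over species whose apparent overlaps are
transition zones (suitability not additive); cumulative rasters take
the cellwise sum; richness counts species with thresholded
suitability > 0.

## Projections, change metrics and shift vectors

Future climates enter as per-GCM layer stacks; only designated climate
layers change, all others are held constant. The ensemble is summarized
cellwise by the median, 10% and 90% quantiles (linear-interpolation
quantile). Change metrics (range size, expansion = newly suitable
cells, contraction = newly unsuitable cells, total suitability, total
SHOI) are computed per quantile against the current thresholded grid,
with the current cost-distance restriction applied to the future grids
as well; "suitable" always means post-threshold value > 0.

Distribution centroids are plain means of suitable cell-centre
coordinates in unprojected lon/lat — faithful to the source procedure
despite its metric distortion at high latitude. Shift distance is the
haversine great-circle distance on a sphere of radius 6,371,000 m;
direction is the initial bearing from the two-argument arctangent,
in (−180°, 180°]. Regional summaries take the circular median of
bearings (minimizer of summed circular distance, searched over the
observations and all pairwise shorter-arc midpoints, ties broken
toward the circular mean — this yields the arc midpoint for two-point
samples) and the ordinary median of lengths.

## Validation

AUC is the rank-based probability that a presence outscores a
background point (ties ½). Partial ROC runs 39 iterations: each draws
50% of the occurrences and an equal number of random landscape cells,
builds both (fractional predicted area, 1 − omission) curves over
thresholds at every 1% of predicted area, and takes the ratio of the
two curve areas; the p-value is the fraction of iterations with
ratio ≤ 1 (one-sided). No omission-error cap is applied — the plain
description of the procedure, not the capped E-variant. EDR comparison
rasterizes polygons by cell-centre containment; commission and
congruence partition the suitable cells (summing to 100%), omission is
the percentage of EDR cells predicted unsuitable.

## The synthetic-data generator

The generator emulates the statistical features the pipeline must
handle, not real climate or snake biology:

- **Environmental layers**: Gaussian-filtered white noise (bandwidth
  σ = 8 cells), standardized; designed collinear pairs are built as
  layer + independent smoothed noise (sd 0.35, giving empirical
  r ≈ 0.94) so the collinearity screen always has work to do.
- **Truth surfaces**: logistic in linear and quadratic layer terms.
- **Occurrences**: cells sampled ∝ truth × bias, jittered within the
  cell; lognormal positional uncertainty with median 100 m (σ = 0.75),
  giving the accuracy filter a realistic spread. The default bias field
  is a smooth west–east "road access" gradient with mild ripple.
- **Population**: lognormal-amplitude Gaussian hotspots (median
  amplitude 500 people/cell, σ = 1, spread 4 cells) over a thin
  exponential background — clustered and right-skewed like settlement
  rasters.
- **Futures**: designated climate layers get a shared mean delta plus
  per-GCM smoothed noise (sd 0.1); everything else is carried over
  unchanged. Seven GCMs by default.
- **EDR polygons**: the union of cells whose truth value reaches a
  cutoff (default 0.5).

The parameter-recovery harness uses a 200×200 landscape, 200 biased
presences, and a truth surface concentrated on roughly 15% of the
landscape (linear coefficients 5 and 3 on two climate layers, one
quadratic optimum, intercept −4) — a range-restricted species, the
regime where presence-background discrimination is informative; with a
niche much broader than this, held-out AUC is bounded well below 0.9
by prevalence alone, for any estimator. What these tests show is that
the chain is self-consistent and recovers a knowable niche under
controlled bias; they do not show robustness to real-data pathologies
(taxonomic error, spatially structured detection, non-stationary
niches, correlated future climate fields).

All generators are bit-reproducible from (grid spec, seed), and the
full pipeline is byte-for-byte reproducible from (config, seed);
manifests record seeds, not timestamps.

## Occurrence filters: decisions on under-specified points

- The 75% accuracy cut is applied per species, with only the
  < 20-record exemption (the "poorly sampled regions" exemption in the
  source is dataset-specific expert knowledge).
- The cut keeps floor(0.75·n) records; ties in uncertainty break by
  record order. Cell dedup keeps the lowest-uncertainty record, ties
  by file order.
- Cell (0,0) is the north-west corner; a point belongs to the cell
  whose half-open [west, east) × (south, north] interval contains it.

## Problem sizes

The shipped analysis uses a 120×120-cell landscape with two MUs and
seven GCMs; the recovery experiment uses 200×200 cells. These sizes
exercise every code path — including ensemble summaries, MU splitting
and regional circular statistics — while keeping a full run in
seconds to minutes on one CPU. All scalar defaults (0.8 correlation
cut, 1000/3000 km clamps, 500 CDU, top-5/1%/n÷20 reduction, 10×70/30
CV, 39×50% partial ROC) are the standard values of the procedure and
live in `snakemaps.pipeline.Params`.

## Known limitations

- CDU is resolution-dependent by construction; changing the grid cell
  size changes what 500 CDU means on the ground.
- The >2-species fade-out generalization and the ln(1+pop) shift are
  this package's choices on points the published procedure leaves
  open; both are documented above.
- No reprojection: everything assumes the common WGS84 0.01° lattice.
- The penalty is a single global β, not Maxent's per-feature-class
  schedule; absolute suitability values can differ from Maxent 3.4.4
  even where rankings agree.
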