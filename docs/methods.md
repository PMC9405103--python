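# Methods

This note documents the models, the parameter choices that matter, what the
synthetic world does and does not emulate, and the numerical decisions taken
where the design was genuinely open. It states no empirical value that the
test suite or `scripts/acceptance.py` does not itself compute.

## The paired-model protocol

For each species × procedure × variable set, two potential distributions are
produced and compared:

1. *Distribution 1*: the procedure is fitted on historical occurrences against
   the historical environmental stack, in 10 subsampling replicates
   (train fraction 0.7; a fresh contrast sample per replicate by default, so
   contrast-sampling uncertainty propagates into the average — a single shared
   draw is available via ``fresh_contrast=False``), the replicate
   maps are averaged, and every replicate's fitted model is then re-predicted
   on the modern stack and averaged again. Projection is always a
   re-evaluation of the fitted response at the new environments — never a
   resampling of the fitted map.
2. *Distribution 2*: the same procedure fitted and predicted entirely on
   modern occurrences and climate.

Agreement is measured in environmental-density space (Schoener's D on
sum-normalized suitability surfaces), in geographic space (stability S =
Jaccard percentage of the binarized presence cells; range-size variation RSV =
signed percent difference of presence-cell counts), and summarized as the
Euclidean distance d of (D, S, RSV) from the ideal point (1, 100, 0), on raw
scales (D unit-scaled, S and RSV in percent). Raw-scale mixing means the
(100 − S) axis dominates d; that is a property of the statistic as defined,
flagged here deliberately: with |RSV| of a few percent the attainable ceiling
of d is just above 100.

Stability's denominator is the *union* of the two presence sets. A
whole-study-area denominator (option `total_cells`) is available but produces
values bounded by the species' prevalence (a few percent) for
restricted-range species, which is incompatible with the magnitudes the
statistic is meant to resolve.

## The synthetic world

Monthly climatologies (12 × tmin, tmax, precipitation) are built from
deterministic structure — a north–south temperature ramp (8 °C across the
grid), a seasonal sinusoid (±9 °C, July peak), winter-wet precipitation
seasonality — plus smoothed seeded white noise (Gaussian blur, σ = 4 cells) to
mimic the spatial autocorrelation of real climate without geostatistical
dependencies. tmax/tmin are mean ± a strictly positive diurnal half-range, so
tmax ≥ tmin holds by construction; drift noise perturbs the shared mean field,
preserving the ordering under any drift setting.

The modern period is historical + drift: constant offsets and/or
north–south gradients per variable plus optional smoothed noise. The default
benchmark drift is +1.0 °C with noise σ = 0.1 °C — a "moderate warming"
between two 30-year climatologies. With zero drift the two periods are
bitwise identical, which pins the MOP identity (strict extrapolation exactly
0).

Virtual species have Gaussian niches over the three a-priori variables
(annual mean temperature bio1, annual precipitation bio12, annual
Thornthwaite PET). Each species is confined to a seeded rectangular
*accessible range* (45 × 45 cells on the default 100 × 120 grid) — the
dispersal-limited area of the BAM framework and standard virtual-species
practice. Without this constraint a purely environmental niche scatters
occurrences across every climatically analogous band of the grid and the
per-species study areas degenerate to the whole map; with it, species are
stenochorous and study areas differ, as intended. The niche covariance is a
scaled diagonal of the within-range environmental variances, with the scale
solved by bisection so that cells with suitability > 0.5 occupy ≈ 3% of the
accessible range (endemic-like prevalence in the 1–5% band).

Occurrences are drawn per period from that period's own true suitability
(weighted sampling without replacement), i.e. under a perfect-equilibrium
assumption: the realized range tracks suitability instantly in both periods.
Real species lag climate, carry sampling bias, and interact; none of that is
emulated, so passing tests demonstrate that the *machinery* measures
transferability correctly under known conditions — not that any procedure
will transfer on real data. Defaults: 150 modern records, historical = 0.5 ×
modern, mirroring unequal archival datasets before balancing.

## Variable sets

The raw stack is bio1–bio19 (standard definitions: monthly mean =
(tmin + tmax)/2; quarters = all 12 wrap-around runs of 3 months, ties broken
to the first run scanning Jan→Dec; bio4 = sd × 100 with ddof = 1; bio15 =
100 · sd / (1 + bio12/12)) plus monthly and annual Thornthwaite PET. PET uses
the classic heat-index equations with the day-length correction disabled
(12-hour days, 30-day months), making it a pure temperature response; the
correction can be reinstated by post-multiplying the monthly factors. The
high-temperature (> 26.5 °C) branch of some PET implementations is omitted —
synthetic monthly means stay below it.

Set I ("apriori3") is bio1, bio12, annual PET, in that fixed order. Set II
("pca3") standardizes every layer over valid cells (mean 0, sd 1), computes a
full PCA, and keeps the first three axis scores; loadings, centring/scaling,
and explained-variance shares are stored on the stack. Each period is
transformed *independently*; because independently derived axes can flip
sign, the modern axes are by default sign-aligned to the historical loadings
(`align_axes`), without which cross-period projection is ill-defined. The
fully independent (unaligned) mode remains available; projection then refuses
to run unless alignment is explicitly waived. Variable-set construction happens
on the full grid first and is then tailored per species (bounding box of both
periods' records + 10-cell buffer).

## Occurrence cleaning

Per species and variable set: (1) thin to one record per (period, cell),
dropping off-mask records; (2) per period, drop records whose environment
lies outside the χ²(0.975, df = L) Mahalanobis ellipsoid of that period's
records (single pass; the level is configurable — no published default
exists); (3) shrink the larger dataset to the smaller one's size by greedily
deleting the record whose removal maximizes the Monte Carlo Jaccard overlap
of the two level-0.975 ellipsoids (20,000 uniform points in the union
bounding box, fixed sub-seed; ties break to input order). Greedy
one-at-a-time deletion approximates the combinatorial subset search of the
reference approach deterministically in O(n²). Modern records discarded by
balancing become the independent modern test set used by OR10, partial ROC
and CBI. Because the filter acts in environmental space, the a-priori and PCA
runs may retain different record subsets for the same species — both are
kept.

## Procedures

Twelve procedures fill the published slots. BIOCLIM (percentile envelope with
midpoint tie convention), DOMAIN (Gower similarity to the nearest presence)
and KDE (Gaussian product kernel on standardized presences, per-dimension
Silverman bandwidth, max-normalized) are native presence-only scorers with
1000 background cells drawn for evaluation. GLM is a native logistic
regression on linear + quadratic terms fitted by IRLS with ridge 1e-6
(unpenalized intercept) against 1000 pseudoabsences. GAM is a native
penalized additive model: per-variable cubic B-spline bases (df 5, quantile
knots) through the same ridge-IRLS core (ridge 1e-3) — penalized regression
splines in the mgcv sense, chosen because off-the-shelf GAM fitters abort on
the perfectly separated presence–pseudoabsence data this design routinely
produces. FDA/CTA/RF/SVM/ANN are served by a generic scikit-learn adapter
(LDA on the quadratic basis, decision tree, 100-tree random forest, RBF-SVC
with Platt probabilities, single-hidden-layer MLP) with pseudoabsences equal
to the presence count. The Maxent slot is filled by `maxent_surrogate`, an
L1-regularized logistic on the quadratic basis against a large background
(10,000 cells, capped at the study-area size) — a surrogate, not a Maxent
reimplementation. The ensemble combines the seven classifier members per
replicate by test-AUC weights with a 0.7 floor (all members retained if none
pass). No MARS implementation exists in the supported ecosystem; the grid
runs without that slot. Pseudoabsence rules exclude exact presence cells;
background rules do not (the background is the whole study area). A
`control_permuted` procedure — the GLM trained on randomly permuted labels —
serves as a deliberately degenerate control in the behavioural benchmark.

No procedure is tuned; each uses its common default settings, since the
question is how routinely-configured procedures transfer, not how well each
can be made to perform.

## Binarization

Averaged suitability is converted to presence/absence through
P = 1/(1 + exp(−(s − β)/α)) with α = 0.05 (suitability units) and β solved by
root-finding so that the mean of P over the study area equals the species'
prevalence (presence cells / valid cells of the cleaned, period-specific
data; tolerance 1e-6). Three realizations are available:

* `bernoulli` (default): each cell drawn independently with probability P —
  the probabilistic conversion, seeded;
* `expected_threshold`: cells with P ≥ 0.5;
* `expected_count`: the round(prevalence × N) cells with highest P, seeded
  jitter breaking exact ties.

The two non-default modes exist because measurement showed the first two
degrade as *pair-comparison* instruments: independent Bernoulli draws floor
the stability of even an identical map pair at Σp²/Σ(2p − p²) (tens of
percent), and P ≥ 0.5 yields an empty presence set whenever a map plateaus
(every plateau cell then carries P = prevalence·N/M < 0.5). The behavioural
benchmark and the acceptance script therefore binarize with
`expected_count`, so that d reflects where the models disagree rather than
draw noise; the single-map workflow keeps the probabilistic default.

## Evaluation metrics and MOP

AUC is the rank statistic U/(n₊·n₋) with ties at ½, computed against the
replicate's own contrast sample (the standard presence–background choice; the
negative class is not otherwise defined for presence-only procedures). OR10
thresholds at the 10th percentile (linear interpolation) of training-presence
scores. Partial ROC (E = 0.05, 500 bootstrap iterations of 50% of the test
points) integrates the sensitivity curve over the region with sensitivity
≥ 1 − E and divides by the analytic area of the uniform-score diagonal over
the same proportion-of-area range; p is the fraction of iterations with ratio
≤ 1. For strict envelopes that omit more than E of the test points at every
positive threshold the region collapses and the ratio is undefined; the
runner records NaN for that cell rather than discarding the comparison. CBI
uses 101 overlapping windows of width 0.1 × range; windows live on the map's
empirical quantile scale by default, which makes the index exactly invariant
under strictly increasing transforms of suitability (the classic raw-value
windowing is available via `value_scale="raw"`); a constant P/E profile
returns 0.

MOP flags strict extrapolation where any variable of a projection cell falls
outside the calibration min–max, and computes a distance surface as the mean
Euclidean distance (calibration-standardized variables) to the nearest 10% of
calibration cells, evaluated in 2000-row chunks (chunking is
result-invariant) and min–max scaled to [0, 1]; projection cells whose
environment coincides exactly with a calibration cell are assigned distance 0
before scaling.

## Statistics layer

Kruskal–Wallis (tie-corrected, χ² approximation) across procedures, followed
by two-sided tie-corrected normal-approximation Mann–Whitney tests on all
pairs with Bonferroni correction at α = 0.01 (significance iff
p < α/m, m = g(g−1)/2). Pooled-identical groups return H = 0, p = 1
(degenerate, not an error). CBI of projected vs modern maps is compared with
the same machinery, per variable set.

## The behavioural benchmark

The default benchmark realizes 10 virtual species under the default scenario
(moderate drift, niche conserved between periods, n_modern = 150) and runs
the cheap procedure panel — bioclim, glm, maxent_surrogate, fda, cta, svm —
plus `control_permuted`, one variable set, comparison metrics only,
`expected_count` binarization. The recovery property asserted by the
acceptance suite: the control lands in the high-distance class (mean d > 70)
while at least four genuine procedures stay below 70, in at least 9 of 10
master seeds. Problem sizes throughout (grid 100 × 120, 45 × 45 accessible
ranges, 150/75 records) were chosen as the smallest world in which the
cleaning cascade, the balancing search, and all twelve procedures operate in
their intended regimes.

## Known limitations

* Perfect equilibrium, no sampling bias, no detection error, no biotic
  interactions — the generator validates the measurement machinery, not
  real-world transferability.
* Grids are planar; any affine/CRS metadata on user rasters is carried
  through untouched, never interpreted.
* The PCA variable pool is the native 19 + PET family, not the full 35-layer
  set of derived-climate products; extra precomputed layers can be supplied
  through the raw-stack interface.
* The distance d inherits the raw-scale dominance of its stability axis; it
  is reported alongside its components, never alone.
* Whether outlier removal should pool periods is unsettled; it runs per
  period here.
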