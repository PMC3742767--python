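# Methods and design notes

This note documents the models, the synthetic survey program they are
exercised on, the numerical choices, and the known limitations. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The count model

Per-bin species counts are modelled as zero-inflated negative binomial
(ZINB):

- Count part: NB2 with mean `mu = exp(x'beta + log area)` and variance
  `mu + alpha mu^2`, `alpha > 0`. The log of the surveyed area
  (bin length x strip width, km²) enters as an exposure offset with its
  coefficient fixed at 1, so the model is an implicit density model and
  bins of different effort are comparable. Habitat covariates enter
  linearly or with a mean-centred quadratic; month and year enter the
  count part as categorical controls (they are not offered to the
  inflation part — with survey programs of this shape the detection
  process is driven by conditions, not season, and adding seasonal
  dummies to a logistic part this small is poorly identified).
- Inflation part: `pi = logistic(z'gamma)` over detection-bias
  covariates only (cloud cover, Beaufort sea state, swell height,
  visibility, time of day as decimal hours). These model *false* zeros
  — bins the species used but the observer missed.

Fitting is by maximum likelihood: the dispersion is parameterized as
`log alpha` so the search is unconstrained, the gradient is analytic
(validated against numerical differentiation), starting values come
from a Poisson GLM (count part) and the marginal zero fraction
(inflation intercept), and scipy's L-BFGS-B does the optimization with
up to three perturbed restarts. Non-convergence and suspected
separation in the inflation part are flagged on the result, never
silent. Wald covariance comes from the numerical Hessian at the
optimum. statsmodels' independent ZINB implementation is used in the
test suite as a cross-check of the likelihood surface, never as the
fitter (its own optimizer diverges on several of our test data sets).

Covariates are standardized to the training sample mean/SD before
fitting; quadratics square the centred value. This bounds collinearity
between a covariate and its square and puts coefficients on a
per-standard-deviation scale. Prediction reuses the training scalers.

Degenerate-control handling: with few cruises, month/year dummies can
become linearly dependent (or absorb cruise-level climate indices
entirely). Dependent *control* columns are pruned automatically with a
log message; a rank-deficient habitat design is an error. A consequence
worth knowing: cruise-level covariates (NPGO, PDO, SOI, UI) are not
identifiable when the number of cruises equals the number of
month/year control parameters — they need multi-year programs.

## Model-building battery

- VIF screen: covariates with VIF ≥ 10 (from OLS of each covariate on
  the rest) are excluded from the candidate set.
- Form choice: per covariate, a single-covariate NB model with
  month/year controls; the quadratic form is kept when the squared term
  holds p < 0.05.
- Backward stepwise (NB): iteratively drop the single worst term with
  p > 0.05, quadratic components before their linear partners, controls
  never; ties broken by the smallest likelihood loss. The procedure is
  deterministic; only endpoint properties (all retained terms
  significant, null covariates retained at roughly the nominal rate)
  are asserted in tests, since any manual stepwise path is
  analyst-specific.
- Detection terms: all five candidates enter the ZINB inflation part,
  then backward selection at 0.05.
- Overdispersion: LR test of NB vs Poisson with the boundary
  correction (alpha = 0 lies on the parameter boundary, so the null
  distribution is a 50:50 mix of a point mass at 0 and chi-square(1);
  statistic 0 gives p = 0.5). The correction is a deliberate
  improvement over quoting the naive chi-square(1) p-value.
- Vuong test: `V = sqrt(n) mean(m)/sd(m)` over per-observation log
  density ratios `m_i = log f_ZINB - log f_NB`; one-sided p, ZINB
  preferred at 0.05. Identical densities are reported as a degenerate
  result at V = 0, p = 0.5. Measured behavior (acceptance suite): null
  rejection within 3–7% at nominal 5%, power > 80% at inflation 0.4.
- Interaction: for each oceanographic covariate (SST, SSS, SSF) in the
  reduced spec, an LR test of adding year x covariate; the largest
  significant statistic wins, none otherwise.
- Cross-validation: seeded random partition into n folds (default 10),
  each observation predicted exactly once from a fit excluding its
  fold, then OLS of observed on predicted counts; F(1, n-2) and p are
  the reported fit statistic.

## Kriging

Per (cruise, variable): empirical semivariogram from binned pairwise
half squared differences (12 lags to half the maximum pairwise
distance), candidate families exponential / spherical / gaussian under
a practical-range convention, parameters by pair-count-weighted least
squares, and the family selected by leave-one-out cross-validation MSE
— a documented, testable replacement for proprietary "parameter
optimization" whose stated objective is the same. Prediction uses
ordinary kriging with the 16 nearest neighbours; weights solve the
constrained system and sum to 1 (checked to 1e-8); a zero nugget makes
the predictor exact at data locations. Duplicate locations are averaged
first. Detrending (first-order plane, added back after kriging) runs
when the plane F test holds p < 0.05 or the empirical semivariogram
grows unboundedly at the largest lags (last three lags increasing and
the final one above twice the sample variance), and is forced on
surfaces whose LOO RMSE exceeds the per-variable mean + 2 SD. Grid
nodes more than 25 km from the nearest datum are flagged as
extrapolated. Single-realization range estimates are biased low by
10–20% at survey-like densities (the acceptance test asserts the median
over replicates within 25%); this is inherent to variogram estimation,
not a defect of the fit.

## Habitat maps

Predictions are made per cruise on a regular grid (default 1-km² cells,
region + 5-km buffer, grid aligned to the region's minimum corner;
centroid-in-closed-region membership). Detection covariates take their
modal observed values (continuous ones rounded to 0.1 before the mode).
The per-cell expectation is `(1-pi) mu` at 1-km² exposure (plain `mu`
for NB-preferred species). Standardization divides each (species,
cruise) surface by its cross-cell mean — a relative-use index with mean
exactly 1 — rather than z-scoring, because the downstream minimum-set
problem needs non-negative "amounts"; a z-score alternative would break
that. Month layers average the standardized surfaces of that calendar
month across years; the across-months-and-years layer averages the
month layers and is re-scaled to mean 1 so every species contributes
equally to the composite (the re-scaling choice is ours; without it,
species surveyed in different month sets would drift slightly off equal
means). The multi-species composite is the cellwise mean; percent rank
is `(rank-1)/(n-1)` with average ranks on ties; deciles are computed on
percent ranks.

## Human use and prioritization

A cell's general human-use score sums the 1–5 impact scores of every
activity whose *dominant* footprint overlaps the cell square (any
overlap, not centroid membership), maximum 17 with the default table.
The minimum-set objective is `sum cost + sum_f SPF_f max(0, target_f -
held_f)`. Scenario 1 costs each cell 1; scenario 2 costs 1 + human-use
score. Targets are 10/30/50% of each species' total standardized
amount. SPF defaults to `100 x (max feature total / feature total)`:
rare features get proportionally larger penalties, and the scale is set
high enough that meeting attainable targets is always cheaper than
paying shortfall (at the default 10x the pruner would trade small
shortfalls for cost on scenario-2 problems; 100x makes targets bind, the
standard way the penalty factor is used in practice).

The annealer uses single-cell toggle moves with Boltzmann acceptance,
an adaptive initial temperature (calibrated so ~80% of uphill moves are
accepted at the start), geometric cooling (factor 0.995 at 2,000 evenly
spaced points over `100 x n_units` moves), then greedy shortfall
repair, redundancy pruning (most expensive first), steepest 1-opt
descent, and a remove-one/add-one exchange descent (skipped above 500
units, where annealing carries the search). Every run also computes a
greedy-construction solution as a floor and returns whichever is
better, so the annealed objective never exceeds the greedy one.
Ensembles are independent seeded runs (default 100; "iterations" in the
Marxan sense); selection frequency is the fraction of runs selecting a
cell, and the best solution is the minimum objective with ties to the
earliest run. An exhaustive oracle (≤ 20 units, ties broken by smaller
cardinality then lexicographic order) validates the annealer: best-of-10
annealing matches the 2^12 optimum on ≥ 95 of 100 random instances.
The boundary-length modifier is fixed at 0 (no compactness penalty) but
exposed for extension.

## The synthetic survey program

The generator emulates an eight-year shipboard monitoring program in a
60 x 45 km planar shelf region (all geometry in metres; no geodesy —
distances are planar GIS-style measurements): 27 cruises April–
September 2004–2011, seven east–west transects of ~35–41 km crossing a
diagonal shelf break, three vessels cycling with nominal strip widths
100/200/300 m (narrowed, never below 50 m, under poor visibility), and
per-kilometre track segments carrying AR(1)-evolving detection
conditions and underway SST/SSS/SSF.

- Ocean fields are low-rank Gaussian random fields (96 random Fourier
  features, squared-exponential correlation, per-variable length scale)
  transformed to match published covariate summaries — SST 12.6 ± 1.62 °C
  (8.9–16), SSS 33.3 ± 0.48 (29.7–34), SSF lognormal 1.08 ± 2.23 mg/m³
  (0–14.9) — and clipped to the stated windows. SD 0 degenerates to a
  constant field. The published swell-height SD (5.07 m on a 0–8 m
  support at mean 1.98) is arithmetically impossible, so the generator
  matches the swell mean and range only.
- Climate indices are AR(1) monthly series clipped to their published
  windows; the upwelling index is a daily AR(1) series, and each bin
  receives the mean of exactly the 10 daily values ending on its
  cruise's last day.
- 11 of 27 cruises lack a thermosalinograph, so their underway SSF is
  missing and must be gap-filled from CTD casts (15–18 stations per
  cruise; the 1–6 m layer value is the SSF field plus noise). In the
  default configuration the SSF field is independent of SST, so the
  gap-fill regression has little explanatory power (R² near 0) and
  imputation shrinks toward the CTD mean — a deliberately conservative
  analogue of the real procedure's reduced predictive variance.
- Counts are drawn from the ZINB law itself with per-species "truth"
  coefficients on the standardized covariate scale. Species intercepts
  were calibrated once, by simulation across several generator seeds,
  so the *marginal* zero fractions match the reference survey's
  per-species zero/non-zero splits (0.82/0.50/0.77/0.85/0.92); the
  single-seed zero fraction still varies a few points with the realized
  cruise-level indices, which the fidelity test accounts for. Bin
  totals are split into sighting groups with geometric sizes (the
  spatial clustering law is a free parameter, not asserted), behaviours
  drawn from foraging/feeding/sitting, plus decoy flying/ship-attract
  records that downstream filtering must remove.
- Six human-activity footprints with the default score table are laid
  out as shipping lanes crossing the shelf, viewing near the colony,
  fishing on the shelf, and an offshore military box; `overlap` and
  `disjoint` layouts exist for testing.

What the generator does **not** emulate: real bathymetry, currents or
prey fields; anisotropy or directional structure in the ocean surfaces;
spatial clustering of sightings beyond the within-bin group sizes;
observer-specific detection functions (strip transects assume full
detectability within the strip); seasonal activity variation in the
human-use layer. Passing tests therefore demonstrate that the *methods*
are implemented correctly and calibrated under a realistic generative
model — not that any particular real ecosystem behaves this way.

## Problem sizes used in the checks

The test suite and acceptance script choose replicate counts and grid
sizes that make the statistical checks sharp while staying desk-scale:
Wald coverage uses 200 replicate fits at n = 2,336 bins (the acceptance
script reports a 100-replicate version); Vuong size uses 1,000 null
replicates at n = 2,000 in the test suite and 400 in the script; the
surface-suite bookkeeping uses a 50 x 50 grid in the tests and the 2-km
pipeline grid in the script; pipeline prioritization ensembles use 25
runs per scenario/target (the module default is 100).

## Known limitations

- The ZINB covariance is the inverse numerical Hessian; no sandwich or
  bootstrap uncertainty, and no uncertainty propagation into the maps.
- Stepwise selection inherits the usual caveats of sequential testing;
  the battery reproduces the classical procedure rather than modern
  model averaging, which is out of scope.
- Ordinary kriging is isotropic with no co-kriging and no current
  covariates.
- The human-use layer has no frequency/effort weighting and no
  seasonality.
- `brute_force` is exact only to 20 planning units; beyond that the
  annealer's quality is supported by the small-problem equivalence and
  its internal floors, not by proof.
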