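# Methods

`treelight` implements a pipeline for asking whether position-based
neighborhood competition indices (NCI) can replace canopy census data as a
light-availability proxy when estimating species-specific light responses of
tropical-tree recruitment and growth. This note records the models, the
numerical choices, and what the synthetic test bed does and does not show.

## Data preparation

Census tables hold, per stem, an id, species, x/y position (m), dbh (mm) and
status flags. Internally dbh is millimeters everywhere; it is converted to
centimeters only inside the NCI formula. Analyses are restricted to a core
region obtained by removing a 30 m margin on every side of the plot (so each
focal point has its full 30 m neighborhood observed); the core is tiled by
5×5 m half-open cells `[x0, x0+5)`, row-major ids from the core origin, so
every tree falls in exactly one cell.

- **Recruits** are trees absent, dead, or below the 10 mm presence threshold
  at the first census and alive with dbh ≥ 10 mm at the second, counted per
  (core cell, species). Margin trees are excluded from counts but retained in
  species abundance (abundance describes the plot-level population).
- **Growth** is the annualized dbh increment of trees alive at both censuses;
  palms, stems with a moved point of measurement or break/resprout, and
  non-main stems are excluded. An optional rounding rule floors dbh below
  55 mm to the nearest 5 mm at *both* censuses before differencing,
  emulating intervals whose first census recorded small stems at 5 mm
  precision only. Growth records may be negative (measurement error).

## Canopy index (CAI)

A canopy census records presence/absence of vegetation in six height layers
(0–2, 2–5, 5–10, 10–20, 20–30, ≥30 m) on a 5 m grid. The shade index at a
focal point with reference height *h* sums `kernel(distance) × layer_weight`
over occupied layer-cells whose layer lower bound is at or above *h* and
whose center is horizontally closer than 20 m. The exact kernel and layer
weights used with real canopy data are site-specific calibrations that are
not reproduced here; the defaults — kernel `1/(1+d)`, unit weight for every
layer — are deliberately simple, monotone stand-ins and both are
configurable.

Shade is converted to CAI (fraction of full irradiance) by rank-based
quantile matching against a reference irradiance distribution: the shade
value at empirical quantile *q* (plotting position `(i−0.5)/n`, average ranks
for ties) maps to the reference's `1−q` quantile, making the mapping strictly
decreasing in shade. The default reference is a lognormal with median 2% of
full irradiance and log-sd 1.0, truncated at 1 — a synthetic stand-in for a
measured understory irradiance distribution, likewise configurable. Cell CAI
is evaluated at cell centers at 2 m height (the height a recruit must
surpass); tree CAI at the tree's allometric crown top, using the mapping
calibrated on the same year's 2 m cell shades. Yearly CAI estimates are
averaged arithmetically over a census interval. By construction CAI ∈ (0,1]
and log CAI ≤ 0; a tree above all occupied layers has shade 0 and receives
the mapping's maximum irradiance.

## Neighborhood competition index

For focal point *i*: `NCI_i = Σ_j dbh_j^α / dist_ij^β` over alive neighbors
*j* within 30 m (dbh in cm, distance in m, margin trees included as
neighbors). Only trees *taller than the focal point* count (competition for
light); neighbor height comes from the height allometry, and for grid cells
the focal height is the 2 m reference. A focal tree is excluded from its own
neighborhood. Distances are floored at 0.1 m to keep the sum finite when a
neighbor coincides with a cell center (configurable; the behavior as
dist → 0 is otherwise undefined). `0^0 = 1` so α = β = 0 counts neighbors.

α and β are chosen by sweeping both from 0 to 3 in steps of 0.2 (256
combinations) and selecting the pair whose NCI has the strongest pooled
Pearson correlation |r| with log CAI across census intervals; ties go to the
smaller α, then the smaller β; combinations with zero NCI variance are
excluded. The selection uses |r| because the expected correlation is
negative (more competition, less light).

The selected NCI is mapped onto the log CAI scale by median (τ = 0.5)
regression with the intercept forced to zero — an empty neighborhood must
mean full irradiance (CAI = 1). The fit minimizes Σ|log CAI − (b₁·NCI +
b₂·NCI²)| as a least-absolute-deviations linear program (HiGHS), which is
exact and deterministic; the quadratic term is used for trees (the
relationship is curved) and omitted for cells. Interval-specific
(`NCI_ts`) and pooled (`NCI_tg`) conversions are supported. Converted values
may exceed the observed log CAI range: extreme NCI outliers map to extremely
low log CAI.

## Recruitment model

Counts `obs_ij` of species *j* in cell *i* are negative binomial with mean
`exp(a_rj + b_rj·x_i)` — `x_i` the centered log light proxy — and
species-specific clumping `k_j` (variance μ + μ²/k), absorbing non-light
aggregation (seed trees, dispersal, soil). Species parameters follow
community regressions on ln abundance:

    a_rj ~ N(α_r1 + α_r2·ln abun_j, σ_rα),
    b_rj ~ N(β_r1 + β_r2·ln abun_j, σ_rβ),   k_j ~ U(0, 100],

with flat hyperpriors (σ's positive). The upper bound on *k* reflects that
beyond k ≈ 10 the negative binomial is already near-Poisson. Species with no
recruits in an interval are dropped from that interval's fit; note this
truncates the community spread slightly (rarely-recruiting species tend to
have low `a_r`), which is visible as a mild downward pull on σ_rα in
recovery experiments. The hyper-regressions use the natural log of
abundance; with the default hyperparameters this yields plausible per-cell
recruit rates across the abundance range.

Sampling: full-scan adaptive Metropolis–Hastings (every parameter updated
sequentially per iteration by a Gaussian random walk, proposals outside
support rejected outright). Two chains with different initial values
(`b_r` started at 0 and 1), burn-in 1000 scans, 6000 sampling scans.
Convergence is monitored by the Gelman–Rubin potential scale reduction
factor `√(((n−1)/n·W + B/n)/W)`; values below 1.1 indicate convergence.

## Growth model

Annual growth of tree *i* of species *j* is predicted as
`pred_ij = exp(a_gj + b_gj·x_i + c_j·log(dbh_i/50))` — dbh centered on
50 mm so `a_g` is the log growth of a 50 mm tree at mean light. True growth
varies lognormally around the prediction (log-sd `d_j`, so the median of
true growth equals the prediction and the spread scales with it), and the
observation differs from true growth by a two-component normal mixture: a
routine size-dependent error `SD1(dbh) = s0 + s1·dbh` and a large error
`SD2` (decimal slips, record mix-ups) affecting a fraction f = 2.7% of
observations; both SDs are divided by the interval length because growth is
annualized. Defaults `s0 = 0.927 mm`, `s1 = 0.0038`, `SD2 = 25.6 mm` follow
published dbh-remeasurement error estimates for tropical censuses and are
configurable. Species parameters follow ln-abundance regressions as above;
`d_j` is lognormal across the community with hyperparameters (δ₁, δ₂),
defaulting to a median species process log-sd of 0.6 (a package choice —
these two are not constrained by published point estimates).

Latent true growth is an explicit model quantity and is sampled rather than
marginalized; a quadrature marginalization is kept as an independent test
oracle. The sampler updates one parameter at a time in cyclic order
(species parameters, then hyperparameters); latent true-growth values are
conditionally independent given the parameters, so their updates are
executed as one element-wise vectorized block per cycle, each latent with
its own Gaussian proposal and accept/reject decision — an exact-MH
formulation of the same single-site scheme, chosen for speed. Latents are
initialized at max(observed growth, 0.05 mm/yr). Desk defaults are 600
burn-in + 800 sampling cycles (≈ 2×10⁵ single-site updates each for a
few-thousand-tree dataset); run lengths are configurable and should be
scaled with the dataset.

## Sampler engineering

Per-parameter proposal steps adapt during burn-in toward a realized
acceptance rate of 0.25: every 50 iterations each step is multiplied by
`exp(2·(rate − 0.25))`, a proportional correction that reaches the target
quickly from badly mis-scaled initial steps and makes only small corrections
near it. Steps freeze at the end of burn-in, so the sampling phase is a
valid fixed-kernel chain. In both hierarchical models the abundance
covariate is centered internally (the sampler works with the intercept at
mean ln abundance, which decorrelates intercept and slope and dramatically
improves mixing); draws are transformed back to the `ln abun = 0` scale
before reporting, and the light covariate's centering constant is stored
with each fit. Posterior summaries are the mean and the 2.5/97.5% empirical
quantiles (linear interpolation of order statistics).

## Classification and comparison

On the log CAI scale the light response *b* is interpretable: negative
(b < 0), decelerating (0 < b < 1), linear (b = 1), accelerating (b > 1).
Classification by posterior mean assigns the boundary values 0 and 1 to
"decelerating" (a measure-zero convention); classification by 95% CI
requires the whole interval inside one open region, otherwise
"unclassified". Classification of fits that used the raw untransformed NCI
as predictor is refused — the exponent has no light-response interpretation
on that scale. Consistency tables count species classified identically
across intervals or light proxies; cross-model agreement reports Pearson r,
the mean signed deviation from the 1:1 line, and the major-axis slope of
the shared species' light-response estimates.

## Synthetic forest

The generator provides every input with known ground truth. Stands draw dbh
values from a lognormal (median 25 mm, log-sd 1.3, truncated at the 10 mm
census threshold) until the basal area reaches 32 m²/ha within 10%
(individual trees that would overshoot the band are skipped); species
identities follow a log-series rank-abundance curve; positions are uniform
or Thomas-clustered. Tree height is `min(3·dbh_cm^0.6, 33 m)`, crown radius
`0.5·dbh_cm^0.6` m, crown depth 30% of height — generic tropical-forest
allometries, not fitted to any site. Canopy occupancy is rasterized from
crown disks into the six layers. Observation simulators draw recruit counts
and growth records from exactly the models above, with species parameters
drawn from the default community hyperparameters, which are posterior point
estimates from a published canopy-index analysis of a lowland tropical
plot (first census interval).

Two canonical scenarios back the recovery tests: recruitment with 60
species × 2000 cells and growth with 40 species × 5000 trees, species
abundances log-uniform over 20–30,000 individuals, per-cell light latent
lognormal (median 2% irradiance for cells, 5% for trees), 5-year census
interval, default measurement-error model. The end-to-end pipeline instead
derives cell light from the generated canopy (`from_canopy`), so the NCI and
CAI proxies are linked through the same stand — in synthetic stands their
correlation is about −0.6, comparable in magnitude to field values.

**What the synthetic tests do not show.** Real canopies are asymmetric,
species differ in allometry and crown transparency, light fields are
spatially autocorrelated with soil and dispersal, and recruit light history
spans more than one interval. Passing recovery tests demonstrates that the
estimation machinery is correct and well-calibrated under the stated model,
not that the model is adequate for any particular forest.

## Numerical notes and limitations

- The negative-binomial log-pmf is computed via `gammaln` with per-species
  caching keyed on the parameter triple, so a full-scan proposal costs one
  species recomputation.
- Zero-variance NCI surfaces, all-equal shade fields, and degenerate
  conversion designs raise errors rather than returning silent NaN.
- The LAD linear program is exact at τ = 0.5; other quantiles are not
  supported.
- Growth-model run lengths are desk-scale defaults; datasets with ≫10⁴
  trees need proportionally longer runs (configurable, not automatic).
- No survival/mortality model, no species-specific (α, β) optimization
  against growth, and no reproduction of any site-specific calibration.
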