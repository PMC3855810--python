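# treelight

Can position-based **neighborhood competition indices (NCI)** replace canopy
census data as a light-availability proxy when estimating how tropical tree
species' recruitment and growth respond to light? Most forest census plots
record only stem positions and diameters; three-dimensional canopy censuses,
from which a **canopy index (CAI**, fraction of full irradiance**)** can be
derived, are rare. `treelight` implements both proxies and the hierarchical
Bayesian demographic models that consume them, so the two approaches can be
compared like-for-like — species rankings, between-species variation, and
classification into light-response groups. A synthetic-forest generator
with known ground truth makes the whole pipeline testable without access to
restricted census data.

## The models

**Light proxies.** The shade index at a focal point is a weighted sum of
occupied canopy layer-cells above the point and within 20 m; quantile
matching against a reference irradiance distribution converts shade to CAI
∈ (0, 1]. The competition index is

    NCI_i = Σ_j dbh_j^α / dist_ij^β        (dbh in cm, dist in m, ≤ 30 m,
                                            neighbors taller than the focal point)

with (α, β) selected from a 0–3 × 0–3 grid in steps of 0.2 (256
combinations) by maximizing |Pearson r| against log CAI, then mapped onto
the log CAI scale by zero-intercept median regression
(`log CAI ≈ b₁·NCI + b₂·NCI²`), so NCI = 0 ⇒ CAI = 1 (full irradiance).

**Recruitment.** Counts per 5×5 m cell are negative binomial,
`obs_ij ~ NB(exp(a_rj + b_rj·x_i), k_j)`, with `x_i` the centered log light
proxy and clumping `k_j ~ U(0, 100]`. **Growth.** Observed annual dbh
increments arise from `pred_ij = exp(a_gj + b_gj·x_i + c_j·log(dbh/50))`
with lognormal process error (log-sd `d_j`) around the prediction and a
two-component normal measurement-error mixture on top (routine
size-dependent error plus a large error affecting f = 2.7% of records);
latent true growth is sampled explicitly. In both models, species
parameters follow community regressions on ln abundance with flat
hyperpriors. Posteriors come from adaptive Metropolis–Hastings (full-scan
for recruitment: two chains, burn-in 1000 + 6000 samples, Gelman–Rubin
R̂ < 1.1; single-site for growth), with proposal steps tuned during burn-in
to a 0.25 acceptance rate. The exponent `b` classifies a species' light
response: negative (b < 0), decelerating (0 < b < 1), accelerating (b > 1).

## Worked example

```python
import numpy as np
from treelight import census, comparison, nci, synthetic
from treelight.allometry import AllometryConfig
from treelight.recruitment import MCMCConfig, fit_recruitment

stand = synthetic.generate_stand(synthetic.StandConfig(
    plot_width=200, plot_height=200, richness=30, seed=1))
grid = census.partition_core(200, 200, margin=30, cell_size=5)
allometry = AllometryConfig()
light = synthetic.simulate_light_field(
    mode="from_canopy", snapshot=stand, allometry=allometry, grid=grid)

pairs = nci.neighbor_pairs(grid.cell_centers(), 2.0, stand, allometry, nci.NCIConfig())
search = nci.grid_search([pairs], [np.log(light.values)])

abundance = census.compute_abundance(stand)
truth = synthetic.draw_species_params(abundance, seed=2)
table = synthetic.simulate_recruit_counts(truth, light, seed=3)
fit = fit_recruitment(table, light, abundance,
                      MCMCConfig(n_chains=2, burn_in=1000, samples=6000, seed=4))
```

Output (exact numbers from this run):

```
9535 trees, 784 cells, median cell CAI 0.020
grid search: 256 combinations, best alpha=1.8, beta=0.8, r=-0.67
conversion: log(CAI) = -6.75e-04 * NCI  (CAI at NCI=0: 1)
fit: 19 species, acceptance 0.25, max R-hat 1.021
           mean  ci_low  ci_high
alpha_r1  -9.46  -11.41    -7.66
alpha_r2   0.68    0.35     1.02
sigma_ra   0.84    0.47     1.41
beta_r1    2.58    1.35     3.77
beta_r2   -0.30   -0.50    -0.08
sigma_rb   0.59    0.32     0.96
by_mean: decelerating 12, accelerating 7
```

The stand meets the 32 m²/ha basal-area target; cell light has the expected
~2% median irradiance; NCI correlates with log CAI at r ≈ −0.67 with the
best exponents in the size-weighted, weakly distance-decaying corner of the
grid; the chains converge (R̂ < 1.1) at the tuned 0.25 acceptance rate; and
the hyperparameter posteriors bracket the generator's community
regressions. `comparison.run_pipeline` chains all of this (including an
NCI-based refit and classification-consistency tables) behind one config,
also available from the shell:

```sh
treelight run --seed 3 --outdir out/
treelight simulate --seed 1 --outdir out/   # census/canopy/truth tables
```

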