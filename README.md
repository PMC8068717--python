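# smrmap

Small-area mapping of standardized mortality ratios (SMRs) with Bayesian
spatial smoothing, built for gender- and age-stratified analyses of rare
events (such as suicide) across hundreds to thousands of municipalities.

Rates in small areas are unstable: a village with three deaths and one
expected looks like a three-fold hotspot. `smrmap` implements the standard
disease-mapping remedy — a hierarchical Poisson model with spatially
structured and unstructured random effects (the Besag–York–Mollié, "BYM",
model) — together with everything around it: indirect standardization to
expected counts, rurality deciles from population density, socioeconomic
covariate adjustment, rate-ratio tables with credible intervals, residual-SMR
maps, and a synthetic-data generator with known ground truth for validating
the whole chain.

## The model

For areas `i = 1..n` with observed counts `O_i` and expected counts `E_i`
(from national gender × 10-year-age-band reference rates applied to each
area's person-years),

```
O_i ~ Poisson(E_i · θ_i)
log θ_i = α + x_iᵀβ + u_i + v_i
```

* `u` — spatially structured effect with an intrinsic conditional
  autoregressive (ICAR) prior on the municipality adjacency graph
  (shared borders plus sea-route edges), density
  `∝ exp(−τ_u/2 · Σ_{i~j}(u_i − u_j)²)`, identified by a sum-to-zero
  constraint per connected component;
* `v_i ~ N(0, 1/τ_v)` — unstructured heterogeneity;
* `τ_u, τ_v ~ Gamma(1, 5·10⁻⁵)`, `β ~ N(0, 1000·I)`, `α` flat.

Inference is by MCMC (conjugate Gibbs for the precisions, adaptive
Metropolis for the fields and coefficients, plus likelihood-invariant
interweaving and shift moves that break the spatial-confounding slow modes
— see `docs/methods.md`). Reported quantities are posterior medians with
95% equal-tailed credible intervals: rate ratios `exp(β)` per rurality
decile (decile 1, most urban, is the reference), smoothed SMRs
`exp(α + u_i + v_i)` from the covariate-free model, and residual SMRs
`exp(u_i + v_i)` from the adjusted model. Dispersion across areas is
summarised by the 90%-range fold difference (95th/5th percentile ratio),
and maps use seven categories symmetric on the log scale
(`<0.50 … ≥2.00`).

## Worked example

Generate a synthetic 400-municipality system (20×20 lattice, densities
spanning four orders of magnitude, a true most-rural rate ratio of 1.2)
and fit the unadjusted decile model:

```python
import smrmap as sm
from smrmap.covariates import build_design
from smrmap.standardize import national_rates, expected_counts, range_ratio, raw_smr

ds = sm.simulate_dataset(sm.SyntheticConfig(seed=1))
obs = ds.counts.groupby("area_id", sort=False)["count"].sum()
rates = national_rates(
    ds.counts.groupby("age_band")["count"].sum(),
    ds.population.groupby("age_band")["person_years"].sum(),
)
pop = ds.population.pivot_table(index="area_id", columns="age_band",
                                values="person_years", aggfunc="sum")
exp = expected_counts(pop, rates).reindex(list(ds.graph.area_ids))

design, names = build_design(ds.deciles, adjusted=False)
model = sm.BYMModel.from_tables(obs, exp, ds.graph, design, names)
res = model.fit(sm.MCMCConfig(seed=1, chains=2, iterations=3000, burn_in=1000))
print(res.summary())
```

prints

```
BYM hierarchical Poisson model
  areas: 400   covariates: 9
  chains: 2  draws/chain: 2000
  acceptance: u=0.45, v=0.41, ab=0.25
  rate ratios (posterior median, 95% CI):
            decile_2: 1.016  (0.943, 1.089)
            decile_3: 0.991  (0.907, 1.082)
            decile_4: 1.042  (0.953, 1.136)
            decile_5: 1.048  (0.950, 1.159)
            decile_6: 1.110* (1.003, 1.227)
            decile_7: 1.019  (0.916, 1.134)
            decile_8: 1.111  (0.996, 1.242)
            decile_9: 1.136  (0.995, 1.276)
           decile_10: 1.115  (0.966, 1.297)
  max split-Rhat: 1.021  min ESS: 35
```

The gradient rises toward the rural deciles, as generated (`*` marks a
95% interval excluding 1). Smoothing pulls the noisy raw SMRs together:

```python
raw_fold = range_ratio(raw_smr(obs.to_numpy(), exp.to_numpy()).defined_values())
print(raw_fold["fold_rounded"])                               # 2.3
print(range_ratio(res.smoothed_smr().to_numpy())["fold_rounded"])  # 1.7
```

i.e. the middle 90% of raw SMRs span a 2.3-fold range, the smoothed SMRs
a 1.7-fold range.

## Command line

```bash
smrmap simulate --config sim.yaml --out data/        # synthetic CSV/GAL + truth.json
smrmap validate-graph data/neighbors.gal             # components, degrees, isolates
smrmap run --config run.yaml --seed 7 --mode adjusted
```

`smrmap run` executes every configured gender × age stratum and model
mode, writing `smr_tables.csv` (raw / smoothed / residual SMRs with map
categories), `rate_ratios.csv`, `range_ratios.json`, an optional
categorized GeoJSON map, and `manifest.json` (seed, config hash,
excluded-record accounting, convergence; exit status 2 flags
non-convergence).

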