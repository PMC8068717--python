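# Methods

## Standardization and descriptive statistics

Expected counts use indirect standardization: reference rates are
computed per gender × 10-year age band (`0–9, …, 70–79, 80+` by default)
from the pooled study region and period, and applied to each area's own
person-years. Pooling implies the self-standardization identity
`Σ E_i = Σ O_i` (checked to 1e-12 relative tolerance); year-by-year
standardization is deliberately out of scope. Age-group strata
(`0–39, 40–59, 60+`) are unions of the 10-year bands.

The 90%-range fold difference is `q95/q5` of the area SMRs, with
quantiles by linear interpolation between order statistics (the "type 7"
convention — the most widespread default, and the one that reproduces
published fold values from published percentile pairs). Published-style
rounding is half-up to one decimal; Python's bankers' rounding would
disagree on exact halves, so the implementation uses `decimal`.

Map bins are the seven categories symmetric on the log scale
(`<0.50, 0.50–<0.67, 0.67–<0.90, 0.90–<1.10, 1.10–<1.50, 1.50–<2.00,
≥2.00`), left-closed/right-open, with a 3-blues / pale-yellow / 3-browns
suggested colour key.

Rurality deciles rank areas by descending population density; groups are
contiguous with sizes differing by at most one, the remainder going to
the leading (most urban) groups, and ties broken by a stable sort on
area id for reproducibility (1887 areas therefore give seven groups of
189 and three of 188). Covariates are z-scored with the sample (n−1)
standard deviation, equal-weighted across municipalities; the two
right-skewed ones (single-person household % and college-educated %) are
natural-log-transformed first.

## The BYM model and its sampler

`O_i ~ Poisson(E_i θ_i)`, `log θ_i = α + x_iᵀβ + u_i + v_i`, ICAR prior
on `u` (pseudo-density `(n−c)/2·log τ_u − τ_u S_u/2` with
`S_u = Σ_{i~j}(u_i−u_j)²` and `c` connected components), iid
`N(0, 1/τ_v)` on `v`, `Gamma(a=1, b=5·10⁻⁵)` on both precisions (the
conventional default for this model family; rate `b` is configurable and
sensitivity-tested), `N(0, 1000)` on each β, flat α. Areas with `E_i = 0`
carry no likelihood information about a rate and are dropped with a
warning (and must be removed from the graph by the caller, since the
ICAR structure would otherwise silently change).

One MCMC sweep consists of:

1. **v**: single-site adaptive random-walk Metropolis, vectorised — the
   `v_i` are conditionally independent, so simultaneous accept/reject is
   the exact product of single-site kernels.
2. **u**: single-site adaptive random-walk Metropolis swept by graph
   colouring (greedy colouring; a 2-colouring on lattices). Within a
   colour class sites are conditionally independent, so each class
   updates as one vectorised block; the ICAR part of the acceptance
   ratio uses the local form `d_i(u_i'²−u_i²) − 2(u_i'−u_i)(Wu)_i`.
3. **Interweaving**: with `w = u + v` held fixed (the likelihood depends
   on the fields only through `w`), `u | w, τ_u, τ_v` is Gaussian with
   precision `τ_u Q + τ_v I`. In the eigenbasis of `Q` (computed once
   per fit for graphs up to 1500 areas) the coordinates are independent
   and the per-component sum-to-zero constraint is exactly "null-space
   coordinates = 0", so this is an exact constrained Gibbs draw costing
   two dense matvecs. It decouples the u/v split — the classic
   slow mode of BYM samplers — from the single-site dynamics.
4. **Re-centring**: `u` is centred to sum to zero with α absorbing the
   shift (likelihood-invariant on a connected graph). With several
   components the per-component residual centring is a projection in the
   GeoBUGS tradition; pipelines are expected to supply connected graphs
   (sea-route edges exist precisely so that every area has neighbours).
5. **Precisions**: conjugate Gibbs — `τ_u ~ Gamma(a + (n−c)/2, b + S_u/2)`,
   `τ_v ~ Gamma(a + n/2, b + Σv²/2)`.
6. **β single-coordinate** random-walk updates (indicator columns only
   touch their own areas), then an **adaptive joint random walk** on
   `(α, β)` with covariance learned from the burn-in history.
7. **Likelihood-invariant shift moves**: `β → β + δg`,
   `u → u − δ(Xg − mean)`, `α → α − δ·mean` leaves every `η_i`
   unchanged, so the acceptance ratio involves only the ICAR and β
   priors. Directions `g`: each coordinate, plus one collective ramp
   across the decile indicators. These moves let the sampler traverse
   the spatial-confounding flat directions (decile indicators lie along
   the smooth density gradient that `u` can mimic) that defeat plain
   random-walk schemes.

Adaptation (Robbins–Monro on log step sizes, targets 0.44 single-site /
0.234 joint; covariance re-estimation every 50 sweeps) runs only during
burn-in, so the retained chain is Markovian. A fixed seed yields
bit-identical draws (chains use `SeedSequence.spawn`). Non-finite states
abort with the offending state attached. Point estimates are posterior
medians (robust under the exp transform); intervals are equal-tailed
95%; a coefficient is flagged significant when its interval excludes 1.
Split-R̂ and effective sample size come from ArviZ; a single chain is
split in half for R̂; quantities below 200 effective draws are reported
with a low-ESS flag rather than suppressed. Smoothed SMRs
(`exp(α+u+v)`) are taken from the covariate-free model and residual
SMRs (`exp(u+v)`) from the fully adjusted model; both conventions are
available on any fitted model, since the attribution of smoothing
between model variants is a genuinely open choice.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
not any real geography: a 4-neighbour lattice (default 20×20 = 400
areas, chosen so a full recovery experiment runs in minutes), optional
detached islands re-attached by single sea-route edges; log-density
smooth in space spanning ~2–20,000 persons/km²; population following
`log pop = log 30000 + 0.55·(log density − median)` — the exponent
reflects that rural municipalities are geographically larger, so
population spans fewer orders of magnitude than density, and the anchor
matches a realistic median municipal population of ~30,000; nine pooled
years of exposure; age-band profiles with suicide-like rates rising
steeply from childhood to old age and female rates ~40% of male; four
spatially correlated covariates loading on log-density, two of them
log-normal (right-skewed); and counts drawn from the BYM model with
true fields `u` (ICAR, τ_u = 25 → marginal sd ≈ 0.14) and `v`
(τ_v = 100 → sd 0.1), and per-decile log rate ratios rising linearly to
`log 1.2` in the most rural decile. These defaults put the smoothed-SMR
90%-range fold near 1.5–1.7, the dispersion scale typical of national
suicide mapping.

Constrained ICAR fields are drawn spectrally per component (exact) up to
2000 areas; larger components use `u = Q⁺Aᵀz/√τ` with `A` the edge
incidence matrix — `Cov(u) = Q⁺/τ` exactly — solved by conjugate
gradients on the sum-to-zero subspace, which stays sparse.

What passing recovery tests on these data do **not** show: robustness to
real-world features the generator omits — irregular adjacency with
highly variable degree, population sizes correlated with covariates in
unmodelled ways, non-Poisson overdispersion beyond the latent fields,
and secular time trends (the model is purely spatial).

## Numerical choices and limitations

* Quantile convention, rounding rule, decile tie-breaks, and (n−1)
  z-scores as above; all configurable only where a published convention
  does not pin them down.
* The eigendecomposition-based interweaving is skipped above 1500 areas;
  fits remain correct but mix more slowly there — relevant for
  full-country graphs (~2000 areas), where longer chains are advised.
* The reference category for rate ratios is the most urban decile;
  reference rows carry RR 1 with empty intervals.
* Exclusion accounting counts events whose area id is missing/unknown or
  whose age band is missing; they are reported in the manifest, never
  silently dropped.
* Recovery experiments run single chains (medians and intervals only);
  the per-replicate convergence flag uses split-half R̂ and is strict —
  non-converged fits are counted and reported, not discarded.
* The paper-scale problem (1887 municipalities, full stratification)
  is supported by the same code paths but is not exercised in the test
  suite; test and acceptance runs use the 400-area default scale.
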