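# Methods

## The problem

Underwater-visual-census programmes for coastal fish produce short annual
time series of population density (here: one protected and two fished
rocky-shore locations, 12 survey years, 8–32 replicate strip transects per
location × year). The scientific questions are (i) whether population
growth depends on current density at each location, and in which functional
form; (ii) how uncertain the fitted demographic parameters are given census
error and small-scale spatial variability; and (iii) what the fitted
dynamics imply for long-run viability (the risk that density falls below a
depletion threshold) and for the fishing mortality implied by the
protected/unprotected growth-rate gap.

Detecting density dependence from such series is delicate: regressing the
realized growth rate ln(N_{t+1}/N_t) on N_t spuriously detects density
dependence, because census error in N_t enters both axes with opposite
signs. This package follows the comparative route instead: fit a family of
density-independent and density-dependent models by maximum likelihood on
the raw transition errors, rank them by AICc, and read the evidence off
Akaike weights. Census error enters through a stratified bootstrap of the
transects, not through the likelihood.

## The models

Five unstructured one-step maps on the annual density N_t (individuals/m²):

| form            | N̂_{t+1} = f(N_t)      | parameters |
|-----------------|------------------------|------------|
| random walk     | N_t                    | —          |
| exponential     | λN_t                   | λ          |
| Ricker          | λN_t e^{−βN_t}         | λ, β       |
| Gompertz        | λN_t e^{−β ln N_t}     | λ, β       |
| theta-logistic  | λN_t e^{−βN_t^θ}       | λ, β, θ    |

λ is the finite growth rate in the density-independent limit
(dimensionless per year-step), β the density-dependence strength (units
depend on the form), θ a dimensionless nonlinearity exponent. The
stochastic model adds ε_t ~ N(0, σ_ε²) **on the density scale**:
N_{t+1} = max(0, f(N_t) + ε_t). Additive (rather than log-additive) noise
is deliberate — the locations are open to larval and juvenile exchange, and
an additive term can represent a net inflow that rescues a collapsed
population; this is also why depletion is treated as non-absorbing.

Closed-form equilibria: Ricker ln(λ)/β, Gompertz exp(ln(λ)/β),
theta-logistic (ln(λ)/β)^{1/θ}; the density-independent forms have none.
Parameter combinations without a positive fixed point report "none" rather
than raising.

Numerical conventions:

- The Gompertz log is the natural log. The map is undefined at N = 0: the
  likelihood refuses series containing zeros, while the simulator defines
  the deterministic part as 0 there (a positive noise draw can still rescue
  the population).
- Negative post-noise densities are clamped to 0 (densities are physical).
- θ is constrained to (0, 5] during fitting; the β–θ trade-off makes an
  unbounded theta-logistic non-robust on short series, and for the same
  reason the theta-logistic is excluded from evidence sums by default
  (which also balances the density-dependent and -independent halves of the
  candidate set).

## Multi-location configurations

A configuration assigns a form to each location plus a sharing pattern:
for each dynamic parameter, a partition of the same-form locations into
blocks that share one free value. Error SDs follow a fixed rule — one σ_ε
per group of same-form locations — so σ grouping is induced by the form
assignment, not enumerated. The free-parameter count k is the number of
dynamic blocks plus the number of σ groups.

Two enumeration schemes: `independent_only` (every form assignment, no
cross-location sharing; 5^L configs) and `full` (additionally, for every
maximal same-form group, every set partition of the group's locations,
independently per dynamic parameter). For three locations the full scheme
yields 469 deduplicated configs in a deterministic order. The scheme is a
definition of this package; a study could restrict or extend it through
the manifest.

## Calibration

For each location and each consecutive-calendar-year transition (gaps in
the survey are skipped, never bridged), the prediction error is
ε_{i,t} = N_{i,t+1} − f_i(N_{i,t}) and the objective is the Gaussian
negative log-likelihood L = −Σ ln φ(ε_{i,t}; 0, σ²) with σ taken from the
location's σ group. Because the errors are Gaussian, each group's σ has the
closed-form MLE σ̂² = mean(ε²), so the search runs over the dynamic
parameters only (profiling and joint optimization share the same optimum).
σ̂ is floored at 1e-8 ind./m² to keep L finite on noise-free input.

The search uses transformed coordinates (log λ, untransformed β, scaled
logit of θ/5) with one moment-based start (λ from the least-squares slope
through the origin, β from a crude regression of ln(N_{t+1}/N_t) on N_t or
ln N_t, θ = 1) plus nine jittered starts by default. Each start runs a
Nelder–Mead descent; the best point is polished by a tight simplex pass and
finally by solving ∇L = 0 with the analytic gradient (a root solve rather
than a line search, because near the optimum the objective is flat to
machine precision while the gradient retains full relative accuracy —
derivative-free polishing alone floors out around 1e-9 in the parameters).
Fits are deterministic given the seed. β is unconstrained in sign;
equilibrium reporting treats non-positive ln(λ)/β as "no equilibrium".

Model selection: AICc = 2L + 2k + 2k(k+1)/(n − k − 1) with n the number of
transitions pooled over the config's locations (the unit over which the
likelihood factorizes; for three complete 12-year series n = 33). When
n ≤ k + 1 the criterion is undefined: the fit carries AICc = NaN and is
excluded from ranking. Akaike weights w_i = exp(−Δ_i/2)/Σ exp(−Δ_k/2);
evidence for a hypothesis is the summed weight of the configs satisfying
it, after dropping configs that use an excluded form at any location and
renormalizing. Multi-model prediction renormalizes the top-m weights
(default m = 3) and averages member predictions.

## Bootstrap

Parameter uncertainty comes from resampling transects with replacement
within each location × year stratum (same size, independent strata),
re-aggregating to annual means and refitting. Central tendency is the
median (less sensitive to the extreme refits resampling can produce);
spread is reported as mean ± SD, median (IQR) and the empirical 5th–95th
percentile 90% interval. Replicate refits use fewer starts and skip the
final polish (percentile summaries do not need 1e-10 accuracy). Failed
refits are dropped and counted; above a 10% failure rate the bootstrap
aborts, since a config that cannot be refitted on resampled data should
not be summarized silently. Model *ranking* is computed once on the
original annual means; the bootstrap quantifies parameter uncertainty for
a given configuration.

**What this bootstrap does and does not capture.** Resampling transects
propagates census error and local spatial variability — nothing else. The
sampling variation of the estimates across hypothetical re-runs of history
(different process-noise realizations over the same 11 transitions) is
substantially larger in study-like conditions: in the suite's coverage
experiment (true Ricker, λ = 3.66, β = 19.11, σ_ε = 0.024, 12 years, 24
transects, census CV 0.3), the across-realization SD of λ̂ is ≈ 1.3 (with
a small-sample upward bias) while the transect-bootstrap 90% interval is
only ≈ 1 wide, so those intervals cover the generating parameters in
roughly 40% of replicate surveys, not 90%. Passing the rest of the suite
therefore says nothing about frequentist coverage of the bootstrap CIs
with respect to process noise; they quantify census-error uncertainty
conditional on the one observed trajectory. A parametric/process bootstrap
would be required for the stronger guarantee and is deliberately out of
scope.

## Population viability analysis

Each location starts at the mean of its observed annual means and is
stepped forward ``horizon`` years (default 100) with the fitted stochastic
map, 10^5 Monte-Carlo runs by default. Depletion is the first year the
density falls strictly below a threshold; a run starting at or below the
threshold is depleted at time 0 by definition. Crossings are non-absorbing:
only the first is recorded and the run continues (immigration can rescue
the population). Reported per threshold: depletion probability and the
mean first-crossing year over depleted runs (undefined when none crossed —
and barely meaningful when few did). The default threshold grid is
logarithmic, 1e-4 to 1e-1 ind./m².

Two ensemble modes combine the top-m ranked models: ``average`` (default)
steps with the AICc-weighted mean deterministic map and weighted-mean σ,
matching the averaged prediction curves; ``sample`` draws one member per
run with probability equal to its renormalized weight, which preserves
between-model variance. The choice of mode is a genuine degree of freedom
of multi-model forecasting; both are exposed.

## Derived quantities

If the protected population's growth rate reflects natural mortality only
(λ_prot = e^{−M}) and the fished one adds fishing mortality
(λ_unprot = e^{−(M+F)}), then F = ln(λ_prot/λ_unprot) yr⁻¹ and the annual
removal fraction is 1 − e^{−F}. This is an upper-bound attribution (the
whole gap is ascribed to fishing); M and Z are not separately estimable. A
negative F is returned as-is with a net-subsidy flag. The function takes
explicit λ inputs — it never silently substitutes model-averaged values;
callers choose the source.

## Synthetic surveys

The generator emulates the survey the analysis assumes: annual truths
simulated from a chosen form with additive process noise; per-transect
censuses drawn around the annual truth with a multiplicative error of
coefficient of variation ``spatial_cv`` (default 0.3) — Gamma by default
(guarantees positivity), truncated Normal as an alternative; transect
counts fixed or drawn uniformly from a range (default 8–32 per stratum).
The default scenario uses the study-like values: Ricker (λ = 3.66,
β = 19.11, σ_ε = 0.024) at the protected location, Ricker (λ = 1.49, same
β and σ) at the southern fished location, random walk (σ_ε = 0.007) at the
northern one, initial densities 0.070/0.010/0.022 ind./m², 12 years.

What the generator does **not** emulate: spatial correlation between
transects (the survey design enforced ≥50 m spacing), observer effects,
within-year seasonal structure (two surveys in a year are pooled, exactly
as the analysis pools them), and any exchange of individuals between
locations beyond what the noise term absorbs. Tests passing on synthetic
surveys therefore validate the estimation machinery under the model's own
assumptions, not the assumptions themselves.

## Problem sizes used in the test suite

The suite runs the full chain at reduced but study-shaped sizes chosen as
the package's own defaults for routine verification: bootstrap coverage at
B = 200 over 50 replicate surveys; spurious-detection screening over 100
12-year random-walk surveys; PVA invariant checks at 5×10³–10⁴ runs; the
demo pipeline at B = 100 and 10⁴ PVA runs. The library defaults remain
B = 1000 and 10⁵ runs.

## Known limitations

- AICc ranking is computed on one aggregation of the data; ranking
  uncertainty (model-selection variability under resampling) is available
  only as a sensitivity flag, not propagated by default.
- The transect bootstrap understates total parameter uncertainty (see
  above); Table-style summaries should be read as census-error intervals.
- Maximum-likelihood estimates of density-dependence strength on ~11
  transitions carry noticeable small-sample bias (λ̂ high by ~15% in the
  suite's study-like experiment); no bias correction is applied.
- The theta-logistic is fitted but excluded from evidence by default; its
  estimates are reported only on explicit request.
- No age/size structure, no explicit migration, no demographic
  (integer-individual) stochasticity.
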