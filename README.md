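# densdep

Detecting density dependence in census time series of protected and
exploited fish populations — maximum-likelihood calibration of
multi-location stochastic demographic models, AICc multi-model inference,
stratified transect bootstrap, and downstream population viability
analysis.

The package is aimed at ecologists analysing underwater-visual-census
monitoring data: short annual series of population density (individuals/m²)
at a handful of locations — typically a marine protected area and nearby
fished sites — with replicate strip transects per location and year.

## What it computes

Five unstructured one-step models for annual density `N_t` are contrasted:
random walk (`N_{t+1} = N_t + ε_t`), exponential growth (`λN_t + ε_t`),
Ricker (`λN_t e^{−βN_t} + ε_t`), Gompertz (`λN_t e^{−β ln N_t} + ε_t`) and
theta-logistic (`λN_t e^{−βN_t^θ} + ε_t`), with additive Gaussian noise
`ε_t ~ N(0, σ_ε²)` that can absorb exchange of individuals with the
surroundings. Multi-location configurations may share a functional form
and any subset of parameters across locations.

Each configuration is fitted by minimizing the Gaussian negative
log-likelihood of the one-step prediction errors (σ profiled out in closed
form), scored with `AICc = 2L + 2k + 2k(k+1)/(n−k−1)` over the pooled
transitions, and ranked; Akaike weights `w_i ∝ exp(−Δ_i/2)` give the
strength of evidence for individual models and for hypotheses such as
"density dependence at the protected location" or "shared β across sites".
Parameter uncertainty comes from a stratified bootstrap that resamples
transects within each location × year stratum and refits. The selected
model ensemble drives a Monte-Carlo viability analysis (probability of,
and expected time to, first crossing of a depletion threshold) and
management quantities such as the implied fishing mortality
`F = ln(λ_protected/λ_unprotected)` with annual removal `1 − e^{−F}`.

A synthetic-survey generator with the same statistical structure (process
noise at the annual level, CV-parameterized census error at the transect
level, 8–32 transects per stratum) makes every stage testable without any
field data. See `docs/methods.md` for the full model description,
numerical choices and limitations.

## Worked example

```python
import densdep as dd

# equilibrium of a fitted Ricker model (protected location medians)
eq = dd.equilibrium_density("ricker", {"lambda": 3.66, "beta": 19.11})
print(f"equilibrium density (MPA): {eq:.3f} ind/m^2")

# fishing mortality implied by the protected/fished growth-rate gap
mp = dd.fishing_mortality(3.66, 1.49)
print(f"F = {mp.F:.2f} /yr, annual removal = {100*mp.removal_fraction:.0f}%")

# fit the best-ranked structure to a synthetic study-like survey
data, truth = dd.generate_dataset(dd.default_study_spec(), seed=1)
series = dd.annual_means(data)
cfg = dd.ModelConfig.build(
    {"EXT/N": "random_walk", "MPA": "ricker", "EXT/S": "ricker"},
    {"beta": [["MPA", "EXT/S"]]},
)
print(dd.fit_config(cfg, series, seed=1).summary())
```

prints

```
equilibrium density (MPA): 0.068 ind/m^2
F = 0.90 /yr, annual removal = 59%
Model fit
========================================================
config:  EXT/N:random_walk|EXT/S:ricker|MPA:ricker;lambda=EXT/S,MPA;beta=EXT/S+MPA
n transitions:    33    k: 5
-log L:   -94.892391    AICc: -177.562559
--------------------------------------------------------
parameter                         estimate
lambda@EXT/S                      0.501383
lambda@MPA                         4.63337
beta@EXT/S+MPA                     19.2788
sigma@EXT/N                     0.00427151
sigma@EXT/S+MPA                  0.0243846
========================================================
```

The equilibrium is the positive fixed point `ln(λ)/β` of the Ricker map —
the density at which the protected population would settle without noise.
`F` is an upper-bound attribution of the whole growth-rate gap to fishing.
In the fitted summary, `k = 5` counts the free values (two growth rates, a
shared density-dependence strength, and one error SD per form group) and
`n = 33` the pooled year-to-year transitions; the shared β ≈ 19.3 and
σ ≈ 0.024 recover the generating values of the synthetic survey, while the
two λ's are noticeably noisier — on 11 transitions per site they are
identified mainly through the narrow range of densities each site visits.

The command line mirrors the library: `densdep demo --seed 1 --out out/`
runs the whole synthetic pipeline (fit all 469 multi-location
configurations, rank, bootstrap the best one, viability analysis, derived
quantities) in a few minutes and writes plotting-ready CSVs plus a
`summary.txt`; `densdep report --input survey.csv ...` does the same for
your own transect table with columns `location,year,transect_id,density`.

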