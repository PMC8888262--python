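# lionscr

Bayesian spatially-explicit capture-recapture (SCR) for **unstructured,
multi-protocol carnivore surveys**: vehicle-based search-encounter driving
plus playback stations, with individuals identified from photographs.  The
package takes raw effort logs (search-track kilometres, playback events)
and capture histories, and returns posterior density surfaces, abundance
with credible intervals, and model-selection diagnostics.  It was built
for lion surveys in human-dominated rangelands — where animals are not
habituated to vehicles and most work happens at night — but nothing in
the model is lion-specific.

## The model

Space is discretized into a state-space of equal-area pixels (default
0.5 km²) covering the survey area plus a buffer (default 15 km), with
non-habitat pixels masked out.  A "trap" is any 1 km² grid cell that
received effort on at least one daily occasion.  The unknown population is
embedded in an augmented super-population of *M* pseudo-individuals, each
with an inclusion indicator *z<sub>i</sub>* ~ Bernoulli(ψ), a sex
~ Bernoulli(ψ<sub>sex</sub>), and a latent activity center
*s<sub>i</sub>* uniform over habitat pixels.  Detection of individual *i*
in trap cell *j* on occasion *k* is Bernoulli(π<sub>ijk</sub>) with

```
cloglog(π_ijk) = log λ0 + β_eff · log(effort_jk) + β_eff2 · effort2_jk
                 + β_sex · sex_i − (d_ij² / 2σ²_sex)^θ
```

where `effort_jk` is search kilometres in the cell that day, `effort2_jk`
a 0/1 playback indicator, `d_ij` the distance from the activity center to
the cell centroid, and θ = 1 fixes a half-normal detection function.
Four candidate models make λ0 (via the cloglog male offset β<sub>sex</sub>)
and/or σ sex-specific: (1) both, (2) σ only, (3) neither, (4) λ0 only.

Fitting is by Metropolis-within-Gibbs MCMC (data-augmentation updates for
*z*, lattice random walks for *s*, conjugate draws for ψ and
ψ<sub>sex</sub>, random-walk Metropolis for the rest), by default 4 chains
of 51,000 iterations with a 1,000-iteration burn-in.  Diagnostics follow
the standard SCR workflow: Gelman-Rubin R-hat (threshold 1.05), 95%
highest-posterior-density intervals, a Freeman-Tukey posterior predictive
p-value, the harmonic-mean log marginal likelihood (MLHM) for ranking the
four models, and pairwise parameter correlations.  Derived quantities
include the pixel density surface, density per 100 km², abundance within
arbitrary regions, and abundance within a buffer of width
σ̄ = ψ<sub>sex</sub>·σ<sub>M</sub> + (1−ψ<sub>sex</sub>)·σ<sub>F</sub>
around the trap array.

A first-class synthetic-survey generator (`lionscr.simulate`) reproduces
the study conditions — 89 daily occasions, ~2700 km of search track over
a 358 km² survey square, 14 playbacks, M = 250, σ ≈ 1.8–2.0 km,
λ0 ≈ 0.003 — so the whole pipeline is testable without any field data.

## Worked example

```python
from lionscr import (SimulationConfig, ModelSpec, Parameters, ChainConfig,
                     generate_dataset, run, summarize, abundance_in_region,
                     bayesian_p_value)

spec = ModelSpec.from_model_number(3, M=60)     # shared lambda0 and sigma
truth = Parameters(lambda0=0.05, sigma_f=1.5, sigma_m=1.5, beta_eff=2.0,
                   beta_eff2=0.3, beta_sex=0.0, psi=0.5, psi_sex=0.4)
config = SimulationConfig(seed=42, survey_area_km2=64.0, n_occasions=15,
                          km_per_occasion=25.0, n_playbacks=3, buffer_km=6.0,
                          M=60, truth=truth, spec=spec)
bundle = generate_dataset(config)
print(f"detected {bundle.capture.n_observed} of {bundle.truth.n_super} "
      f"included individuals ({int(bundle.capture.y.sum())} detections)")

chains = ChainConfig(seed=9, n_chains=4, n_iter=3000, burn_in=500, latent_stride=5)
samples = run(spec, bundle.capture, bundle.state_space, chains)

survey = abundance_in_region(samples, bundle.survey_mask(),
                             bundle.state_space, area_km2=64.0)
density = survey.draws / 64.0 * 100.0
print(summarize(samples, derived={"D_per_100km2": density}).round(3))
print("Bayesian p-value:",
      bayesian_p_value(samples, bundle.capture, bundle.state_space, seed=1))
```

prints

```
detected 9 of 27 included individuals (53 detections)
                mean    psd  hpd_lower  hpd_upper   rhat
parameter
sigma          1.518  0.168      1.211      1.835  1.007
beta_eff       2.474  0.307      1.891      3.089  1.009
beta_eff2     -7.933  6.037    -19.565      1.415  1.002
lambda0        0.037  0.014      0.013      0.066  1.004
psi            0.453  0.139      0.198      0.730  1.001
psi_sex        0.272  0.127      0.049      0.522  1.000
n_super       27.057  7.755     12.000     41.000  1.001
D_per_100km2  11.147  2.212      6.250     14.062  1.004
Bayesian p-value: 0.54
```

The generating values (σ = 1.5 km, λ0 = 0.05, β_eff = 2.0, realized
density 12.5/100 km²) fall inside every 95% HPD; all R-hats are at 1.0 and
the posterior predictive p-value is central, indicating adequate fit.
The playback coefficient is essentially unidentified here — only three
playbacks occurred and none yielded a detection — so its posterior just
reflects the prior, as expected.

A command-line interface wraps the same pipeline:

```
lionscr simulate -c sim.yml -o bundle/
lionscr fit -c fit.yml                 # one or all four candidate models
lionscr summarize --fit-dir fits/model1
lionscr density-map --fit-dir fits/model1 -o maps/ --region survey.geojson
```

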