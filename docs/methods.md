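# Methods

## Model

The package implements a single-session spatially-explicit
capture-recapture (SCR) model for unstructured, multi-protocol surveys,
with Bayesian data augmentation.

**State process.**  The state-space is a regular lattice of equal-area
pixels (default 0.5 km²) covering the survey extent plus a buffer
(default 15 km), with non-habitat pixels removed; a pixel is habitat iff
its centroid falls outside the mask polygons (or on an "on" raster
cell).  The unknown population is embedded in a super-population of
`M` pseudo-individuals.  Each carries an inclusion indicator
`z_i ~ Bernoulli(psi)`, a sex `~ Bernoulli(psi_sex)` (1 = male), and an
activity center `s_i` uniform over habitat pixels.  Realized abundance in
any region is the count of included individuals whose activity center
falls inside it; `N_super = sum(z)` is abundance over the whole
state-space.

**Observation process.**  A trap is any 1 km² grid cell with search or
playback effort on at least one daily occasion.  Detections are Bernoulli
per individual × trap cell × occasion, with a complementary log-log
linear predictor

    cloglog(pi_ijk) = log(lambda0) + beta_eff * log(effort_jk)
                      + beta_eff2 * playback_jk + beta_sex * sex_i
                      - (d_ij^2 / (2 sigma_sex^2))^theta

`theta` is fixed at 1 (half-normal detection) but exposed.  Multiple
sightings of one individual in the same cell-occasion collapse to one
binary detection.  Cell-occasions with no effort are structurally outside
the likelihood: no effort, no detection.  Four candidate structures tie
or free the sex-specificity of the encounter rate (via `beta_sex`) and of
`sigma`; model 1 frees both, model 3 neither.  Making the basal rate
sex-specific through the cloglog offset `beta_sex` is equivalent to a
male/female rate pair with `lambda0_M = lambda0 * exp(beta_sex)`, and is
how the single reported `lambda0` plus `beta_sex` should be read.

A playback-only cell-occasion (playback = 1, zero search km) contributes
no log-effort term rather than log(0); in practice playbacks happen on
cells that were driven to, so the case is rare, but the convention keeps
the predictor finite.

## Parameters, units, defaults

| parameter | meaning | unit | default prior |
|---|---|---|---|
| `lambda0` | female basal encounter rate at a trap centroid with 1 km effort | per occasion | log-uniform on (-20, 5) |
| `sigma_f`, `sigma_m` | movement / detection spatial scale | km | Uniform(0, buffer width) |
| `beta_eff` | effect of log search-km | cloglog units | Normal(0, 10) |
| `beta_eff2` | playback indicator effect | cloglog units | Normal(0, 10) |
| `beta_sex` | male offset | cloglog units | Normal(0, 10) |
| `psi` | augmentation inclusion probability | — | Uniform(0, 1) |
| `psi_sex` | probability an individual is male | — | Uniform(0, 1) |

The analysis this package follows cites its priors from earlier work
without restating them; the table above is this package's own
weakly-informative choice, and every prior is configurable
(`lionscr.model.Priors`).  Parameter recovery, not prior minutiae, is
what the test suite checks.

## Sampler

Metropolis-within-Gibbs, chosen over HMC or an off-the-shelf PPL so the
data-augmentation structure matches the SCR sampler lineage:

* `z` for all-zero augmented individuals: Gibbs draw with
  `p* = psi p0 / (psi p0 + 1 - psi)`, `p0` the probability of an all-miss
  history at the current activity center.
* `s` for included individuals: symmetric discretized random walk
  (uniform offsets in a ±5-pixel window), accepted on the individual's
  detection likelihood ratio; proposals into non-habitat are rejected.
  For excluded individuals `s` and sex are prior draws (exact Gibbs).
* sex for included individuals without an observed label: Gibbs using the
  likelihood under both sexes.
* `psi`, `psi_sex`: conjugate Beta draws under the uniform priors.
* `lambda0`, `sigma` (log scale) and the betas (identity): Gaussian
  random-walk Metropolis, one block each.  Proposal scales adapt toward a
  0.2–0.5 acceptance rate during burn-in only, so the post-burn-in chain
  has the correct stationary distribution.  The log-scale sigma walk
  includes the Jacobian term for its Uniform-on-sigma prior.

The per-individual likelihood factorizes as
`-Lambda_i + sum_detections h(eta)` with
`Lambda_i = lambda0 e^{beta_sex sex} sum_j K_ij E_j`, where `K` is the
distance kernel over (individual, trap) and
`E_j = sum_k exp(beta_eff log effort_jk + beta_eff2 playback_jk)` collects
the effort covariates per trap.  `K` and `E` are maintained
incrementally, which is what makes 4 × 51,000 iterations at M = 250
practical; the incremental log-likelihood is unit-tested against a plain
reference implementation at stored iterations.

Initial values are over-dispersed per chain: parameters drawn from wide
truncated ranges, observed activity centers at the habitat pixel nearest
the mean of each individual's detection locations, augmented ones
uniform.  Non-finite initial likelihoods trigger a bounded redraw.  All
randomness flows from one seed through per-chain substreams; a fixed
seed + config + data reproduces output bit-identically.

Numerical care: `h(eta) = log(exp(exp(eta)) - 1)` switches to its
asymptote for large rates and `log(expm1(.))` otherwise; miss
probabilities use `-exp(eta)` directly, so nothing ever exponentiates a
probability of 1.

## Diagnostics

* **R-hat** — classic between/within Gelman-Rubin PSRF; convergence is
  declared at R-hat ≤ 1.05.  A split-chain option covers single-chain use.
* **HPD** — shortest contiguous window containing `ceil(mass n)` sorted
  draws; ties go to the earliest window, making it brute-force
  verifiable.
* **Bayesian p-value** — the analysis lineage does not pin down the
  discrepancy; this package uses the Freeman-Tukey statistic on
  individual encounter frequencies over included individuals (a standard
  choice in that lineage), simulated at stored latent draws.  The
  statistic is pluggable in principle (the function is self-contained);
  values outside ~(0.15, 0.85) flag misfit.
* **MLHM** — harmonic-mean estimator of the log marginal likelihood from
  the stored complete-data log-likelihood draws, computed in log space.
  It is reported per model for ranking; no composite of the three
  model-choice criteria (p-value, MLHM, correlation plots) is invented,
  since the original model choice weighed them judgmentally.

## Derived quantities

The density surface is the per-pixel posterior mean count of included
activity centers, computed from latent draws stored every
`latent_stride` (default 10) iterations; its total equals mean `N_super`
by construction, which is asserted on every fit.  Survey-area abundance
is computed both ways the analysis reports it — area × posterior mean
density, and draw-wise pixel sums — and the two agree by construction up
to draw thinning.  The buffered region uses
`sigma_bar = psi_sex sigma_M + (1 - psi_sex) sigma_F` — weighting by the
posterior sex proportion, which reproduces the reported 1.88 km scale —
and is the union of `sigma_bar`-radius discs around trap centroids,
discretized to pixels (disc union rather than hull dilation; the original
construction is not stated).  Count-based weights can be passed instead.

## Synthetic surveys

The generator emulates what the detection model sees, not the field
logistics.  Daily effort is a bounded random-walk patrol (legs of 1.5 km
within 5 km of a daily center, drawn uniformly over the survey square)
summing to 30.3 km/day for 89 days ≈ 2697 km, rasterized to per-cell
kilometres by exact segment clipping; 14 playback events sit on track
vertices.  The leg length and patrol radius were chosen so that, with the
reported parameter values, simulated surveys yield detection totals on
the scale of the field survey (median ≈ 90 detections of ≈ 16–20
individuals across seeds, against 84 of 19 in the field).  What the
generator deliberately omits: road networks and revisit habits, GPS
error, social structure (activity centers are independent, which lions
violate; SCR is reported robust to this), temporary emigration, and any
behavioral response to playbacks beyond the indicator covariate.  Passing
recovery tests therefore demonstrates estimator correctness under the
model's own assumptions at realistic data scale — not robustness to the
ways real surveys break those assumptions.

## Test-scale choices

The enumeration oracle uses 3 habitat pixels, 1 trap, 2 occasions, M = 3
with fixed parameters, where the (z, s, sex) posterior is exhaustively
enumerable; the sampler (latent updates only) must match within 3
chain-level standard errors.  The parameter-recovery experiment runs 20
synthetic surveys at full survey scale (M = 250, 89 occasions, ~2700 km)
fitted with 4 × 5,000-iteration chains — long enough that R-hats sit near
1.00–1.03 — checking 95% HPD coverage of density, `lambda0` and `sigma`
(≥ 90% of replicates) and posterior-mean density bias (within ±15%), with
posterior predictive p-values collected from the same fits.  The recovery
experiment uses the shared-parameter model (model 3) so the generating
values are exactly the fitted ones.

## Known limitations

* The harmonic-mean marginal likelihood estimator is famously
  high-variance; it is provided because it is the model-ranking statistic
  this workflow reports, not because it is the best available.
* `psi` (and hence `N_super`) retains noticeable prior influence at
  ~19 observed individuals; regional abundance and density, which the
  survey actually reports, are much better identified.
* Binary detections discard within-cell-day repeat sightings; a count
  model is out of scope.
* Coordinates are planar km; project lon/lat data locally before use.
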