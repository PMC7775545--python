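# Methods

`phenobridge` predicts rice days to heading (DTH) by combining a
process-based phenology model with Bayesian calibration and a
machine-learning bridge from marker genotypes to the model's
genotype-specific parameters.  This note documents the models, the
defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions.

## The DVR phenology model

Pre-heading development is tracked by a dimensionless developmental
stage DVS, 0 at sowing and 1 at heading, accumulated daily:

    DVS_d = sum_{i<=d} DVR_i

Each day's developmental rate multiplies a temperature response `f` and
(inside the photoperiod-sensitive phase) a photoperiod response `g`:

    DVR_i = f(T_i) / G                    DVS < DVS1 or DVS > DVS2
    DVR_i = f(T_i) g(P_i) / G             DVS1 <= DVS < DVS2

`f` and `g` are beta functions over cardinal values (base/optimum/
ceiling).  Temperatures use 8/30/42 degC; photoperiods 0/10/24 h.
`f` is 0 at or outside base/ceiling and 1 at the optimum; because rice
is a short-day plant, `g` is 1 at or below the 10 h optimum and decays
to 0 at the ceiling, so long days slow development.  Genotype-specific
parameters:

| parameter | meaning | calibration range |
|---|---|---|
| alpha | temperature sensitivity exponent | 0-20 |
| beta  | photoperiod sensitivity exponent | 0-25 |
| G     | days to heading under optimal conditions | 30-120 d |

The sensitive window is tied to G: `DVS1 = 0.145 + 0.005 G`,
`DVS2 = 0.345 + 0.005 G` (width 0.2 always).

Numerical conventions (degenerate cases are resolved once, here):

* Daily Euler step.  The branch for day *i* is chosen from the DVS
  accumulated **through day i-1**; the sensitive branch applies on the
  half-open window `[DVS1, DVS2)`.
* DVS integration starts at sowing (day offset 0 is the sowing day);
  no sowing-to-emergence lag is modelled, because integer DTH from the
  sowing date is the fitted and reported quantity.
* DTH is the 1-based index of the first day with DVS >= 1 - 1e-9 (the
  epsilon absorbs accumulated rounding in ~100-term sums); there is no
  sub-day interpolation, matching date-resolution observations.
* A trajectory that does not reach DVS = 1 within `max_days`
  (default 200) is censored.
* alpha = 0 (a prior bound) gives f = 1 inside the cardinal range and
  0 outside, never NaN.

Day length is the CBM model (revolution angle, declination, day-length
formula).  The twilight coefficient is configurable in degrees of solar
elevation and defaults to 0 (geometric sunrise-sunset of the solar
centre): the source for "theoretical day length" does not state a
twilight convention, and the 10 h optimum photoperiod is calibrated
jointly with whatever convention is used, so the geometric choice is
the neutral one.

## DREAM calibration

Per genotype, the posterior of (alpha, beta, G) is sampled with the
DREAM algorithm: multiple chains (default 10, at least 2x the number of
parameters + 1) propose differential-evolution jumps built from other
chains' states, which self-tunes the proposal scale and orientation —
important here because the three parameters are strongly correlated a
posteriori (a larger alpha can compensate a smaller G) and the
posterior can be multimodal.

Priors are truncated normals: alpha ~ N(3,1) on [0,20], beta ~ N(4,1)
on [0,25], G ~ N(35,2) on [30,120] days.  Note the G prior is tight;
with few observations per genotype posterior means of G shrink several
days toward 35.

Operator constants (standard published values, restated here because
they are package defaults): delta pairs sampled from {1,2,3}; jump rate
`gamma = 2.38 / sqrt(2 delta d')` with a unit jump (`gamma = 1`,
enabling mode hopping) with probability 0.2; three crossover levels
CR in {1/3, 2/3, 1} with selection probabilities adapted from
normalized jump distances during burn-in only; multiplicative jitter
U(-0.05, 0.05) and additive noise N(0, 1e-6); out-of-bound proposals
reflected at the violated bound, then clamped.  Outlier chains (mean
log-posterior over the last half of burn-in below Q1 - 2 IQR) are reset
to the best chain's state, during burn-in only, so retained draws form
a valid MCMC sample.

Likelihood: observed DTH is the crop-model prediction plus iid Gaussian
error with scale `sigma_obs` (config; default 2 days for observational
data — heading is scored as a calendar date on a plot, so day-scale
error is the floor).  When fitting data whose noise level is known
(e.g. the synthetic generator's 1 day), set `sigma_obs` to it.  An
alternative likelihood with the error variance concentrated out
(`-n/2 log SSE`) is selectable.  A censored simulation contributes the
finite residual `max_days - observed + 30` days: strongly unfavorable
but finite, so chains remain mobile instead of being absorbed by -inf.

Counting conventions: `n_iterations` is generations per chain;
`n_burn_in` and `n_keep` count pooled draws (generation-major order,
chains within a generation).  After dropping burn-in, the pool is
thinned evenly to exactly `n_keep`.  Convergence is monitored by the
Gelman-Rubin statistic on the post-burn-in generations; estimates with
rhat > 1.2 are flagged, not dropped.  The posterior mode is reported as
the midpoint of the highest Freedman-Diaconis histogram bin per
marginal (a mode estimator is needed for reporting but none is implied
by the model; this one is deterministic and scale-free).  Posterior
*means* are the point estimates used everywhere downstream.

## Machine-learning bridge

Markers are one-hot encoded: one indicator column per observed level
per marker (no reference level is dropped — tree ensembles are
indifferent and the ELM readout handles the collinearity via the
minimum-norm solve).  Missing codes are imputed to the marker's modal
level.  A level unseen at training (a heterozygote among inbred
training lines) maps to all-zero dummies for that marker.

Back-ends behind one fit/predict surface:

* **ELM** (written from its definition): features centred/scaled,
  hidden weights and biases drawn uniform [-1, 1] under a seed, sigmoid
  activation, 100 hidden nodes by default, readout solved by
  minimum-norm least squares.  Deterministic given the seed.
* **RF**: scikit-learn random forest, 500 trees, mtry = p/3.
* **XGB-style gradient boosting**: scikit-learn gradient tree
  boosting, depth 6, learning rate 0.1, 200 rounds.

The two-step route fits one regressor per parameter (correlations among
alpha, beta, G are not modelled) and clips predictions to the
calibration ranges before they reach the crop model.

The direct route regresses DTH on 200 daily mean temperatures from the
sowing day, the photoperiod at day offsets 0/100/200 (three
representative days — the full photoperiod curve is a smooth function
of latitude and date and would be collinear), and the marker dummies.

## Cross-validation and leakage policy

* fivefold: random partition of observations stratified by genotype, so
  every genotype keeps training rows (the interpolation scenario).
  The bare crop model re-estimates each genotype's parameters from the
  training rows of each fold — test rows never inform the parameters.
* leave-one-genotype-out (LOGO): parameters of training genotypes are
  their own-row estimates (removing the test genotype does not change
  them); the bridge is refit per fold without the test genotype.
* leave-one-genotype-and-location-out (LOGLO): training excludes all
  rows of the test genotype and of the test location; parameters of
  training genotypes are re-estimated without the test location's rows
  (cached per left-out location).

The bare crop model is only evaluated under fivefold (it needs the
target genotype's own data); integrated methods under LOGO/LOGLO;
direct ML under all three.  Censored integrated predictions are
excluded from the metrics with a logged count.  Metrics: RMSE, Pearson
correlation (undefined and reported missing under zero variance), and
mean absolute difference.

## F2 simulation

Both parents must be fully inbred (codes 0/2), so the F1 is trivially
phased.  Gametes are simulated per chromosome: a fair coin chooses the
starting haplotype and adjacent markers at map distance d cM switch
haplotype with the Haldane fraction `r = (1 - e^(-2d/100))/2` (no
crossover interference; the mapping function is not dictated by the
problem, Haldane is the standard interference-free choice).  An F2
individual is the sum of two independent gametes.  Predicted and
observed populations are compared at the 10/50/90th percentiles across
populations; quantiles use linear interpolation between order
statistics (numpy default, type 7), computed on each sample as-is
(96-plant observed populations vs 1,000 simulated progeny are not
resampled to equal n).

## Synthetic data: what it emulates and what it does not

The generator emulates a Japanese multi-location rice trial: sites with
latitudes uniform on [31, 43] N; per site-year, daily mean temperature
is an annual sinusoid (mean 27 - 0.3 lat degC, i.e. ~14-18 degC;
amplitude 10-14 degC growing with latitude; peak near day of year 210)
plus AR(1) noise (rho = 0.7, marginal sd 1.5 degC); photoperiods are
CBM day lengths.  Sowing alternates between mid-April (day 105) and
early June (day 155) across years within a site so that post-sowing
windows include both long and short days — without long-day exposure
beta is unidentifiable and its posterior simply widens to the prior.

The genetic architecture is additive on the parameters: 14 biallelic
markers on 5 chromosomes (5-20 cM spacing), inbred codes 0/2 so any
pair of lines can seed an F2 cross.  Five large-effect markers act on
beta (|effect| 0.4-1.5 per allele dose, random sign) and on G (up to
+-4 days per dose); all markers carry small alpha effects (+-0.1).
Intercepts (alpha 1.0, beta 3.0, G 55 d) centre the panel on observed
Japanese cultivar ranges, and the default 100-genotype panel spans
photoperiod-insensitive (beta <= 1) to sensitive (beta >= 6) types.
Observations are the exact crop-model simulation plus rounded N(0, 1)
day noise (heading is scored as a date, so sub-day precision is
impossible), floored at 1; censored cases are dropped and counted.

What a green end-to-end test does **not** establish: the synthetic
world is generated by the same DVR model that the crop-model route
fits, so there is no model misspecification; weather is a smooth
latitude-indexed sinusoid, so a left-out location is partially
interpolable from the remaining ones, which makes the extrapolation
penalty for direct machine learning milder than with real weather; and
the additive genetic architecture has no dominance or epistasis.
Method orderings are also scale-dependent: direct machine learning
approaches the 1-day noise floor only with a large training panel
(hundreds to thousands of rows), while the crop-model route's fivefold
accuracy depends mainly on the environments available per genotype, so
on small panels the correctly specified crop model can beat a
data-starved regressor even where the opposite holds at full scale.
Conclusions about real-data performance require real data.

## Known limitations

* Maturation (DVS = 2) is not simulated; the model stops at heading.
* Transplanting shock, CO2 and stress effects, and sub-daily
  temperature interpolation are out of scope.
* Heterozygous parents cannot be crossed (no phasing).
* The G prior is deliberately tight (sd 2 days); with few environments
  per genotype, posterior means of G shrink noticeably toward 35 days.
  This is a property of the stated prior, not a sampler defect.
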