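# Methods

`memtrain` re-implements, as a reusable and tested pipeline, the
longitudinal analysis of a two-age-group crossover memory-training
intervention: young adults (twenties) and older adults (seventies)
alternate 10-week periods of mnemonic training (Method of Loci) and
rest in an ABAB or BABA order, with cognitive testing and MRI at every
period boundary and a follow-up roughly three years later. Because the
original raw data are available only on request, the package pairs every
analysis with a synthetic-cohort generator that realizes the same models
as data-generating processes, so each estimator can be validated by
parameter recovery.

## The retention model

The criterion outcome is free written recall of a 100-noun list
(0–100 words); the transfer outcome is cued recall of 36 word pairs
(0–36). For participant *i* in age group *g* with sex *s*, the expected
score at a visit is

    E[y] = mu + alpha_older·1(g = older) + gamma_sex·1(s = M)
         + (x1·beta1_g + x2·beta2_g) · exp(−lambda_g · Δt)
         + rho_retest · retest
         + delta_g · (age_at_visit − mean_age_g)

where `x1`/`x2` indicate exactly one / exactly two completed training
periods, `Δt` is years since the end of the last completed training,
and `retest` flags any prior exposure to the test. Because
`exp(−lambda·Δt) = 1` at `Δt = 0`, `beta1_g` and `beta2_g` are the
*immediate* effects of the first and second training period, and
`lambda_g ≥ 0` (1/years) governs how fast the gain fades. The age
covariate is centered on the group mean age recomputed from the data at
hand. A participant random intercept (SD `sigma_b`) plus i.i.d. residual
(SD `sigma_e`) give a compound-symmetry within-person covariance
`sigma_b²·J + sigma_e²·I`.

**Estimation.** The marginal Gaussian likelihood is evaluated per
subject in closed form (Sherman–Morrison; no matrix factorizations) and
maximized by ML. The residual variance is concentrated out analytically:
the optimizer works over the 12 mean parameters plus the log variance
*ratio* `sigma_b²/sigma_e²`, with `sigma_e²` restored in closed form.
This profiling removes the ill-conditioning of a raw two-variance search
and handles the zero-noise limit cleanly. `lambda` is optimized on the
log scale; three starting decay rates (0.5, 0.1, 2.0 per year) guard
against the flat-likelihood pathology of exponential decay when effects
are small. The analytic gradient is supplied to L-BFGS-B; convergence is
declared at a relative log-likelihood tolerance of 1e-8 (max 500
iterations), and the fit is deterministic given data and settings.
Standard errors come from the observed information (numerical Hessian of
the full 14-parameter likelihood), mapped to the natural scale by the
delta method; intervals are Wald 95% intervals. Profile or bootstrap
intervals for `lambda` near zero would be more faithful; the Wald choice
matches the symmetric intervals the analysis reports, and the boundary
case is flagged by the estimate itself collapsing toward zero.

Inclusion rule: participants with at least two non-missing outcome
visits who completed at least one training period. Missing outcomes are
dropped row-wise (likelihood marginalization), never imputed. The
transfer analysis first keeps only rows that carry a criterion score,
then drops participants with fewer than two word-pair scores, counting
the exclusions.

## Retention curve, bootstrap band, prevail time

The long-term effect is summarized by `beta1_g · exp(−lambda_g · Δt)`
on 201 equally spaced points of `Δt ∈ [0, 5]` years. Uncertainty comes
from a nonparametric **case bootstrap coupled with an individual
residual bootstrap**: each replicate (i) resamples participants with
replacement, keeping full visit histories; (ii) rebuilds each sampled
participant's outcomes as fitted fixed-effect means plus a resampled
participant-level random-intercept prediction plus independently
resampled observation residuals; (iii) refits the full model
(warm-started at the original optimum; every parameter, including
`lambda`, is re-estimated); and (iv) evaluates the curve on the grid.
Bands are pointwise 2.5/97.5 percentile intervals.

Two numerical choices matter for calibration. First, empirical BLUPs and
conditional residuals are shrunken, so the centered resampling pools are
**reflated** to the estimated `sigma_b`/`sigma_e` before resampling;
without this the rebuilt outcomes are under-dispersed and the band is
systematically narrow. Second, tail quantiles use the quantile-unbiased
(`normal_unbiased`) estimator, since at a few hundred replicates the
default linear interpolation places the 2.5/97.5 endpoints slightly
inside the tails. Replicates that fail to refit are dropped and counted
(a warning fires above 10%). B defaults to 1000 for tests and 10,000 for
full runs.

The **prevail time** is operationalized as the largest grid `Δt` whose
lower band bound exceeds zero — an interpretation, since the original
phrasing does not state the decision rule. A band positive over the
whole grid returns the grid maximum flagged `censored`.

## Hippocampal volume models

Volumes are the left+right hemisphere sum in mm³, modelled unstandardized.
*Short term*: intervention-phase visits only; fixed effects are training
status (`baseline` reference, `post_train` = scanned immediately after a
training period, `post_rest` = one rest period later) interacting with
age group, age group, a per-group time slope, centered ICV, and sex;
random intercept and time slope per participant; REML. *Long term*:
trainers' pre-first-training visits and their follow-up, plus passive
controls' two visits, with a time × age-group × trained three-way
interaction (all lower-order terms), ICV, sex, and random
intercept+slope. The trained-vs-control difference is reported at each
group's mean follow-up interval, in two readings: the slope-difference ×
horizon product, and the level difference at follow-up (which adds any
baseline offset); the generator's truth corresponds to the first.
ICV enters as the per-visit value when recorded, else the participant
mean — ICV is anatomically stable and the per-visit variation in real
tables is segmentation noise.

Fitting is delegated to statsmodels `MixedLM`. Gradient-based optimizers
stall on these designs (many subjects contribute only 1–3 visits, so the
random-slope likelihood is nearly flat); Powell is used first, with
L-BFGS as fallback, which converged in every replicate of the recovery
studies. The package's own `lmm_marginal_loglik` implements the marginal
ML/REML likelihood directly and is cross-checked in the tests against a
dense multivariate-normal construction and against statsmodels' reported
likelihood at its optimum.

## Change–change correlations

Per participant, an ordinary least-squares line of each outcome against
time since baseline is fitted (follow-up visit excluded to isolate the
training period; minimum two points; no weighting), and Pearson
correlations between per-individual slopes (or intercepts, for "overall
level") are computed over pairwise-complete participants, with Fisher-z
95% intervals. Zero-variance slope sets are flagged rather than
propagated as NaN arithmetic.

## The synthetic cohort generator

`paper_defaults()` encodes the published study conditions: arm sizes
ABAB 34/46 (young/older), BABA 19/42, active-control-then-train (CBA)
4/12, passive controls 47/36; 0.21-year periods with 0.01-year visit
jitter (the realized, not idealized, interval); follow-up intervals
N(2.90, 0.80) / N(2.97, 0.61) years for trainers and N(3.80, 0.51) /
N(2.33, 0.47) for passive controls; baseline ages N(26.3, 3.1) and
N(73.3, 3.1); 59% female; ICV ~N(1.56e6, 1.5e5) mm³, constant within
participant. Monotone MCAR dropout at 5% per visit from the third visit
on (an optional frailty term can induce ability-correlated attrition,
off by default because the original models do not adjust for it).
Scores are integer-rounded and clamped to their ranges; a warning is
logged if clamping touches more than 1% of scores.

Generative fixed effects equal the published point estimates
(beta1 17.6/7.23 words, beta2 20.6/8.11, retest 2.80, age slopes
−0.08/−0.54 words/year; transfer effects 1.89/0.37 and 3.94/2.36 pairs;
hippocampal status effects 10.3/22.4 and 28.5/26.9 mm³; long-term
trained-vs-control differences −77/+136 mm³ at the mean follow-up
horizon, realized as trainer slope offsets). Decay rates and variance
components are not published and are **calibrated**: lambda 0.40/0.10
per year reproduces the follow-up score gains and the statement that
effects prevail for years (slower decay in the older group);
sigma_b = sigma_e = 3.0 words keeps the older baseline (~9 words) far
enough from zero that clamping is rare while matching the order of the
published SDs; word-pair SDs 2.0/2.0; hippocampal random intercept 600,
random slope 15 mm³/year, residual 40 mm³ (≈0.5% of volume, a plausible
longitudinal segmentation error).

For the change–change analyses the generator switches to a coupling
mode: per-participant latent (slope, level) pairs for the two outcomes,
slopes bivariate normal with target correlation rho (default 0.42, the
published young-group value), trajectories linear over the intervention
year and flat afterwards. The measurement residuals in this mode (0.75
words, 0.4 pairs) are deliberately small so that OLS slope-estimation
noise attenuates the latent correlation by under ~2% *including*
dropout-shortened series; the mode measures the correlation machinery,
not residual realism.

**What passing recovery tests do and do not show.** The generator
realizes exactly the likelihoods the estimators assume (up to rounding,
clamping, and MCAR dropout), so recovery demonstrates the correctness
and calibration of the estimation code under the study's design — not
robustness to the misspecifications real data carry (non-Gaussian
scores, outcome-dependent attrition, segmentation artifacts, practice
heterogeneity).

## Problem sizes and reproducibility

Recovery studies use 100 replicates of the full 240-participant design;
bootstrap calibration uses 20 outer replicates at B = 200; these sizes
make each criterion a minutes-scale computation. All randomness flows
from a single root seed through named `numpy.random.SeedSequence`
substreams, so cohorts, bootstrap draws, and whole pipeline runs are
bit-reproducible; identical config + seed yields byte-identical CSV
output.

## Known limitations

- Wald intervals for `lambda` and the variance components are poor near
  the `lambda = 0` boundary (the log-scale SE diverges); the bootstrap
  band is the better uncertainty summary for the decay curve.
- The compound-symmetry assumption of the retention model ignores any
  within-person autocorrelation beyond the random intercept.
- Percentile bands at B in the low hundreds carry visible quantile
  noise; B = 10,000 (the full-run default) is recommended for reported
  intervals.
- The sex and age-group codings (F=0/M=1, young=0/older=1) and the
  exact covariate set follow the quoted model description; further
  covariates of the original analysis scripts are not reconstructed,
  but extra terms can be passed through the LMM specs.
- The generator's dropout is independent of outcomes by default,
  whereas the original cohort documents ability-related attrition.
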