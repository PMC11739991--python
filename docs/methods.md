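# Methods

## Model

Each patient carries a six-dimensional random-effects vector
b = (b₀…b₅) ~ N(0, Σ) with unstructured covariance, shared across four
longitudinal submodels:

| channel      | response                          | link / error                | random effects |
|--------------|-----------------------------------|-----------------------------|----------------|
| `psa`        | log₂ serum PSA (ng/mL)            | identity, Gaussian σ_psa    | intercept b₀, slope b₁ (per year) |
| `volume`     | log₂ prostate volume (mL)         | identity, Gaussian σ_vol    | intercept b₂, slope b₃ |
| `mri_lesion` | suspicious lesion on MRI (0/1)    | logit, Bernoulli            | intercept b₄ |
| `benign`     | biopsy without cancer (0/1)       | logit, Bernoulli            | intercept b₅ |

Fixed effects are linear in time by default (an optional natural cubic
spline basis with two interior knots is available for the fixed trend;
the random effects stay intercept+slope, which keeps the instantaneous
velocity well defined). The benign channel describes the benign-vs-GG1
outcome of *non-reclassifying* surveillance biopsies; biopsy grades are
coded 0 = no cancer found, 1 = GG1 present, ≥ 2 = reclassification, and
the reclassifying biopsy itself belongs to the survival model, not the
benign submodel. Treating "benign" as merely "non-reclassifying" would
make that channel the deterministic complement of the event indicator,
which degenerates the joint posterior (the random intercept becomes a
free frailty perfectly separating events).

The hazard of detected reclassification is
h(t) = h₀(t)·exp(lp(t)) with

lp(t) = γ·(age − c₀) + α₁(m_psa(t) − c₁) + α₂(m′_psa(t) − c₂)
      + α₃(m_vol(t) − c₃) + α₄(m_les(t) − c₄) + α₅(m_ben(t) − c₅),

where the m are the patient-specific linear predictors (log₂ scale for
PSA/volume, logit scale for the binary channels), m′_psa is the analytic
derivative of the fitted log₂-PSA profile, and the c are centring
constants (cohort means in a fit, so hazard ratios are unchanged but the
association coefficients decouple from the baseline-hazard scale). The
binary channels enter on the linear-predictor (logit) scale; a
configurable alternative (`benign_covariate_mode="count"`) replaces the
fitted benign value by the raw count of previous negative biopsies,
matching the usual reporting convention. h₀ is piecewise constant on
five intervals with knots at event-time quantiles; under linear bases
every interval integral of the cumulative hazard is closed-form, which
the sampler, the simulator and dynamic prediction all exploit. A
B-spline log-hazard family is not implemented.

Outcome definition is GG ≥ 2 by default; GG ≥ 3 is a configuration flag
(a detected GG2 then censors the patient at that biopsy, since detection
ends surveillance follow-up).

### Detection likelihood

Reclassification is only observable at biopsies. Two event-time
conventions are implemented:

- `exact` (default): the detecting biopsy's date is the event time —
  the standard joint-model convention and the one the package's
  `joint_log_likelihood` contract states.
- `interval`: the event occurred in (previous biopsy, detecting biopsy].
  Implemented in the sampler by latent event-time augmentation: exact
  event times are drawn each sweep from the truncated piecewise-
  exponential density (closed-form inverse CDF), which preserves the
  conjugate baseline-hazard update. This removes the detection-delay
  attenuation of hazard coefficients — profiling the likelihood at the
  true random effects shows the exact-time convention biases a strong
  velocity coefficient downward by a third even with quarterly biopsies
  — and is what the parameter-recovery experiments use.

## Estimation

Full Bayes with the random effects as latent parameters, sampled by an
adaptive Metropolis-within-Gibbs scheme (written for this package; no
probabilistic-programming backend is used):

- per-patient random effects: vectorised random-walk Metropolis with a
  per-patient adaptive scalar step and proposal covariance Σ with a
  floored diagonal (the floor prevents the classic funnel trap where a
  collapsing variance component freezes its own proposals);
- fixed effects per channel and the six association coefficients:
  adaptive Gaussian block Metropolis (Haario-style empirical covariance
  learned during warmup);
- residual variances: conjugate inverse-gamma; random-effects
  covariance: conjugate inverse-Wishart; baseline-hazard heights:
  conjugate gamma (the piecewise-exponential likelihood is Poisson-form
  in h₀);
- two families of ancillary moves that traverse the posterior's ridges:
  translation moves exchanging mass between a fixed effect and the mean
  of its random-effect column, and frailty-loading scale moves
  (α→fα, b→b/f, matching Σ row/column → /f) whose acceptance depends
  only on the channel likelihood and priors since the survival term and
  the random-effects prior are invariant.

Priors: N(0, 10²) on submodel intercepts (an N(0, 2²) prior would bias
intercepts like log₂ volume ≈ 5.5), N(0, 2²) on time slopes and
association coefficients, inverse-gamma(0.01, 0.01) on residual
variances, gamma(0.01, 0.01) on baseline-hazard heights, and
inverse-Wishart(df = 8, scale = diag(0.5, 0.1, 0.5, 0.05, 1.5, 1.0)²)
on Σ — conjugacy is the reason for inverse-Wishart rather than an
LKJ-type factorisation. Initialisation is a two-stage warm start from
pooled per-channel fits. Convergence is summarised by split-R̂ and bulk
ESS for every scalar parameter (via `arviz`); any R̂ > 1.05 flags the
fit `converged=False` with a prominent warning. At desk scale (n = 300,
2 chains × 1500 draws after 3000 warmup, ~30 s) the weakly identified
loading/covariance parameters typically settle around R̂ 1.3–1.6; the
returned intervals are nevertheless well calibrated in the recovery
experiments below.

## Dynamic prediction

`posterior_profile` conditions the random effects on all observations up
to the landmark *and* on event-free survival to the landmark (a fast
path without survival conditioning exists and is what the closed-form
BLUP oracle tests exercise; with a single Gaussian channel and fixed
parameters the Laplace computation is exact GLS). The default sampling
mode refines a Laplace approximation with a short per-patient Metropolis
chain vectorised across posterior draws. `dynamic_risk` then evaluates
1 − S(t+h)/S(t) in closed form per draw (≥ 500 draws by default), so the
risk is exactly 0 at h = 0 and exactly monotone in h per draw; the
credible interval is the 2.5/97.5 percentile of the per-draw conditional
risks. Under the count covariate mode the negative-biopsy count is
frozen at its landmark value, because future biopsy outcomes are
undefined under the very deferral decision being considered. The
decision rule is biopsy iff risk ≥ threshold (boundary inclusive), with
7.5% and 15% the conventional thresholds and 1.5 y the default horizon.

## Evaluation

- **Time-dependent AUC**: among patients at risk at the landmark, cases
  are events detected within (t, t+w], controls are known event-free at
  t+w; ties count ½. Patients censored inside the window are excluded
  by default (outcomes are biopsy-adjudicated); an IPCW variant retains
  them. The default window is 2.5 y, spanning from one protocol biopsy
  to past the next.
- **Accuracy tables**: confusion counts normalised per 1000 biopsy
  decisions with fractional cells; Wilson 95% CIs; printed-table
  rounding is nearest integer, half away from zero.
  `reconstruct_confusion_from_deferral` inverts published columns
  (sensitivity, biopsies deferred, reclassifications delayed per 1000)
  back to the full table via prevalence = fn/(1 − sens).
- **Net benefit**: nb_model = tp/1000 − fp/1000·pt/(1−pt) against
  biopsy-for-all, reported as net biopsies avoided per 100 patients,
  100·(nb_model − nb_all)·(1−pt)/pt.
- **Calibration**: quantile bins of predicted risk vs Kaplan–Meier
  observed incidence at the horizon, plus the overall
  mean-predicted-vs-observed pair (calibration-in-the-large).
- **Recalibration**: with association coefficients fixed, the
  proportional baseline-hazard scale has the closed-form MLE
  e^δ = D / Σᵢ Hᵢ, with Hᵢ each patient's expected cumulative hazard
  under the current fit (random effects at their Laplace modes given the
  longitudinal history). On a dense-biopsy cohort with doubled hazard
  this recovers δ ≈ ln 2 and brings calibration-in-the-large to ~0.

## Synthetic data: what it emulates and what it does not

The generator reproduces the statistical structure the analysis
assumes: entry criteria (measured baseline PSA ≤ 10 ng/mL, PSA density
≤ 0.2 ng/mL/cm³; violators are redrawn, so the random-effects
distribution is truncated at entry), a fixed protocol (PSA quarterly
for two years then semi-annually; MRI and biopsies at years 1, 4, 7,
10), per-patient scatter of actual visit dates around the protocol grid
(SD ≈ one month — without it all detected event times sit on a handful
of grid atoms, a structure no continuous-time hazard can represent, and
the posterior exploits a degenerate manufactured-frailty mode),
correlated trajectories, lesion probabilities evolving per patient,
benign-vs-GG1 biopsy outcomes from the benign submodel, latent
reclassification times from the trajectory-driven hazard
(inverse-transform sampling on a 0.01-y grid), detection at the first
biopsy at or after the latent time, random dropout, and censoring at
the last biopsy. GG at detection is ≥ 3 with probability 0.27.

Key default parameters (units in years, ng/mL, mL):

- baseline locations match the development registry's summaries: log₂ 5.7
  PSA, log₂ 46 volume, 56% lesion prevalence at the average visit; 70%
  of non-reclassifying biopsies benign (an assumption);
- trajectory slopes 0.06 log₂/y (PSA) and 0.02 log₂/y (volume), residual
  SDs 0.16 and 0.12 log₂ (≈ 12% and 8% CV) — assumptions, as the
  registry's assay noise is not published;
- random-effect SDs (0.45, 0.08, 0.45, 0.025, 1.0, 0.7) with modest
  cross-channel correlations (e.g. +0.55 PSA–volume intercepts);
- `default_model_params()` carries deliberately strong associations
  (α = 0.04/y, 0.9, 6.0, −1.6, 1.0, −0.8; linear-predictor spread ≈ 1.4)
  so that shipped simulations exercise genuine discrimination
  (time-dependent AUC averaging ≈ 0.7–0.78 over the 1.5–5 y landmark
  grid at n = 500; individual landmarks fluctuate between ≈ 0.62 and
  0.85 with the modest per-window case counts) — these coefficients are
  larger than registry-estimated hazard ratios;
- `registry_model_params()` carries the registry-magnitude coefficients
  (age 1.47/10 y, PSA 1.42 per doubling, volume 0.56 per doubling,
  lesion ≈ 1.45, benign protective) and is the ground truth for
  parameter recovery, where realistic effect sizes are the relevant
  regime;
- baseline hazard heights are calibrated once so the detected five-year
  actuarial reclassification risk is ≈ 39% under the default protocol
  (0.037/y for the strong set; 0.10/y for the registry set's
  dense-biopsy recovery variant, giving ≈ 40% events over five years);
- dropout rate 0.22/y (default cohorts; median censored follow-up ≈ 1 y)
  or 0.05/y (recovery cohorts); per-visit nonadherence 10%, with the
  baseline visit and first biopsy always attended (mirroring the
  at-least-one-follow-up-biopsy inclusion rule).

What passing tests on this synthetic world do **not** show: real PSA
assay behaviour (no lab effects, no spikes from prostatitis), real MRI
reading variability (the lesion flag is a clean Bernoulli), protocol
deviations beyond independent nonadherence/dropout (no risk-triggered
early biopsies), non-linear trajectory shapes, or the case mix of any
actual registry. Real-data hazard ratios and AUCs are not reproduced
here — the published cohorts are not public — and the strong-association
defaults deliberately exceed them.

## Problem sizes and numerical choices

Test-suite and acceptance-script experiments run at desk scale, chosen
as the package's own defaults: recovery fits n = 300 with 2 × 1500
draws (five replicates, pooled 95%-credible-interval coverage of the six
associations ≥ 90%), discrimination at n = 500 with 200 prediction
draws, recalibration at n = 1000. Quadrature is 15-node Gauss–Legendre
per baseline-hazard panel; the piecewise-exponential `expdiff` and
moment helpers switch to series expansions below |c| < 1e-10; Laplace
optimisation is Newton with step halving on a concave objective;
random-effect draws in prediction use 60 Metropolis steps from the
Laplace mode. All randomness flows from explicit integer seeds;
identical seeds give byte-identical cohorts, fits and predictions.

## Known limitations

- The exact-time detection convention attenuates hazard coefficients
  when detection lags the latent event (use `interval` for simulation
  studies); conversely the interval convention is not available in the
  raw-count covariate mode.
- Split-R̂ on weakly identified loading/variance parameters stays above
  the 1.05 flag at n = 300; intervals remain usable (coverage-checked)
  but single-dataset point estimates of the binary-channel loadings are
  noisy.
- Fitting requires the linear time basis; the spline basis is available
  for profiles, velocity and hazard evaluation only.
- The simulator draws visit nonadherence independently per visit;
  informative (risk-related) nonadherence is out of scope.
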