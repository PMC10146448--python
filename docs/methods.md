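# Methods

`pavlearn` models a probabilistic serial-reversal Pavlovian learning
experiment: on each trial a subject sees one of two cues and predicts whether
it will be followed by an affective (appetitive or aversive) or a neutral
outcome. One cue carries the affective outcome with probability 0.75, the
other with 0.25; whenever the subject is correct on five consecutive trials
the cue–outcome mapping reverses, with the reversal applied one to three
trials later so its onset cannot be fully anticipated. The package simulates
this task, fits trial-wise learning models to the responses, propagates the
models' prediction errors (PEs) into fMRI-style parametric-modulation GLMs on
region-of-interest (ROI) time series, and carries the resulting effects
through group statistics, trait correlations and a three-node path analysis.
Everything runs on synthetic cohorts with known generating parameters, so
every stage is testable by parameter recovery.

## Task model

The schedule is generated per session from a single seeded random stream in
trial order (cue order, outcome draws, reversal delays, agent choice noise).
Design choices where the experimental description leaves room:

- **Outcome draws are per-trial Bernoulli(0.75)**, not an exact 75/25 ratio
  per block: reversal timing is random, so block lengths are unknowable in
  advance and only a probabilistic schedule is compatible with
  criterion-triggered reversals.
- **Cue balance is over cue identity** (20/20 in a 40-trial session). Exact
  balance over cue *roles* cannot be guaranteed because roles flip at
  unpredictable reversals; identity balance is the implementable reading.
- **The reversal criterion is edge-triggered**: correct runs that occur while
  a reversal is already pending do not schedule a second one, and the
  consecutive-correct counter resets when the criterion fires and again when
  the reversal is applied.
- **Pending reversals leave the old mapping in force** until applied; outcomes
  during the delay are drawn under the old contingency.
- **Missed responses** carry no correctness and neither advance nor reset the
  consecutive-correct counter; they are excluded from model likelihoods and
  value updates (no outcome is assumed to be experienced).

Trial onsets are synthesized on a realistic grid: reinforcement events of 3 s
start 4 s after trial onset, separated by inter-trial intervals drawn
uniformly from 5–7 s, which keeps a 40-trial session inside a 405-scan run at
TR = 1.5 s.

## Learning models

The core model is Rescorla–Wagner in a *concurrence* frame. The latent value
V is the expectation that the trial's outcome matches the outcome initially
linked with the presented cue; the match is coded R = 1, a violation R = 0.
Because the two cues' contingencies reverse jointly, a single V serves both
cues and a reversal manifests as a drop in V. Updates are the delta rule
δt = Rt − Vt, Vt+1 = Vt + α·δt, with V1 = 0.5 (maximal uncertainty). For
reporting and for the response model, values are re-expressed in the
*affective* frame — V′ is the anticipated probability of the non-neutral
outcome under the presented cue (V′ = V for initially affective-linked cues,
1 − V otherwise), with R′ = 1 on affective outcomes and δ′ = R′ − V′. The
two frames satisfy |δ′| = |δ| on every trial (with δ′ = ±δ by cue identity),
which is property-tested for all model families.

One V per session, not per cue: the R coding makes the two cues exactly
symmetric (their information content is identical), so a per-cue variant adds
parameters without adding signal; it is a documented alternative only.

Responses are Bernoulli with a unit-square-sigmoid read-out,
p(affective) = V′^ζ / (V′^ζ + (1 − V′)^ζ) = expit(ζ·logit V′), the standard
binary response model for this family; ζ ≥ 0 is the response precision
(ζ = 1 is probability matching, ζ → ∞ an argmax responder). The identity with
the logit form is used in code for overflow safety.

Two comparator families:

- **TD**: a two-time-step temporal-difference extension. Each trial is a
  two-state episode; the cue state bootstraps with discount γ on a learned
  post-outcome state value W (itself delta-rule updated from R), giving
  δt = Rt + γWt − Vt. At γ = 0 this reduces *exactly* to RW, which is tested
  to machine tolerance. γ > 0 can push V outside [0, 1]; the read-out clips
  to the unit interval.
- **HGF**: the standard three-level hierarchical Gaussian filter for binary
  inputs. Level 2 is a Gaussian belief on the outcome tendency (V is its
  sigmoid-transformed prediction), level 3 tracks log-volatility. The coupling
  κ is fixed at 1 and initial beliefs at (μ2, σ2, μ3, σ3) = (0, 1, 1, 1) —
  the usual identifiability constraints for binary data — leaving ω2, ω3 and
  ζ free. Non-positive posterior precisions or exploding volatility
  (log ν2 > 15) raise a divergence signal that the fitter treats as a
  rejected parameter point.

**Fitting** is bounded maximum likelihood on unconstrained scales (logit for
α and γ, log for ζ, raw clipped ω's), with 10 (default) seeded Nelder–Mead
restarts and tolerance 1e-6. Nelder–Mead was preferred to quasi-Newton
because the per-session likelihood is cheap and not smooth at the α edges.
ζ is fitted per session rather than shared across a valence's sessions: the
session is the natural fitting unit here, the parameter count per session is
unchanged (ζ is in every model's k), and per-session fits keep the AIC
granularity — per session, summed within subject per valence — intact.
Parameter counts for AIC (2k − 2 lnL): RW k = 2 (α, ζ), TD k = 3 (α, γ, ζ),
HGF k = 3 (ω2, ω3, ζ).

Model comparison: Friedman rank test over the subjects × models AIC table
(mid-ranks, tie-corrected, χ² reference with k − 1 df), then pairwise
Wilcoxon signed-rank tests of the reference model against each comparator,
Bonferroni-corrected for the number of pairs (2 here: RW–TD, RW–HGF). The
Wilcoxon uses the exact null distribution up to n = 25 untied pairs and the
continuity-corrected normal approximation beyond; both branches agree within
0.01 in p at the boundary on random data (tested).

## fMRI GLM

Designs follow the common first-level convention: 3-s reinforcement-event
boxcars per condition (events preceded by the currently
high-probability-affective cue vs the high-probability-neutral cue), convolved
with a canonical double-gamma HRF (response gamma shape 6, undershoot shape
16 at 1/6 amplitude, 32 s support, peak-normalised; peak ≈ 5 s). Each
modulated condition adds a parametric-modulator column whose boxcar heights
are the trial-wise δ′ values **mean-centred within condition and not serially
orthogonalised further** — centring makes the modulator orthogonal to the
constant and is a reproducible, documented convention, whereas full serial
orthogonalisation is a toolbox default we would be guessing at. Slow drifts
are removed by a discrete-cosine basis with periods ≥ 128 s plus a constant.
Designs are built at a microtime resolution of TR/16 and sampled at the first
microtime bin of each TR. Estimation is OLS (no prewhitening); an AR(1) noise
option exists for *simulation only*, to demonstrate the variance inflation a
prewhitening estimator would address. The split into negative/positive PE
maps arises naturally: HP-affective-cue trials carry predominantly negative
δ′ (omitted affective outcomes), HP-neutral-cue trials predominantly positive
δ′.

## Group statistics

Accuracy is the correct-response ratio over non-missed trials, pooled over a
subject's sessions of a condition, tested against chance 0.5 with a one-sample
t test. ROI betas get one-sample t tests against zero with Bonferroni
correction over the number of ROIs (4) within each condition — conditions are
not pooled into the family. The 2×2 repeated-measures ANOVA (PE type ×
learning type, both within-subject) is computed via within-subject contrasts:
with 1 numerator df each, every effect's F is exactly the squared paired t of
its contrast, which is verified against an independent textbook
sums-of-squares decomposition to 1e-8. Trait–activity relations are Pearson
correlations with two-sided t-based p (n − 2 df). All tests are two-sided;
directional claims ride on signs. A trend-reporting threshold of 0.1 is
exposed as a constant.

## Path analysis

The effective-connectivity model is a recursive chain over three observed
variables (CMA → posterior mOFC → lOFC) with five free parameters (two paths,
one exogenous, two residual variances) against six covariance moments, hence
df = 1. Fitting minimises the Wishart ML discrepancy
F = ln|Σ(θ)| + tr(SΣ⁻¹) − ln|S| − 3 by BFGS on (b1, b2, log-variances),
seeded by the closed-form regression solution; χ² = (N − 1)·F_min (the
classical multiplier; the source convention is not stated, so this is a
declared choice). Standard errors come from the numerical Hessian of
(N − 1)/2·F at the optimum; coefficient p values are Wald z, two-sided.
Variables are z-scored by default so coefficients are standardized — the
printed coefficients being of standardized magnitude — with raw-scale fitting
available via `standardize=False`. For the standardized chain, the ML path
estimates coincide with the simple regression slopes of z-scored variables,
which is used as a closed-form cross-check.

## Synthetic cohorts: what they state and what they do not

Defaults are the stated world of the emulated design: 37 subjects; 4 sessions
of 40 trials (2 per valence); RW agents with α ~ Beta(3, 7) (mean 0.3) and
ζ ~ log-normal(ln 5, 0.3) (median 5 — reliable but noisy responders);
neuroticism ~ N(20, 8) and extraversion ~ N(28, 6) truncated to the 0–48
instrument range; BMI ~ N(23.25, 3.13) (the reported sample moments); ROI
beta means of 0.8 (in units of the unit-variance beta noise, i.e. d = 0.8) in
the three CMA negative-PE cells where the emulated design shows effects; and
trait couplings −0.36 (neuroticism) and +0.48 (extraversion) on the left-CMA
negative-aversive-PE cell only. Couplings are injected as
beta = mean + Σ r·z(trait) + √(1 − Σr²)·ε with independent traits, so each r
is the population trait–beta correlation; configurations whose Σr² ≥ 1 are
rejected. These calibrations make the generator's world *resemble* the
reported effect pattern; a green test establishes that the pipeline recovers
what the generator put in — not that the original findings are reproduced.
The generator omits, deliberately: physiological/motion noise structure
beyond white/AR(1), between-session non-stationarity of α, missed responses
(agents always answer), and any real anatomy.

Seeding: a master seed spawns per-subject child streams
(`SeedSequence.spawn`), so any subject subset regenerates bit-exactly;
cohort-level draws (traits, betas) use a dedicated extra stream.

## Numerical choices and scale-downs

- Likelihood floors at 1e-12 before log; V′ clipped to [1e-12, 1 − 1e-12].
- Fit convergence: Nelder–Mead xatol = fatol = 1e-6; SEM BFGS gtol = 1e-10;
  SEM Hessian by central differences at step 1e-5.
- Degenerate inputs signal dedicated exceptions (constant Friedman rows,
  all-zero Wilcoxon differences, zero-variance t/correlation inputs,
  rank-deficient designs name the offending columns).
- Recovery suites are sized to run on one CPU within a CI budget: model
  recovery 20 subjects (observed RW win rate 0.90 against a 0.6 criterion),
  α recovery 25 subjects (observed bias ≈ 0.02 against 0.1), GLM unbiasedness
  200 simulated runs, test-calibration checks at 10⁴ null replicates.

## Known limitations

- The fitted ζ is mildly biased upward at 40-trial sessions (few trials near
  V′ = 0.5); α recovery is the validated quantity.
- The TD read-out clip means γ is weakly identified when α is large; TD
  serves as a comparator, not an inference target.
- The HGF here is the textbook 3-level binary filter; toolbox variants with
  free κ or informative priors will not match it numerically.
- OLS on AR(1) ROI noise gives valid point estimates but optimistic standard
  errors; group inference in this package always operates on per-subject
  summaries, where this does not propagate.
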