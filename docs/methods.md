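# Methods

## Task geometry and designs

A ball of diameter s(t) at eye distance d(t) subtends 2·arctan(s/2d).
Trials last T = 1 s with linear kinematics s(t) = s₀ + ṡt, axial depth
d₀ + ḋt, and a fronto-parallel sinusoidal oscillation (amplitude 5–15 mm,
frequency 0.35–0.5 Hz, drawn uniformly per trial) that adds to the
line-of-sight distance geometrically.  The oscillation exists to mimic the
rendering geometry of the task (it defeats local edge-motion cues); the
observer models deliberately ignore it, and on the zero-image-change line
its residual effect on the visual angle is below 0.02 deg for the task
geometry (checked numerically in the tests).

Zero image change is defined at trial endpoints under small-angle
projection, s(T)/d(T) = s₀/d₀, which yields the same straight locus
ṡ = k_img·ḋ (k_img = s₀/d₀) as an instantaneous linearization.  Because
arctan is monotone, the *sign* of the end-to-start image-angle change
equals the sign of ṡ − k_img·ḋ exactly, which is what the image-only
oracle uses.

**Experiment 1** crosses 3 pedestal distance rates {−71.5, 0, +71.5} mm/s
with 11 satellite offsets {−32.5 … +32.5} mm/s; each satellite is paired
one-to-one with a size rate from {−11 … +11} mm/s, giving 33 unique
(ḋ, ṡ) pairs, replicated 10 times per cue condition (H±/B±) in the
default configuration.  The printed design does not state the
satellite↔size-rate pairing order; the default is monotone
(−32.5 ↔ −11 … +32.5 ↔ +11) and `pairing="antimonotone"` is available.
All downstream statistics are pairing-invariant because the analysis
estimates the pairing slope from the records themselves (below).  Initial
distance is uniform on [443, 455] mm (the stated range; the distribution
is a package choice).

**Experiment 2** is 2IFC speed discrimination: standards ±55 mm/s,
comparison offsets {−54 … +54} mm/s in 18 mm/s steps, 14 repeats per cell
per single-cue condition, interval order balanced within cells.  Size
rate is 0 throughout.

## Observer model

State x = (ṡ, ḋ) with zero-mean Gaussian priors; σ_prior(ḋ) = 30 mm/s
(slow-motion prior) and σ_prior(ṡ) = 1000 mm/s (deliberately weak — only
the distance prior is theoretically motivated, so the size prior is close
to flat).  Cues: m_I = ṡ − k_img·ḋ + ε_I with σ_I = 2 mm/s (the image cue
is expressed in mm/s-equivalent units so σ_I is commensurate with the
stimulus grid and all geometry stays in the design module);
m_B = ḋ + ε_B, m_H = ḋ + ε_H with default σ_B = σ_H = 13 mm/s, chosen so
the simulated 2IFC JND (≈ 18.4 mm/s) sits plausibly inside the ±54 mm/s
comparison range, and equal across cues so that any binocular/haptic
asymmetry must come from trust, which is the phenomenon of interest.
Trust w ∈ [0, 1] inflates an auxiliary cue's effective variance to σ²/w
(defaults w_B = 1, w_H = 0.3).  A causal-mixture account of trust would
be a natural extension; variance inflation is used because it keeps the
model closed-form and already reproduces the binocular>haptic asymmetry.
Lapse rate 0.02.

The posterior is exact 2×2 Gaussian conditioning.  Decisions are the sign
of the posterior mean of ṡ (MAP for Gaussians; no criterion bias — biases
would surface as PSE shifts downstream and are representable there).
Setting the expected posterior mean to zero at noiseless cues gives the
closed-form predicted confusion

    confusion = p_d / (p_d + w_B·1{B+}/σ_B² + w_H·1{H+}/σ_H²),

with p_d the prior precision of ḋ — notably independent of σ_I and of the
ṡ prior.  The implementation evaluates the posterior kernel; the scalar
formula above is re-derived independently in the test suite as an oracle.

In Experiment 2 the simulated percept of each interval is |ḋ| plus
Gaussian noise with the cue's *raw* σ (no trust inflation): the task is a
direct speed judgment of the cue itself, with no explaining-away step, so
it measures reliability in isolation — exactly why the design pairs the
two experiments.

Oracle observers (image-only, veridical) answer by the sign of the
linearized image change or of ṡ, plus a small Gaussian decision noise
(default 1.0 mm/s, roughly half the 2.2 mm/s size-rate step) so their
psychometric functions have finite slope and the MLE is well-posed.

## Psychometric fitting

ψ(x) = λ + (1−2λ)Φ((x−μ)/σ), binomial ML.  The single symmetric lapse is
bounded at λ_max = 0.06 (robust-fitting convention; the source analyses
cite that approach without printing bounds).  PSE ≡ μ: with symmetric
lapse the midpoint of the compressed range coincides with the 50% point,
and μ remains stable when λ > 0.  JND ≡ σ.

Optimization: L-BFGS-B on (μ, log σ, λ) with analytic gradients,
multi-start (closed-form probit-regression start plus grid-initialized μ
quantiles), likelihood tolerance 1e-10; flat likelihoods near degenerate
data are why multi-start is mandatory.  Bounds: μ within the level range
±2 spans, σ ∈ [10⁻³, 50] spans.  Convergence is reported honestly: fewer
than 3 distinct levels, all-identical responses, or σ at its upper bound
(flat data) are flagged non-converged, and PSE/JND accessors refuse such
fits.  Perfect step data converge with σ at the lower bound; in the 2IFC
path this is additionally flagged as ceiling performance because the JND
is then design-limited.  If no start terminates cleanly, the fit is
retried from the default start set and finally polished gradient-free
(Nelder–Mead) — selection prefers a cleanly converged optimum within 1e-6
of the best likelihood over an abnormal line-search termination.
Asymptotic PSE standard errors come from a finite-difference Hessian of
the negative log-likelihood.

Bootstrap: the design is fixed and responses are the random element, so
resampling is binomial within level (k* ~ Bin(n, k̂/n)), refit warm-started
from the point estimate.  Percentile CIs; error bars are MADC of the
resample distribution, 1.4826·b_n·median|x − median x|, with the standard
finite-sample factors (b₂ = 1.196 … b₉ = 1.107, n/(n−0.8) beyond).

## Boundary fit and confusion ratio

The satellite design co-varies ḋ with ṡ along each direction group
(slope r = dḋ/dṡ = 32.5/11 for the monotone pairing, estimated from the
records by within-group regression so any pairing works).  A group's PSE
therefore corresponds to the 2-D point (pedestal + r·PSE, PSE) on its
group line; fitting the boundary through those points recovers the
observer's decision-boundary slope exactly in expectation.  (Regressing
PSE on the raw pedestal instead would inflate the slope by 1/(1 − m·r) —
about 30% at m = k_img — and the image-only endpoint would no longer
equal 1.)  The ML line fit uses Gaussian PSE errors, i.e. weighted least
squares with weights 1/SE², via statsmodels.  Confusion = slope/k_img,
reported unclamped since sampling noise can overshoot [0, 1];
normalization uses k_img = 35/449 (mid initial distance) by default,
configurable.  Bootstrap for the confusion CI resamples responses within
(group × level) cells and re-runs the entire chain.

Experiment 2: per-standard JNDs are averaged before the σ = JND/√2
conversion (the pooling is not stated in the source analysis; averaging
is symmetric and variance-reducing).  The √2 is fixed by standard 2IFC
signal-detection theory and surfaced as `IFC_FACTOR`.  The bootstrap
reliability test compares the two independent resample sets by exhaustive
cross-pairing (deterministic, lower-variance than random pairing of the
same estimand) with add-one smoothing so p > 0.

## What the synthetic data does and does not emulate

The generator reproduces the stimulus sets, trial counts, randomized
geometry and cue structure of the two designs, and response statistics of
a stationary linear-Gaussian observer.  It does not emulate: sequential
effects or learning, criterion drift, non-Gaussian or signal-dependent
sensory noise, binocular rendering artifacts, motor/timing errors, or
between-participant heterogeneity (a "participant" is one parameter set).
Passing tests therefore validate the *analysis chain* and the normative
model's internal consistency — not claims about human data, which the
package cannot re-measure.

## Problem sizes and checks

The end-to-end checks run at sizes chosen to make Monte-Carlo error small
relative to the tolerances while staying desk-scale: oracle endpoints and
model-vs-pipeline agreement at 200 repeats per grid point (6,600 trials
per condition; pipeline-vs-closed-form agreement within 0.03), σ recovery
at 100 repeats per level (50 replications per σ ∈ {6, 13, 26} mm/s,
median relative error < 10%), and the reliability test's size at the
design's own 196-trial sessions (200 replications, rejection rate ≤ ~7%
at nominal 5%).  `scripts/acceptance.py` re-runs the oracle endpoint
pipeline from scratch and writes the recovered confusions as JSON.

## Known limitations

* Trust-as-variance-inflation cannot express full causal inference
  (e.g. cue vetoing at large conflicts).
* σ recovery for small σ (6 mm/s) is limited by the 18 mm/s comparison
  spacing: only the inner levels are informative and the lapse/slope
  trade-off adds bias at single-session sizes.
* The boundary fit assumes PSE errors dominate (errors-in-x from the
  r·PSE term are ignored in the weights; the bootstrap, which re-runs
  everything, absorbs this in the reported uncertainty).
* The repeated-measures ANOVA reported for participant-level summaries in
  human studies is out of scope; `paired_sign_test` plus standard
  statsmodels/pingouin calls on the tidy tables cover that use.
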