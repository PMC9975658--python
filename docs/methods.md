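# Methods

This note documents the models implemented by `speechsync`, the defaults
chosen where the underlying analysis conventions leave room, and what the
synthetic generators do and do not emulate.

## Envelopes and phase

The stimulus ("cochlear") envelope is a gammatone filterbank: 30 channels
with centre frequencies equally spaced on the ERB-number scale over
180–7246 Hz, per-channel Hilbert magnitude, averaged across channels.
Channel count and the across-channel mean are declared defaults — the
convention only fixes the band edges — and both are configurable. The
production envelope is the broadband Hilbert magnitude of the waveform.

Both envelopes are polyphase-downsampled to 100 Hz (anti-aliased;
upsampling is refused since the analysis only ever reduces rate), bandpass
filtered 3.5–5.5 Hz with a 4th-order Butterworth applied forward-backward
(zero phase, so the phase relation between the two envelopes is untouched),
and converted to instantaneous phase by the Hilbert transform. Each
`PhaseSeries` carries an `edge_trim_s` margin (default 1 s) marking
filter/Hilbert edge artifacts; windowed PLV can drop it. Stereo input is
averaged to mono with a warning.

## PLV and synchronizer classification

`PLV = (1/T)|Σ exp(i(θ1 − θ2))|` over equal-length phase series. Windowed
estimation uses 5 s windows advancing by 3 s (2 s overlap); a trailing
partial window is dropped so all windows carry equal weight. The trial PLV
is the arithmetic mean over windows, the participant PLV the mean over
trials; pooling all windows across runs instead is available but not the
default. For independent uniform phases the estimator concentrates at
`sqrt(pi/(4T))` (Rayleigh), which the tests verify by Monte Carlo.

Cohort classification is 1-D k-means with k = 2, 50 restarts and a fixed
seed; the higher-centre cluster is HIGH. Optimal 1-D 2-means is a threshold
split, so the tests compare against an exhaustive partition oracle.
Bimodality is assumed, not tested; the silhouette score is reported so a
degenerate cohort is visible. All-identical PLVs raise rather than
returning an arbitrary split.

## Synthetic phase coupling

Produced phase is modelled as `θ2(t) = θ1(t) + lag + ε(t)` with
`ε ~ von Mises(0, κ)`, giving the analytic expectation
`E[PLV] = I1(κ)/I0(κ)`. By default one independent noise draw is made per
sample, so the marginal of `ε` is exactly von Mises and the Bessel-ratio
identity holds sample-wise. Smoothing the noise (e.g. low-pass filtering)
would concentrate its marginal and bias the PLV above the Bessel ratio, so
it is deliberately not done; users who want slowly varying phases can set
`noise_update_hz`, which holds each draw for a fixed interval —
piecewise-constant noise keeps the marginal distribution intact at the cost
of fewer independent draws (the PLV estimator's small positive bias,
`E|mean| ≥ |E mean|`, grows as the count of independent draws per window
shrinks; at the defaults it is negligible).

Cohorts draw each participant's target PLV from a normal around the group
mean (defaults: HIGH 0.73, LOW 0.36, sd 0.09 — the empirically observed
regime for this task), invert the Bessel ratio for an individual κ, and add
a participant-specific lag. Group sizes default to 41/41 (n = 82).

## Syllable nuclei and articulation rate

The detector computes a frame-wise RMS intensity contour (25 ms frames,
10 ms hop, dB) and accepts local maxima at least `threshold_db` (2 dB)
above the median intensity with prominence at least `dip_db` (2 dB) —
the peak-dip logic of the widely used Praat nuclei scripts, with every
threshold exposed because the original script's values are conventions,
not standards. Pauses are silent runs (> 25 dB below the contour maximum)
of at least 0.3 s; the articulation rate is nuclei / (total − pause)
seconds. A `pause_margin_s` allowance (0.1 s) is trimmed from each
speech-adjacent pause edge: the contour falls silent roughly half an
inter-syllable gap after the last nucleus, so raw silent spans
systematically overshoot the perceptual pause. A voicing (periodicity)
check is off by default because whispered speech and the burst fixtures
are unvoiced. All-silent input returns zero nuclei and an undefined
(`None`) rate rather than zero.

The burst generator places 50 ms Hann-windowed tone bursts on a rate grid
inside declared voiced segments (unambiguous envelope peaks by design),
with optional jitter, over a Gaussian noise floor. It emulates the timing
and pause structure of spontaneous speech, not its spectrum, coarticulation
or amplitude variability — exact-count recovery on these fixtures
demonstrates the detector's peak/pause logic, not its robustness to real
conversational audio.

## Preferred auditory rate (2IFC)

The generator's latent preference is
`g(r) = exp(−(r − peak)² / 2σ²)`, `σ = FWHM / (2√(2 ln 2))`; on each trial
the item with the larger `g(r) + N(0, decision_noise)` wins, exact ties
(noise-free self-pairs) fall to a fair coin. Defaults: peak 5.57 syl/s,
FWHM 4.89 syl/s (the observed cohort means), decision noise 0.2, 20 trials
per pair over the 7-rate grid including self-pairs.

The analysis aggregates each non-catch trial's preferred item into per-rate
counts and fits `a·exp(−(r − μ)²/2σ²)` by bounded least squares,
initialised at the empirical mode; peak and FWHM are scale-invariant, so
fitting counts versus proportions is immaterial. Catch-trial exclusion
keeps participants at or above 75% accuracy (strictly below excluded).

A structural caveat, verified by a deterministic expected-count analysis:
the count profile of a pairwise tournament is a monotone transform of
`g`, not a density sample of it. The fitted peak localises the latent peak
well (expected bias < 0.07 syl/s at the defaults), but the count-scale
FWHM is bounded below by the rank-staircase profile of the grid (~3.7
syl/s for this 7-point grid) regardless of how narrow the latent tuning
is, and grows with decision noise. The FWHM should therefore be read as an
index of response specificity on the count scale, comparable across
participants measured with the same grid and task, not as an estimate of
the latent tuning width.

## Perplexity

`PP = exp(−(1/N) Σ ln p_i)`, computed in log space (no underflow at
N = 1000, p = 1e-6). The "inverse of the mean probability weighted by
sentence length" phrasing admits an arithmetic-mean reading
(`1 / mean(p_i)`), provided behind `mean="arithmetic"`; the geometric form
is the default because it is the standard intrinsic language-model metric.
The bundled provider is an add-k smoothed unigram/bigram model over a
closed vocabulary plus an out-of-vocabulary symbol (per-context
probabilities sum to one); bigrams condition the first token on a
start-of-sentence context and no end-of-sentence token is scored. Any
model that returns per-token conditional probabilities can be substituted.

## Scoring

Intelligibility is multiset (order-free) matching of case-folded,
punctuation-stripped tokens: matched = Σ min(count_ref, count_resp) per
type, as a percentage of reference length. Order-free matching with
min-counts is the declared rule for repeated words. Word-order judgements
are exact comparisons of the chosen versus true first target; the
word-order index is the per-item percentage of control participants
correct.

## Mixed-model inference

The binomial-logit GLMM has crossed random intercepts (participant, item)
and optionally one random slope block (syllabic rate by participant,
uncorrelated with the intercepts). For fixed variance parameters the joint
penalized log-likelihood is maximized over (β, u) by Newton iterations —
the random-effects design is sparse, the q×q system dense (q ≈ 400 at
study scale) — and the profiled Laplace objective
`ℓ(β̂,û) − ½û'D⁻¹û − ½log|D| − ½log|Z'WZ + D⁻¹|` is optimized over the
log-SDs by Nelder-Mead. This is the nAGQ = 1 approximation `glmer` uses,
and the test suite checks agreement with `lme4` on a shared fixture
(coefficients within 0.03, random-effect SDs within 0.02, logLik within
0.5). Fixed-effect covariance is the inverse Schur complement of the joint
Hessian at the mode; p-values are Wald z; AIC counts fixed effects plus
variance parameters. Without random effects the same machinery reduces to
ordinary logistic ML (matches `statsmodels` GLM to 1e-5). If the
random-slope model fails, the fit falls back to random intercepts only
with a warning — the conventional response to GLMM non-convergence.

Continuous predictors are z-scored over the analyzed trials (after
exclusions), so coefficients are log-odds per SD and `OR = exp(β)`;
z-scoring order relative to exclusions is configurable. VIFs are computed
from the inverse correlation matrix of the modeled predictors and checked
against a bound (default 10; perfect collinearity raises). FDR control is
Benjamini-Hochberg step-up (via statsmodels, oracle-checked in the tests).
Rate-binned accuracies with Wilson intervals summarize the rate effect in
place of a spline-smooth fit, which is out of scope.

Known limitation: with binary outcomes and moderate random effects the
Laplace fixed effects are slightly attenuated (~5% on the rate coefficient
in the 82 × 240 recovery simulations) and Wald CIs are correspondingly
mildly anti-conservative (pooled 95% CI coverage ≈ 93% over 100 simulated
cohorts, per-effect 89–97%). `glmer` at nAGQ = 1 shares this bias; adaptive
quadrature is not available for crossed random effects.

## Comprehension generator

Outcomes are Bernoulli draws from a logit-linear model applied to z-scored
covariates, so the generating coefficients live on the same per-SD scale
as the fitted ones. Default coefficients reproduce the reported effect
sizes for the word-order task (rate OR 0.65, motor rate 1.19, sync group
1.34, preferred rate 1.14, working memory 1.20, perplexity 0.84, intercept
1.75 ≈ 85% baseline accuracy); random-effect SDs default to 0.5
(participant), 0.3 (item) and 0.2 (rate slope) — values typical of
repeated-measures behavioural logits, chosen once since the study reports
none. Participant covariates are drawn in realistic raw units (motor rate
N(4.30, 0.45), preferred rate N(5.57, 0.86), digit span N(8.46, 2.12));
item rates cycle through the six word-order-task levels (5.00–15.00
syl/s); item perplexity is log-normal. Interactions are written `a:b` on
z-scored components.

## Problem sizes and determinism

Every generator is deterministic given its spec and seed; the pipeline
derives all stage seeds from one master seed, and repeated runs are
bit-identical. The test suite exercises the cohort stages at the study's
scale (82 participants, 240 items, ~19 700 trials; 100-cohort coverage
simulation) and the signal stages on 80 s trials at 100 Hz; the demo
pipeline and acceptance script use the same code at these scales, with the
burst-speech stage at 8 kHz and a few tens of seconds per participant,
which is ample for the timing-level questions the fixtures can answer.
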