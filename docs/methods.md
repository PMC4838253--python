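# Methods

`tempasym` re-implements, as a tested pipeline, the computational chain
linking the temporal asymmetry of ramped and damped sinusoids to perceived
pitch salience and to the N100m auditory evoked field: stimulus synthesis,
an auditory-periphery front end, two pitch models with stimulus-dependent
temporal integration, paired-comparison scaling, and evoked-field
quantification, together with a synthetic-data generator that stands in
for human MEG/psychophysics recordings.

## Stimuli

A damped sinusoid is a carrier `sin(2π f t)` (default f = 1 kHz)
multiplied by a periodic exponential envelope

    E(t) = (1 / T½) · exp(−t ln2 / T½),   t ∈ [0, C)

with half-life `T½ ∈ {0.5, 1, 4, 16, 32}` ms and cycle length C = 50 ms;
the ramped partner uses the within-cycle time reverse `E(C − t)`.  "log 2"
is read as the natural logarithm of 2 — the only reading under which the
envelope halves per half-life.  The cycle holds an integer number of
carrier periods, so the envelope discontinuity always falls on an
upward-going zero crossing and every cycle starts in the same phase.
Twenty cycles are concatenated (1 s, 48 kHz).  Levels are scaled by
`level_ref · √T½`, which equalises RMS across half-lives up to the small
truncation loss of the longest envelopes (< 10 %); the free constant
`level_ref` is fixed so the 4 ms condition has RMS 0.1 full scale
(absolute SPL is a playback property and out of scope).  Ramped/damped
partners share their long-term magnitude spectrum to within a few percent
(the residual comes from the one-sample offset of the discrete mirror).

## Auditory periphery

The shared front end of both models:

* **Filterbank** — 100 gammatone channels, characteristic frequencies
  ERB-rate-spaced over 100–10 000 Hz.  Each 4th-order gammatone is
  implemented as a cascade of four complex one-pole resonators with unit
  gain at CF; a single high-order IIR section is numerically unstable at
  low CF relative to 48 kHz, the cascade is stable at every CF.
* **Hair-cell stage** — per channel: half-wave rectification; power-law
  compression with exponent 0.6 above a low-level knee (0.03) and linear
  below it, so near-silent channels are not expanded; a saturating stage
  `p/(p + 0.3)` modelling the firing-rate ceiling (sharp onset peaks are
  clipped, gradual rises are not); a 2nd-order Butterworth low-pass at
  3 kHz (phase-locking limit); and weak divisive adaptation
  `p/(1 + 0.5·s)` with `s` a 30 ms running average of the channel's own
  output.  The result is the neural activity pattern (NAP) `p(t, k) ≥ 0`.
* **Decimation** — anti-aliased downsampling to 8 kHz (0.125 ms frames)
  before any lag analysis; this resolves the 1 ms carrier lag at
  desk-scale cost.

These defaults were calibrated so the NAP reproduces the qualitative
response pattern reported for this stimulus family in the auditory nerve
and its established models: tonotopy; carrier-lag coincidence that grows
with half-life within each envelope type; and a ramped > damped sustained
response, maximal at T½ = 4 ms.  The stage is a functional model — it is
not a transmission-line filterbank and not a full reservoir hair-cell
model — and this is the main fidelity caveat of the package: effects that
depend on cochlear two-tone suppression or on spike-train statistics are
outside what it can show.

## Hierarchical generative pitch model (GPM)

Stage 1 computes coincidences across cochlear delay lines,

    A₁(t, l) = Σₖ p(t, k) · p(t − l, k),

on a lag grid at NAP resolution spanning **0.5–40 ms**.  The lower edge
restricts the delay lines to the existence region of periodicity pitch
(≤ 2 kHz).  This matters beyond physiology: any smoothed non-negative
activity pattern carries a trivial correlation ridge at lags below its
own autocorrelation width (~0.4 ms here), and for click-like stimuli that
ridge would otherwise beat the carrier peak.  The upper edge keeps the
50 ms envelope lag outside the grid.  The summary autocorrelation
function (SACF) is the exponentially weighted running sum of A₁ over
time.

Stages 2 and 3 are leaky integrators run as time-varying exponential
averages

    Aₙ(t, l) = Aₙ(t−Δt, l)·e^(−Δt/Eₙ(t)) + (1 − e^(−Δt/Eₙ(t)))·Aₙ₋₁(t, l)

with lag-dependent τ₂(l) = clip(2l, 2 ms, 100 ms) and τ₃ = 250 ms.  The
drive normalisation gₙ(t) is chosen so a unit constant input yields a
unit plateau; this makes plateau values independent of the integration
step (halving Δt leaves them unchanged) and absorbs the step-size factor
that a literal reading of the discrete recursion would leave in the
drive term.

**Top-down control.**  The effective windows are `Eₙ = τₙ/(1 + g(t))`
with a shared gain `g = ωλ`.  The controller is causal: at each frame the
lag predictions of stages 2 and 3 (profile argmax, ties to the shortest
lag) are compared against an *expectation* — a 20 ms exponential average
of recent predictions.  A discrepancy beyond one lag bin at either
stage, or the absence of any discrepancy for longer than a 250 ms
stability horizon, jumps the gain to g_max = 9 (windows shrink tenfold);
otherwise the gain relaxes exponentially (50 ms).  A strictly one-frame
expectation was rejected: a slowly drifting prediction then passes as
stable (each one-bin step is inside the tolerance), every condition
produces the same purely periodic gain trace, and the adaptive model
loses its condition sensitivity.  The controller is an approximation;
all parameters are exposed.  The static-window control is the identical
pipeline with the gain clamped to zero.

**Read-outs.**  The pitch prediction is `L₃(t)`, the lag of the A₃
maximum.  The settled lag profile is the time average of A₃ over the
last 250 ms (an endpoint snapshot would alias the phase of the last
modulation cycle: at stimulus offset, slow-τ₂ lags still hold activity
the fast lags have already lost).  The salience prediction is the mean
of `A₃(t, L₃(t))` over the settled half of the response (t ≥ 500 ms).
The N100m-predicting signal is the time derivative of `A₃(t, L₃(t))`
smoothed over 25–50 ms (the evoked-field comparison lives below the
20 Hz envelope rate; the raw per-frame derivative is dominated by
within-cycle ripple), and the model-side N100m amplitude proxy is its
maximum over 25–125 ms — the build-up to the N100m latency.  A peak
read-out taken over the whole response was rejected: it rewards onset
and instability transients and inverts the orderings the settled
response shows.

## Auditory image model (simplified)

Per channel, strobes are local NAP maxima exceeding an adaptive
threshold that is reset to the strobed value and released linearly to
zero over 20 ms — asymmetric in time, so rising envelopes strobe on
nearly every carrier peak while decaying envelopes strobe only at their
onsets.  On each strobe the NAP is copied into a time-interval buffer
starting at interval zero, and the copying continues until the next
strobe (inclusive) or until the 35 ms span is exhausted; between strobes
the buffer decays exponentially (30 ms).  The image reported is the
exact time average of the evolving buffer over the stimulus (computed
analytically from the piecewise-exponential decay), with the strobe
sample itself (interval 0) and sub-0.5 ms intervals excluded from the
reported axis for the same pitch-existence-region reason as the lag
grid.  The buffer is deliberately **not** normalised by strobe count:
the snapshot-rate sensitivity — more strobes build a larger image before
the decay takes it back — is precisely the mechanism by which strobed
integration amplifies the ramped/damped asymmetry; the fixed 30 ms decay
already bounds accumulation and makes conditions comparable.  Interval
positions are reported as negative delays (the display convention for
auditory images).  Carrier salience is the height of the summary-image
peak nearest the carrier period.

## Psychophysics

The schedule presents every ordered pair of distinct conditions
(n(n−1) = 90 trials for 10 conditions; 45 unordered pairs).  Salience is
scaled by the Bradley–Terry–Luce model, `P(i beats j) = Sᵢ/(Sᵢ+Sⱼ)`,
fitted by minorisation–maximisation to 1e−8; only ratios are identified,
so strengths are normalised to sum to one.  Items that win or lose every
comparison are flagged, with optional half-pseudo-count regularisation.
The asymmetry index `AI = (x_r − x_d)/(x_r + x_d)` is used for display;
inference is meant to run on the raw choice data, since the index is
ill-conditioned near zero.

## Evoked-field analysis

Source epochs (−500…1400 ms, 1 kHz) are baseline-corrected over the
100 ms before onset; drift is removed by fitting an offset-plus-slope
trend on the last 100 ms of the epoch and subtracting its extrapolation
(with a single series per condition, the principal component of that
segment is its dominant trend), then re-zeroing the baseline.  The N100m
is the minimum in a 50–200 ms search window (ties to the earliest
sample; monotone windows are flagged, not rejected); the sustained field
is the mean over the inclusive 800–1000 ms window (201 samples).  Pooled
nonparametric tests use, per subject, the peak sample ±15 ms
(31 samples; 27 subjects give n = 837) or the full sustained-field
window (201 samples; n = 5427), compared with two-sided Wilcoxon
rank-sum tests; correlations are Pearson.  The model-to-field map is a
least-squares line from the smoothed model derivative to the field over
a 50 ms window centred on the N100m latency, assessed by fitting on one
subject and evaluating on each of the others — N(N−1) ordered folds
(702 for 27 subjects) with per-fold Pearson r and RMSE.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
not MEG physics.  Ground-truth N100m magnitudes (nAm-like units) grow
with half-life, ramped ≥ damped with the gap maximal at 4 ms
(ramped 11/14/22/25/28, damped 10/12/14/22/26 for 0.5/1/4/16/32 ms); a
+5 right-hemisphere boost of the ramped 4 ms response makes the contrast
right-lateralised at that half-life only.  Epochs are a negative
Gaussian deflection (σ = 15 ms) at 100 ms latency (+15 ms for ramped,
whose energy arrives late in the cycle), a smoothed sustained-field
rectangle from 300 ms to shortly after tone offset at 0.6·M₀, linear
drift (|slope| ≤ 0.004 units/ms), white noise (SD 0.8, the residual
noise of a ~120-trial average), and a per-subject log-normal response
scale (σ = 0.2).  BTL strengths are proportional to hemisphere-averaged
M₀, so perception and fields are co-monotone by construction — passing
end-to-end tests therefore shows the pipeline recovers an injected
pattern, not that the pattern holds in real cortex.  Choices are
Bernoulli draws from BTL probabilities, 20 trials per ordered pair.  All
randomness flows through one explicitly passed seeded generator; outputs
are byte-reproducible.

Known biases the tests account for: picking the window minimum on noisy
epochs inflates the measured magnitude by roughly the expected extreme
deviation of the noise (~2 SD over the search window), and the
drift-trend extrapolation from a 100 ms tail adds zero-mean error that
averages out across subjects.

## Numerical choices and problem sizes

Analyses run at a 8 kHz NAP rate with a 0.5–40 ms lag grid
(317 delay lines), full 1 s stimuli, 27 synthetic subjects and
20 trials per ordered comparison pair; the complete test suite and the
acceptance script each run in well under a minute on one CPU.  Ties in
argmax read-outs break towards the shortest lag (deterministic, and
favouring the carrier over envelope periodicity when activity is equal).
Degenerate inputs fail loudly: empty waveforms, non-positive decay or
window constants, lag grids finer than the NAP sampling, disconnected
comparison graphs, and epochs not covering the measurement windows all
raise errors rather than propagate silently.

## Limitations

The periphery is functional, not biophysical; the top-down controller
approximates an unspecified mechanism and is documented as such; BESA
dipole fitting, sensor-space processing and SPL calibration are out of
scope; and no claim about real recordings follows from the synthetic
replication — the reported correlations of the original experiments
require the original in-lab data.
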