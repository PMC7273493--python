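# Methods

## Signal model and processing chain

The package models a two-microphone tracheal recording setup. The
primary microphone, acoustically coupled to the trachea, records the
breath sound `d(n) = B(n) + ν(n)`, where `B(n)` is the clean tracheal
sound and `ν(n)` is ambient noise that leaked into the sensor. The
reference microphone records the ambient noise `x(n)` alone. Because the
leakage path from the room to the primary sensor is an unknown,
possibly time-varying linear system, `ν(n)` is treated as a filtered
version of `x(n)`, which is exactly the setting adaptive noise
cancellation addresses.

Processing order is fixed: cancellation runs first, on the raw 22050 Hz
channels; the detector's band-pass runs afterwards on the canceller's
output. Running the canceller wideband lets it remove noise energy both
inside and outside the detection band, and keeps a single unambiguous
definition of the error signal for SNR evaluation.

## NLMS canceller

A transversal filter with `M` taps estimates the leakage path:

* noise estimate `y(n) = wᵀ(n) x⃗(n)` over the `M` most recent
  reference samples;
* output `e(n) = d(n) − y(n)`, the denoised tracheal sound;
* update `w(n+1) = w(n) + μ/(x⃗ᵀ(n)x⃗(n) + ψ) · e(n) x⃗(n)`.

Parameters, with defaults:

| parameter | default | meaning |
|---|---|---|
| `step_size_mu` | 0.08 | adaptation rate, normalized by tap energy (dimensionless) |
| `regularizer_psi` | 0.02 | keeps the update finite on silent reference stretches |
| `filter_order` | 64 | taps; the leakage paths this filter can model exactly |

Numerical choices: weights initialize to zero, which makes the
silent-reference case an exact identity (the filter never moves, the
primary passes through untouched). The tap buffer is zero-padded before
sample `M`, so no warm-up samples are trimmed and output timestamps stay
aligned with annotations. The tap-energy normalization uses only the
current `M`-sample buffer. The whole recursion runs in float64; the
update is driven by differences `e(n)`, and lower precision there
measurably biases convergence. The recursion is compiled per-sample
(numba); the test suite pins it against an independent straight-loop
implementation at ≤ 1e-9 relative error.

Weights are reset at the start of every record. Whether a deployment
should carry weights across records depends on whether the acoustic
path is stable between them; per-record reset is the conservative
choice and the only one that makes records independent test units.

## Breath detection

The detection feature is the log of the short-time variance of the
band-passed sound. Tracheal breath-sound energy lies roughly in
100–1000 Hz; the 150–800 Hz 5th-order Butterworth band-pass removes
heart sounds and muscle/movement rumble below and broadband hiss above.
The filter is applied forward-backward (zero phase) so that event
boundaries are not delayed relative to reference annotations; the
effective magnitude response is squared, which only helps the stop-band.

Windowing: window = `round(0.020·rate)` samples (441 at 22050 Hz), hop =
`round(window·0.25)` (110 samples ≈ 5 ms); a trailing partial window is
dropped. Variance is the population (1/N) variance, clamped below at
`variance_floor = 1e-12` (signals are unit-full-scale) so digital
silence gives a finite log.

Threshold: the log-var histogram of a usable record is bimodal — a
silence/background mode and a breath-burst mode. The threshold is
computed once per record by deterministic 2-class 1-D k-means (centers
initialized at the 10th/90th percentiles, Lloyd iterations to
convergence) and placed at the midpoint of the two centers. If the two
centers end up closer than 1.0 log-var units the record is effectively
unimodal — either all silence or continuously loud — and the threshold
is set above the maximum so nothing is detected; flagging the whole
record as one long apnea-candidate gap is the conservative failure mode
for a monitor. Per-record computation matches the ~15 min record length
of the protocol; no adaptation schedule is claimed.

Breath marking: maximal runs of windows above threshold, with runs
separated by < 0.25 s merged first (single-window dropouts are common at
a 5 ms hop; 0.25 s is far below any physiologic pause), then runs
shorter than 0.5 s discarded. Event boundaries are the first/last
window-center times of the run.

## Apnea rule and scoring

A gap with no detected inspiration or expiration strictly longer than
15 s is an apnea. Gaps against the record boundaries count: the rule is
about absence of breathing, and a record that starts mid-hold should be
flagged. Scorers that disagree can drop boundary events before scoring.

Scoring is event-level. A detected apnea matches at most one reference
apnea and vice versa; any positive temporal overlap qualifies
(configurable via `min_overlap`), and assignment is greedy by
decreasing overlap length, which resolves the rare one-detection-spans-
two-references case in favour of the larger overlap. Matched reference
events are TPs, unmatched reference events FNs, unmatched detections
FPs. TNs quantize time: the total duration flagged by neither method,
divided by 15 s and floored. Flooring is the conservative reading — a
fractional "true negative event" has no meaning in a contingency table.

Metrics follow the standard 2×2 definitions; Cohen's kappa uses
`(p_o − p_e)/(1 − p_e)` with chance agreement `p_e` from the table
marginals. Any metric with a zero denominator is reported as NaN rather
than a fabricated 0 or 1; a table with only one class present on both
margins has `p_e = 1` and kappa is NaN.

## Mixture SNR evaluation

Cancellation quality on known ground truth is measured on synthetic
mixtures `s(n) = B(n) + Gi·x(n)` (20 s segments by default), with

```
SNRo = 10·log10( var(B) / var(s − B) ),   SNRf = 10·log10( var(B) / var(e − B) )
```

Variance is population (1/N) variance — at 20 s × 22050 Hz the biased/
unbiased difference is ~2e-6 dB, and fixing 1/N makes results
bit-reproducible. An exact identity follows from the definition:
`SNRo(Gi) = SNRo(1) − 20·log10(Gi)`, which pins the expected spacing of
the Gi = 1/1.5/2 operating points. When the canceller is evaluated at
gain Gi, its reference channel is `Gi·x(n)` — the scaled noise actually
present in the mixture.

## Synthetic records

The generator emulates a breath-hold validation protocol: a 900 s
record with a 120 s resting lead-in, then ten 40 s cycles each holding
a 20 s central breath-hold (10 s breathing / 20 s hold / 10 s
breathing). Centring the hold inside the cycle keeps breathing adjacent
to both ends of every hold, so each scheduled hold produces exactly one
inter-breath gap of ~21 s. Breathing is two ~1 s bursts (inspiration,
expiration) per 4 s cycle.

The clean tracheal sound is white noise band-passed to 150–800 Hz and
amplitude-modulated by Tukey (α = 0.5) burst envelopes — it puts all
signal energy in the detector band with realistic soft onsets, but makes
no claim of physiologic spectral detail. The speech-like noise is white
noise shaped by a three-resonance all-pole spectrum (500/1500/2500 Hz)
with 2–8 Hz syllabic amplitude modulation: spectrally and temporally
speech-like without shipping any recorded audio. The noise reaches the
primary channel through a random unit-norm FIR path of 64 taps —
deliberately equal to the canceller's order, so the canceller *can*
model the path exactly but must adapt 64 weights to do so. With
`target_snr_db` set, the coupled-noise gain is solved from the measured
variance ratio, so the requested input SNR is hit exactly.

All draws come from one seeded `numpy` generator; identical protocols
are bit-identical.

What the simulator does **not** model: heart sounds, snoring, body
movement, sensor detachment, hypopnea (reduced rather than absent
flow), breath-to-breath amplitude variability, or a time-varying
leakage path. Passing the validation suite therefore demonstrates the
pipeline's correctness and the canceller's benefit under the modeled
conditions; it does not by itself establish clinical performance on
real recordings.

## Validation problem sizes

The test suite validates schedule recovery on ten noise-free 15-minute
records and the noise-rescue property on five 15-minute records at
−5 dB input SNR with speech-like noise; mixture-SNR properties use ten
seeded 20 s segment pairs. The acceptance script reproduces the
mixture-SNR operating points on 20 s segments (441 000 samples).

## Known limitations

* The log-var threshold rule here (k-means midpoint) is a documented,
  reproducible stand-in; the original acoustic-detection literature does
  not publish its exact threshold computation, and no equivalence is
  claimed.
* Event-level matching has no minimum-overlap requirement by default; a
  1 ms graze counts as a hit. For long (>15 s) events this is benign,
  but `min_overlap` exists for stricter studies.
* Detection runs at the native 22050 Hz; decimating before the log-var
  stage would cut compute ~10× at negligible accuracy cost but is left
  to the caller.
* The canceller assumes the reference microphone picks up no breath
  sound; reference contamination would cause self-cancellation, which
  the simulator does not model.
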