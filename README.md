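# apneasound

Acoustic apnea detection from tracheal sounds, with two-microphone
adaptive noise cancellation.

Tracheal sounds recorded by a microphone over the suprasternal notch are
a cheap, non-invasive way to monitor breathing — during sedation, in the
post-anesthesia care unit, or when screening for obstructive sleep apnea.
The weak point is ambient noise: talking, television, machine alarms leak
into the microphone and get mistaken for breaths, so real apneas are
missed. This package implements the standard remedy from adaptive signal
processing: a second, reference microphone records the ambient noise
alone, and a normalized least-mean-squares (NLMS) filter estimates and
subtracts the noise component from the tracheal channel before breath
detection. It is written for biomedical-signal researchers and engineers
who want a tested, scriptable reference pipeline.

## Method

**Noise cancellation.** With primary input `d(n)` (tracheal sound +
noise) and reference input `x(n)` (noise alone), an `M`-tap transversal
filter produces

```
y(n)   = wᵀ(n) x⃗(n)
e(n)   = d(n) − y(n)
w(n+1) = w(n) + μ / (x⃗ᵀ(n) x⃗(n) + ψ) · e(n) x⃗(n)
```

where `x⃗(n)` holds the last `M` reference samples. `e(n)` is the
denoised tracheal sound. Defaults: `μ = 0.08`, `ψ = 0.02`, `M = 64`.

**Breath detection.** The (denoised) sound is band-passed 150–800 Hz
(5th-order Butterworth, zero-phase), segmented into 20 ms windows with
75 % overlap, and the log of the windowed variance ("log-var") is
thresholded; supra-threshold runs lasting ≥ 0.5 s are inspirations/
expirations. The threshold comes from 2-class k-means on the record's
log-var values.

**Apnea rule.** Any breath-free gap strictly longer than 15 s is an
apnea event.

**Scoring.** Detected apneas are matched to gold-standard events by
temporal overlap (greedy, one-to-one); true negatives count breath-free
time in 15 s quanta. Sensitivity, specificity, PPV, NPV, accuracy and
Cohen's kappa are derived from the resulting 2×2 table.

**Evaluation.** Mixtures `s(n) = B(n) + Gi·x(n)` of clean breathing `B`
and noise `x` are graded by `SNRo = 10·log10(var(B)/var(s−B))` before and
`SNRf` (same, with the filter output) after cancellation.

A seeded simulator generates two-channel validation records emulating a
breath-hold protocol: ~15 min records, 2 min resting breathing, then ten
~20 s breath-holds repeated every 40 s, with optional speech-like noise
coupled into the primary channel through a random FIR path.

## Worked example

```python
from apneasound import SynthProtocol, generate, nlms_cancel
from apneasound.pipeline import detect_events
from apneasound.scoring import build_contingency, compute_metrics

protocol = SynthProtocol(noise_kind="speech_like", target_snr_db=-5.0, seed=507)
record = generate(protocol)          # 900 s, ten 20 s breath-holds, -5 dB SNR

for label, audio in [("raw     ", record.primary),
                     ("filtered", nlms_cancel(record.primary, record.reference))]:
    _, apneas, _ = detect_events(audio)
    table = build_contingency(apneas, record.true_apneas, audio.duration)
    m = compute_metrics(table)
    print(label, f"tp={table.tp} fp={table.fp} fn={table.fn}",
          f"sensitivity={m.sensitivity:.2f}")
```

prints

```
raw      tp=0 fp=0 fn=10 sensitivity=0.00
filtered tp=10 fp=0 fn=0 sensitivity=1.00
```

On the raw channel the speech-like noise fills the breath-hold gaps with
spurious "breaths", so all ten scheduled holds are missed; after
cancellation all ten are recovered with no false alarms.

The same flow is available from the shell:

```
apneasound simulate --duration 900 --noise speech_like --target-snr -5 \
    --seed 507 --out-prefix rec
apneasound filter --primary rec_primary.wav --reference rec_reference.wav \
    --out filtered.wav
apneasound detect --in filtered.wav --out breaths.csv
apneasound score --detected breaths_apneas.csv --reference rec_truth.csv \
    --duration 900
```

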