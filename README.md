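# penpulse

Heart-rate and RR-interval extraction from the built-in triaxial
accelerometer of a hand-held writing device, with ECG-anchored cutoff
calibration and a method-agreement statistics battery.

## The problem

Every heartbeat drives a small acceleration transient into the
fingertips. A sensor-equipped pen held in a writing grip picks this
ballistocardiographic signal up alongside much larger, higher-frequency
handwriting motion. `penpulse` is for researchers who want to turn such
recordings (raw counts from a 100 Hz MEMS accelerometer) into beat
timestamps, beat-to-beat (RR) intervals and heart rate, and to validate
the result against a simultaneously recorded ECG.

The processing chain is:

1. **Magnitude fusion** — the orientation-free Euclidean magnitude
   `a = √(ax² + ay² + az²)` of the rescaled axes;
2. **Detrend** — removal of the ~1 g gravity offset (global mean by
   default, optional);
3. **Low-pass** — a 4th-order Butterworth with 2 Hz cutoff, applied
   forward–backward (zero-phase) so beat timestamps are not delayed;
4. **Beat detection** — strict local maxima with a prominence floor and
   a 0.33 s refractory separation, giving the *t*-vector (timestamps),
   the *Δt*-vector (successive differences) and `HR = 60/Δt` bpm.

Validation tooling reproduces two study-style analyses: a **cutoff
scan** that selects the low-pass cutoff whose detected beat count best
matches a reference (ECG) beat series, and an **agreement battery** per
recording pair — mean Δt ± SD and mean HR per device, Pearson and
cosine similarity of matched *t*-vectors, MSE and Welch's
unequal-variance *t*-test of paired Δt-vectors, an OLS regression of
pen timestamps on ECG timestamps, and five-number Δt summaries.
Two-device beat series are aligned by an exact dynamic program: the
monotone one-to-one matching that maximizes the number of pairs within
a 1 s window, breaking ties by minimal total offset.

Because raw recordings of this kind are rarely shareable, the package
includes a synthetic-recording generator (gravity offset + cardiac
pulse train with Gaussian RR variability + band-limited writing noise +
white sensor noise, quantized to sensor counts) with paired ground-truth
beat lists, so the entire pipeline is testable end to end.

## Worked example

Simulate one 300 s subject, analyze the pen recording, and compare the
detected beats with the ground truth:

```sh
$ penpulse simulate --out demo --subjects 1 --seed 42 --duration 300
[penpulse] subject 1: mean HR 81.5 bpm -> rec_01.csv

$ penpulse analyze --pen demo/rec_01.csv --out demo/analysis
[penpulse] pipeline: magnitude -> detrend(mean) -> butterworth(order=4, cutoff=2.0 Hz,
           zero_phase=True) -> peaks(min_rr=0.33 s, prominence_frac=1.5)
[penpulse] 408 beats, mean HR 81.55 bpm (mean Δt 0.736 s ± 0.053)

$ penpulse compare --pen-events demo/analysis/events.csv --ecg-events demo/truth_01.csv \
      --out demo/report.json
[penpulse] pearson 1.000000, mse(Δt) 2.761e-04 s², ΔHR 0.04 bpm, welch p 0.989
```

Reading the numbers: the pen pipeline found 408 beats at a mean heart
rate of 81.55 bpm; 407 of them matched a ground-truth beat within 1 s.
Matched timestamps correlate at r > 0.9999 (the two clocks tick
together), the mean squared error between paired Δt-vectors is
2.8 × 10⁻⁴ s² (≈17 ms RMS per interval), the mean heart rate deviates
from truth by 0.04 bpm, and Welch's test finds no significant
difference between the interval distributions (p = 0.99). The report
JSON additionally carries both devices' Δt summaries, the regression of
pen on reference timestamps (here y = 0.99999x + 0.0013) and boxplot
five-number summaries.

The same operations are available as a library
(`penpulse.analyze_recording`, `penpulse.compare`,
`penpulse.scan_cutoffs`, `penpulse.generate_cohort`, ...); see
`docs/methods.md` for the model and parameter details.

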