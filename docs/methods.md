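# Methods

This note documents the models, numerical choices and limitations
behind `penpulse`, in the order the pipeline runs.

## Signal model and units

A pen-mounted MEMS accelerometer (LSM6DSL-class, 100 Hz) reports raw
integer counts per axis. Counts convert to units of g through an affine
`ScaleConfig`; the default assumes a ±2 g range at 16384 counts/g with
zero offset, and every field is overridable because vendors and range
settings vary. All times are seconds as floats, indices 0-based; each
file starts its own clock, and cross-device clock offsets are handled
at the alignment stage, never by the readers.

The working channel is the Euclidean magnitude of the three axes. For a
hand-held pen the attitude is uncontrolled, so any axis-wise analysis
would confound grip orientation with physiology; the magnitude is
rotation invariant (property-tested against random orthonormal
rotations). A resting grip leaves the magnitude near 1 g; the default
detrend subtracts the global mean so that peak prominences are
comparable across recordings. A centred moving-mean variant (window in
seconds) exists for drifting grips, and detrending can be disabled to
run the filter directly on the offset signal — the low-pass pipeline
itself does not require it.

## Filtering

The cardiac fundamental at resting rates lies at 0.9–1.4 Hz, while
handwriting strokes and tremor concentrate higher. The separating
filter is a 4th-order digital Butterworth low-pass at 2 Hz (bilinear
design with prewarping, second-order sections), maximally flat with its
−3.01 dB point exactly at the cutoff.

Application is **zero-phase** (forward–backward) by default. The
pipeline's output is compared per-beat against ECG R-wave timestamps;
a causal 4th-order filter at 2 Hz would shift every peak by a
group delay of the order of 0.2 s, turning a timing comparison into a
comparison of filter artifacts. Forward–backward application cancels
phase exactly (sub-cutoff peak displacement under one sample,
asserted in tests) at the cost of squaring the magnitude response —
the effective attenuation order doubles, and `frequency_response`
exposes both the single-pass |H| and the effective |H|². Edges are
handled by reflective padding of 3× the filter order in samples;
recordings are minutes long, so edge transients are confined to a
fraction of a second at either end. Causal mode is available for
streaming-style use.

## Beat detection

A beat is accepted where the filtered trace has a strict local maximum
whose topographic prominence reaches `prominence_frac` × SD(trace),
with no larger accepted peak within `min_rr` seconds (greedy
enforcement in decreasing height order, ties to the earlier sample; the
whole detector is verified against an exhaustive brute-force scan on
random traces).

* `min_rr = 0.33 s` caps detectable rates near 181 bpm — far above any
  seated writing scenario — while rejecting stroke residuals.
* `prominence_frac = 1.5`. The threshold must sit above the prominence
  distribution of low-passed broadband noise: after a 2 Hz zero-phase
  low-pass, white sensor noise retains ≈4% of its power, and its local
  maxima reach prominences of ~2–3 noise SD. At low heart rates the
  diastolic gap (up to ~0.8 s beyond the refractory window) leaves room
  for such maxima to be accepted; with a 0.5·SD threshold this produced
  tens of false beats per 5-minute recording at 55 bpm in simulation,
  while 1.5·SD rejects them and still sits well below the prominence of
  a cardiac bump on any usable recording. Both parameters are exposed
  in the run configuration.

Peak time is the time of the maximal sample; sub-sample parabolic
interpolation exists behind a flag but is off by default, since all
timing contracts are stated at one-sample resolution. Mean heart rate
is defined as 60/mean(Δt) — the reciprocal of the mean interval, not
the mean of per-beat rates.

## Cutoff calibration

`scan_cutoffs` reproduces the verification loop used to justify the
2 Hz cutoff: for each candidate cutoff, filter, detect, and score by
|detected count − reference count|; ties break by the higher Pearson
correlation of matched timestamps, then by the lower cutoff (stronger
noise rejection). The default grid is 0.5–8 Hz in 0.25 Hz steps. At the
selected cutoff, an OLS regression of matched pen timestamps on
reference timestamps is reported; a perfectly aligned pair gives
y = x. This is a development-time tool — it requires a reference beat
series that a deployed pen does not have.

## Event alignment and agreement statistics

Two independently detected beat series are aligned by an exact dynamic
program over monotone one-to-one matchings: maximize the number of
pairs subject to |pen − ecg| ≤ `max_offset` (default 1 s, matching the
observed sub-second inter-device delays), break ties by minimal total
absolute offset. The DP encodes the lexicographic objective in a single
float score (pairs·BIG − cost) and is verified against a recursive
enumeration oracle. An optional global clock-shift estimate (pair-count
maximization over a ±5 s grid) precedes matching for two-device
recordings with unsynchronized clocks; it defaults off, since synthetic
pairs share one clock. One caveat is documented rather than patched:
when the RR interval is shorter than `max_offset`, a spurious-plus-missed
detection pair can let the maximum-cardinality objective chain-shift a
stretch of pairs by one beat; the paired-Δt restriction below keeps the
interval statistics immune to all but the boundary of such a stretch.

The battery per pair:

* **t-vector statistics** (Pearson r, cosine similarity, OLS
  regression) use matched pairs only — with unequal series lengths this
  is the only well-defined reading. Cosine similarity is computed on the
  raw, uncentred timestamps.
* **Δt statistics** (MSE, Welch's t) use intervals bounded by
  *consecutively* matched beats in both series, so a missed or spurious
  beat never contaminates a paired interval. Welch's test is two-sided
  with Welch–Satterthwaite degrees of freedom, hand-computed from the
  formula and cross-checked in tests against an independent
  implementation and a permutation oracle; the degenerate
  both-samples-constant case returns t = 0, p = 1 (equal means) by
  convention.
* **Per-device summaries** (mean Δt, sample SD, mean HR, five-number
  boxplot summaries, median difference) use each device's full
  Δt-vector. The median difference is stored signed (pen − ecg).

Reports serialize to JSON with repr-precision floats: re-reading
reproduces every field bit-exactly, and identical reports produce
byte-identical files.

## Synthetic recordings

The generator emulates a five-minute seated-writing acquisition and is
the package's test bed; its defaults *are* the declared study
conditions.

| parameter | default | meaning |
|---|---|---|
| `duration`, `fs` | 300 s, 100 Hz | acquisition length and rate |
| `mean_hr`, `sdnn` | 70 bpm, 0.05 s | truncated-Gaussian RR model (floor 0.33 s); optional AR(1) correlation behind `rr_ar1` |
| `pulse_amp` | 0.08 g | apex of the cardiac bump (Gaussian-windowed raised cosine, width 0.15 s) |
| `writing_band`, `writing_amp` | 4–8 Hz, 0.08 g RMS | band-limited writing-motion noise |
| `sensor_noise_sd` | 0.01 g | per-axis white noise |
| `gravity`, `orientation` | 1 g, (0.36, 0.48, 0.80) | static grip attitude |

Choices that were genuinely open:

* **Pulse template.** The pipeline uses only the timing of the pulse
  apex, so waveform realism beyond a smooth, correctly timed peak is
  out of scope. The noise-free magnitude peaks at the truth beat times
  to within one sample by construction.
* **Pulse amplitude.** Published fingertip/pen-coupled cardiac
  transients span roughly 0.01–0.1 g depending on grip and mounting;
  the default sits at the upper-middle of that range, emulating the
  clearly-detectable-beat regime that motivated the original
  acquisition, and giving the pipeline its design margins (mean-HR
  error ≤ 1 bpm across 54–85 bpm at the default noise levels,
  beat count within ±2 even at 3× writing noise).
* **Writing noise geometry.** By default the writing component is a
  single scalar band-limited process along the grip direction. Isotropic
  per-axis noise, the obvious alternative, rectifies through the
  magnitude nonlinearity (|w|²/2g), dumping intermodulation power
  *below* 2 Hz and breaking the band separation the model is designed
  around; the isotropic variant is retained behind `writing_isotropic`
  for stress testing. The band default (4–8 Hz) makes the calibration
  scan's qualitative outcome reproducible: 1 Hz clips the cardiac band,
  4 Hz admits stroke noise, 2 Hz wins.
* **Quantization** to the sensor count grid is applied last, using the
  same `ScaleConfig` as the readers, so write–read round trips lose at
  most one count.

Every recording is a pure function of its own sub-seed (spawned from
the master seed), so cohorts are reproducible and order-independent.

What the generator does **not** emulate — and therefore what passing
tests do not show about real data: respiratory and autonomic modulation
of RR beyond (optionally AR(1)-correlated) Gaussian variability,
grip-orientation dynamics and posture shifts, the true spectrum and
intermittency of handwriting (real strokes are bursty and partly
sub-2 Hz, where they would compete with the cardiac band), sensor bias
drift, and inter-device clock skew (the synthetic pair shares one
clock, so regression slopes near exactly 1 are expected there).

## Problem sizes in the test suite

The suites validate at the declared study scale: 8-subject cohorts of
300 s recordings for the headline agreement bounds, a 20-seed cutoff
scan over {1, 2, 4} Hz, 1000 random traces against the brute-force peak
oracle, matching against the enumeration oracle up to 50 events, a
10⁵-draw permutation check of one Welch p-value at n = 30 per group,
and 1000 null replicates for type-I calibration.
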