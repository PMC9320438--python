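# Methods

## Signal model

The horizontal pupil-center coordinate of each eye during optokinetic
stimulation is modelled as a sawtooth: slow-phase (SP) ramps at the pursuit
velocity, interrupted 2–4 times per second by fast-phase (FP) resets lasting
a few tens of milliseconds. Coordinates are kept in the tracker's native
linear unit ("tracker units"): the device reports pupil displacement on a
scale it labels millimetres, but the magnitudes (0.031 units across a 40°
sweep) are not physical millimetres, so the unit is treated as opaque and
converted to visual degrees only through the calibration model
(`deg_per_unit = 2·θ_calib / d`, ≈ 1290 deg/unit for the reference setup).

Assumptions: the stimulus moves horizontally at constant speed; the subject's
head is stabilised (drift and gaze-away excursions are treated as artifacts,
not signal); analysis is monocular per channel, with both eyes carried on a
single time base.

## Abnormal-point filtering

A sample is deleted when either eye's coordinate leaves
`[C − h, C + h]` (strict inequalities; boundary values retained) or the
tracker flags the sample invalid. The half-range `h` comes from scaling the
calibration sweep displacement to the full screen width and halving it
(0.02325 units for the reference geometry; conventionally printed truncated
as 0.023 — the model keeps full precision and exposes `truncate_3dp` only to
reproduce printed constants, so rounding error is never baked into the
filter).

Both eyes are deleted jointly when any rule fires: downstream slope
arithmetic assumes one time base, and a sample untrustworthy in one eye is
suspect in the other (blinks and head motion are binocular). Deletion — never
interpolation — is the filtering mechanism; the trace is then split wherever
the timestamp gap exceeds `max_gap_samples/fs` (default 5 samples ≈ 33 ms)
and fragments shorter than `min_segment_s` (default 0.5 s, under two OKN
cycles) are dropped, since extrema and slopes spanning a blink are
meaningless and a sub-cycle fragment cannot anchor the adaptive thresholds.

## Detection

**Extrema.** Interior turning points are found by neighbour comparison
(plateaus take their first index — a deterministic tie-break; trace endpoints
are never candidates, as they cannot be compared on both sides). Candidates
are then gated sequentially: an opposite-kind candidate is accepted only if
it differs from the last accepted extremum by strictly more than `min_gap`
(default 0.001 tracker units); a same-kind candidate replaces the last one
when more extreme. The output alternates max/min with gaps above `min_gap`,
and is verified in the test suite against an independent brute-force oracle
on 1,000 random series.

**Classification.** Segments between consecutive extrema carry slope
`Δx/Δt`. For a leftward stimulus the SP follows the stripes (positive slope)
and the FP resets (negative slope, magnitude ≥ M); mirrored for rightward.
`M` defaults to `2 × median(|slope|)` over segments whose slope sign matches
the SP convention. Anchoring the median on the SP-sign population matters:
FP and SP segments alternate in roughly equal numbers, so a median over
*all* segments lands midway between the two populations and twice that value
would exceed the FP slopes themselves. FP slopes are several-fold steeper
than SP slopes by construction (the reset covers the whole slow-phase
excursion in a few tens of milliseconds), so twice the SP scale separates
them without committing to a unit system. An absolute `M` can be configured
instead.

**Amplitude consistency.** Each fast phase resets the excursion accumulated
by the preceding slow phase, so within a trace FP amplitudes track SP
segment amplitudes. FP candidates below `fp_amplitude_factor` (default 0.5)
times the median SP amplitude are demoted to unclassified: under realistic
sample jitter, extremum pairs marginally above the 0.001-unit gate appear
with steep slopes and would otherwise be counted as fast phases. The gate is
structural (no-op on clean data, where the two amplitude populations
coincide; no-op without SP segments to anchor it) and is disabled by setting
the factor to 0.

**Refinement.** FP endpoints snap to the raw local extremum within
±`refine_window` samples (default 3 = 20 ms at 150 Hz), clamped so endpoints
cannot cross; this can only grow the amplitude. The event onset `t_peak` is
then estimated by velocity thresholding: take the steepest single-sample
step of the reset, walk back while steps remain at least a third as steep,
and place the onset where that run starts. On clean data this is exactly the
onset-side extremum; on jittery data it is markedly more stable, because the
highest raw sample can precede the true reset corner by several samples
(jitter standard deviation exceeds the per-sample SP rise), while the
steep-step run boundary moves by at most a sample or two.

## Metrics and evaluation

MSPV is the mean absolute SP-segment slope converted to deg/s; gain is
MSPV over stimulus speed. Detections are scored against reference fast-phase
times (physician marks or simulator truth) by greedy one-to-one matching in
increasing time order within a tolerance (default 0.033 s = 5 samples at
150 Hz, within-saccade precision; the matching is monotone non-decreasing in
the tolerance). `recognition_rate` is the matched fraction of reference
events; the false-positive rate, precision and F1 are reported alongside.

## Baselines

* **Naive peak finding** — every strict interior local maximum; no gating.
* **Welch periodogram** — averaged modified periodogram; defaults: Hamming
  window, 2 s segments (0.5 Hz resolution, ample for the 2–4 Hz OKN band),
  50% overlap, density scaling (integral ≈ variance).
* **Fourier series** — truncated trigonometric representation
  `S(k) = x0/2 + Σ xi cos(2πiTk) + bi sin(2πiTk)`; fitting one period via
  the DFT reconstructs the samples exactly (Nyquist term halved for even
  lengths).
* **FIR filtering + threshold** — zero-phase (forward–backward) linear-phase
  FIR; defaults: high-pass 1.5 Hz or band-pass 2–4 Hz, 101 taps. The series
  mean is removed first (neither mode passes DC, and at these cutoff/tap
  ratios the designed stopband alone leaves percent-level DC leakage).
  Peaks of the filtered magnitude above an adjustable threshold (default:
  95th percentile of the magnitude — scale-free, and robust to the band-pass
  case where the filter passes the OKN fundamental itself and median-based
  rules exceed the global maximum) are mapped to the adjacent raw local
  maximum and minimum. "Adjacent" extrema must dominate the raw series over
  the saccade timescale (40 ms of samples each side) so the mapping does not
  latch onto per-sample jitter.

The spectral/FIR baselines receive the trace with invalid samples linearly
interpolated: they require a contiguous series, and dropout placeholders
(coordinate 0) would otherwise dominate the filters with step transients.
The slope-threshold pipeline never interpolates.

### Comparison protocol

`okn compare` / `oknkit.benchmark.compare_methods` scores each method on the
same fixtures under a clean and a noisy condition. Reference marks exclude
fast phases inside contaminated windows — events swallowed by a blink or
excursion are unrecoverable by any method — and detections inside those
windows are excluded symmetrically. Since the FIR baselines' threshold is
operator-adjustable by design, the harness grants them the benefit of
adjustment (a per-trace sweep over magnitude quantiles, keeping the best
score); the slope-threshold detector runs fully automatic. Methods are
ranked on F1 from one-to-one matching: recall alone cannot rank them because
over-detection (the naive peak finder emits hundreds of jitter peaks)
saturates recall under nearest matching.

## Synthetic generator

`generate_okn` emulates what the tracker records during a stimulus session:
a binocular sawtooth (both eyes move identically, centred on their own
fixation values) sampled at 150 Hz for 20 s by default. A trace of duration
`D` at fast-phase rate `r` contains `floor(D·r)` resets separated by
`floor(D·r)+1` SP ramps, so every reset has samples on both sides and is in
principle detectable; SP ramp lengths are jittered ±10% (configurable) so
the comb is not unrealistically regular, and each reset exactly cancels its
ramp, keeping the trace stationary and inside the outlier bounds in the
absence of noise. Defaults: SP velocity 20 deg/s, FP rate 3/s, FP duration
30 ms, centres CL = 0.35 / CR = 0.40, scale from the reference calibration.
FP amplitude is not a free parameter: it equals SP velocity × ramp length in
tracker units (≈ 0.005 units at the defaults), which keeps the waveform
bounded like real recordings.

The noise model covers the disturbance taxonomy that motivates the filter:

| component   | default (preset)          | emulates                          |
|-------------|---------------------------|-----------------------------------|
| jitter      | σ = 3·10⁻⁴ units/sample   | sensor/estimation noise           |
| blinks      | rate 1/3 Hz × 0.15 s (≈5% of samples, invalidated & zeroed) | eyelid closure / pupil loss |
| gaze-away   | 3 × 0.5 s, ±0.05 units    | looking off-screen                |
| drift       | 0.002 units, 0.1 Hz sinusoid | fatigue / slow head motion     |

Noise windows are placed (seeded, rejection-sampled) at least 1 s apart and
0.6 s from the trace edges so clean spans always exceed the 0.5 s
minimum-segment cutoff; ground truth records each window expanded by 50 ms,
since a fast phase that close to a dropout loses the neighbouring samples
its bracketing extrema need.

What the generator does **not** model: physiological saccade velocity
profiles (resets are linear), vertical/torsional components, pupil-size
changes, asymmetric or disconjugate eye movements, and slow habituation of
the OKN rhythm. Tests passing on these fixtures therefore demonstrate the
algorithmic properties of the pipeline (gating, classification, robustness
to the modelled artifact classes), not clinical performance on patient
recordings.

## Numerical choices and degenerate inputs

Seeded `numpy` generators drive all randomness (one integer seed per
fixture). Plateau ties break to the first index; `argmax`/`argmin` ties in
refinement break to the earliest sample; spectral ties break to the lowest
frequency. Empty traces filter to empty reports (not errors); traces where
no segment survives preprocessing yield an empty event list with a warning.
Boundary values exactly on the outlier bounds are retained; a slope of
exactly zero is left unclassified. Evaluation with an empty reference
returns recognition 0.

Problem sizes used by the test suite and the acceptance script — 10
noise-free and 20 noisy 20 s fixtures, 1,000 random series for the oracle
check, 5 seeds per condition in the method comparison — are the package's
standing benchmark configuration; all run in seconds.

## Known limitations

* The slope threshold and amplitude gate assume a reasonably stationary OKN
  rhythm within each analysis segment; congenital-nystagmus waveforms or
  strongly habituating responses would need per-window adaptation.
* Joint binocular deletion discards monocular information; genuinely
  disconjugate recordings would be better served by per-eye filtering.
* The onset estimator presumes the reset is the steepest feature locally;
  overlapping artifacts steeper than saccades inside a retained segment
  could mislead it.
* Tracker units are assumed linear in gaze angle over the screen; no
  nonlinear gaze mapping is attempted.
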