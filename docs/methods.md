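# Methods

This note records the models, parameter choices and numerical conventions
behind `capbio`, and what the synthetic-data experiments do and do not
demonstrate.

## Signal model and conventions

All signals are uniformly sampled voltage traces (`TimeSeries`) with an
explicit sampling rate and start time; sample `i` of a series is at
`t0 + i/fs` exactly. Times are seconds from record start, indices are
0-based, and every interval is half-open `[start, end)`; slicing at
non-aligned times rounds the start up and the end down to sample times,
so adjacent slices partition exactly. All channels of a session are
assumed to share one clock (the acquisition model is a single multichannel
ADC). The digitization model is a uniform mid-rise quantizer —
`2**bits` levels across `[vmin, vmax]`, defaults 16 bit over ±10 V —
with clipping at the rails; in-range quantization error is bounded by
half an LSB. The canonical file dialect is delimited text (`time_s`
column plus one column per channel; annotations as `time_s,label`),
chosen so fixtures stay human-inspectable; the sampling rate is
recovered from the time column and snapped to 6 decimals to absorb
text-formatting rounding.

## Synthetic sessions

The generator exists to exercise the analysis chain, not to be a
physiological simulator. Its defaults encode the recording conditions the
analyses assume: 10 kHz sampling, 2-min rest periods, seven two-cough
cycles.

**RR sequence.** `RR(t) = 60/HR + d_LF·sin(2πf_LF t) + d_HF·sin(2πf_HF t)
+ N(0, σ_RR)`, with draws below 0.25 s resampled (a hard physiological
floor that also guarantees the detector's refractory assumption). The
first beat falls one RR after record start and generation stops half a
second before record end, so no complex is truncated at an edge. Defaults:
HR 70 bpm, σ_RR 20 ms, no deterministic modulation (HRV experiments
switch it on explicitly).

**ECG morphology.** Each beat is five Gaussian bumps (P, Q, R, S, T) at
fixed offsets (−200, −40, 0, +40, +300 ms) and widths (35, 10, 12, 10,
55 ms). Only the amplitude ratios and timing matter downstream, which is
why a published dynamical ECG model is not used: the Gaussian template
keeps every oracle analytic (the R apex is the global extremum, the R/T
ratio is a direct quotient of configured amplitudes). Default amplitudes:
R 100 µV — the signal level the front end is designed around — T 30 µV,
P 10 µV, Q −15 µV, S −20 µV at the electrode.

**Capacitive distortion.** The capacitive copy optionally passes a
single-pass first-order low-pass (magnitude `1/√(1+(f/fc)²)`), the
analytic stand-in for stray-capacitance attenuation, plus extra baseline
wander (low-passed noise, RMS-scaled) and white noise. Ground-truth
R-times are those of the underlying beats and are not shifted by the
filter's phase lag; the detector's RRI-based scoring is insensitive to
constant delays, which is what makes this convention safe.

**Degraded-subject profile.** `t_dominant_profile()` encodes the failure
regime observed in practice: R 35 µV, T 110 µV, first-order attenuation
at 12 Hz, broadband noise σ 60 µV, wander 25 µV RMS. The parameters were
set from the in-band amplitude budget: after the detection preprocessing
the R residual is ≈8.5 µV while 60 µV broadband noise leaves ≈2 µV of
in-band noise, i.e. an in-band SNR ≈ 2 with ~1200 candidate noise extrema
per 2 min — enough that an 80 %-of-largest-five threshold sits above most
true beats. This reproduces the qualitative failure (mostly missed beats
plus false detections) without being calibrated to any particular
accuracy number.

**Cough protocol.** Layout: 120 s rest, then `n_cycles` (default 7)
two-cough cycles — two 0.4-s bursts 0.4 s apart, cycles 4 s apart — then
120 s rest. Bursts are white noise band-passed to 40–500 Hz, RMS-scaled
(default 100 µV vs 10 µV resting background, i.e. burst RMS 10× rest),
half-cosine tapered, and copied to the capacitive channel at 0.6× with
its own background noise. One annotation stamp per cycle sits at the
cycle midpoint — the stamp is only a reference point, and the midpoint
makes the segment search symmetric. A decaying 0.8 Hz oscillation after
each cycle emulates post-cough baseline wander in the cECG. All draws in
a session flow from one seeded generator; equal seeds give bit-identical
sessions.

What the generator does **not** emulate: respiration and
ballistocardiogram components, motion artifacts other than post-cough
wander, powerline interference, electrode repositioning, beat-to-beat
amplitude variation, and cough-vs-swallow/inhalation confusers. Passing
tests therefore demonstrate the correctness and calibration of the
analysis chain under the stated model, not field performance on real
pillow recordings.

## R-wave detection and scoring

The band-pass is realized as a 4th-order Butterworth applied
forward-backward (zero phase): the specification of the original chain
names only "IIR, 10–20 Hz", and zero phase keeps detected extremum times
alignable with ground truth. The moving average is centered with
truncated edges. Differencing is `x[n] − x[n−Δ]`, Δ = round(10 ms·fs),
with the leading Δ samples zeroed to preserve length.

Threshold estimation selects candidate local extrema of the dominant
polarity (the polarity whose top-five extrema have the larger mean
magnitude — detection of R-wave bottoms falls out automatically when the
trace is inverted), separated by the refractory interval (default 0.25 s,
HR ≤ 240 bpm). "Five assumed R-waves chosen at random" is implemented
seedably; a deterministic largest-five mode is the test default, since a
random choice is otherwise irreproducible. On a clean record the two
modes agree by construction (all candidate R-waves have nearly equal
amplitude).

Beat scoring pairs trains greedily by nearest time within ±150 ms, then
applies the RRI rule: a paired test beat whose predecessor is also paired
is a true positive iff `|RRI_test − RRI_ref| ≤ 10 ms`; a violating pair
produces one FP (test side) and one FN (reference side); unpaired
RRI-bearing beats are FP/FN respectively. Only RRI-bearing beats (those
with a predecessor) are counted, so identical k-beat trains give
`N_TP = k−1`. This bookkeeping makes the counts conserve: every test
RRI-beat is TP or FP and every reference RRI-beat is TP or FN — a
property the test suite asserts over random trains. With `N_TN = 0`,
accuracy is algebraically ≤ min(sensitivity, PPV). Display rounding is
half-away-from-zero to one decimal, the convention needed to match the
published per-subject table from its integer counts.

## Cough-EMG analysis

Segment boundaries were identified manually in the original protocol;
here they are automated as RMS-envelope thresholding (50-ms window)
at `μ_rest + 5σ_rest`, with activity gaps under 0.5 s bridged so a
two-cough pair forms a single segment. All three parameters are exposed
in `SegmentSelectionConfig`. The same threshold defines "stable" resting
segments (envelope maximum below it), replacing the visual exclusion of
swallowing/inhalation firings. Boundary identification runs on the
reference EMG channel and the windows are reused for the capacitive
channel, mirroring the original procedure.

The DFT amplitude spectrum is single-sided and unwindowed (rectangular) —
a Hann option exists but the rectangular transform is canonical here —
with `A[k] = (2/N)|X[k]|` at interior bins and `(1/N)|X[k]|` at DC and
Nyquist, so Parseval's identity holds in the form
`mean(x²) = A₀² + Σ A_k²/2 (+ A_Nyq²)`. TSA sums bins with
`40 Hz ≤ f ≤ 500 Hz`, both edges inclusive on the DFT grid; whether the
original statistic summed bins or integrated density is not documented,
and bin-sum is the implemented, documented choice. The group comparison
runs Shapiro–Wilk (α = 0.05) on the paired differences — no specific
normality test was named in the original description — then a paired
t-test (normal) or Wilcoxon signed-rank (otherwise), one-sided
coughing > resting by default with a two-sided option. Note that with
five pairs the smallest attainable one-sided Wilcoxon p is 1/32 ≈ 0.031.

## HRV bands

The commercial HRV tool used for the original comparison is a black box,
so the estimator here is a documented stand-in validated by simulation
properties (injected LF/HF modulation lands in the right band; band
power scales with modulation amplitude squared): cubic-spline
resampling of the RRI sequence at 8 Hz, Welch PSD (segment length 256
samples, 50 % overlap, mean removed), and per-band summary = mean PSD
over bins inside the band, DC excluded (the VLF band starts at the first
nonzero bin). Published absolute band PSDs are therefore not reproduction
targets; the error-rate arithmetic `100·|ref−test|/ref` on the published
PSD pairs is exact and is what the acceptance checks recompute. The
bundled published table stores values as printed strings so each cell's
printing resolution is known; recomputed error rates are compared within
the uncertainty that resolution propagates (some printed error cells
derive from unrounded PSDs and cannot be matched digit-for-digit from
the printed operands).

## Front-end model

All impedances are real magnitudes at a stated frequency — the same
level of abstraction as the design arithmetic being reproduced; a
complex-phasor mode is deliberately out of scope. The varistor is ideal
(`Rh` strictly below threshold, short otherwise), and the boundary
`|v| = V_thr` is assigned to the clamped branch: the underlying relation
is an open interval, so a convention is required. The permittivity
default `8.85e-12 F/m` is treated as the absolute permittivity of the
coupling dielectric; the design arithmetic (57.5 pF from S = 2.00e-3 m²,
d = 3.08e-4 m) only works under that reading. Below threshold the exact
`Z = R1 + Rbv + R1·Rbv/R3` is dominated by `R1·Rh/R3`; the relative gap
is bounded by `(R1+Rh)/(R1·Rh/R3)`, asserted numerically in the tests.

## Problem sizes and numerical tolerances

Simulated sessions used throughout the tests and analyses are 2-min
resting recordings and ~4.5-min cough-protocol sessions at the full
10 kHz rate (the multi-seed calibration study runs 100 such sessions).
The first-order attenuation check allows 2 % for bilinear-transform
warping; envelope boundary recovery is checked to within one envelope
window (50 ms); Parseval to 1e-9 relative; detector jitter on clean
records to < 2 ms standard deviation. Degenerate inputs (empty trains,
zero denominators, constant differences) return explicit sentinels
(`None`) rather than zeros, so undefined metrics can never masquerade as
perfect or null results.
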