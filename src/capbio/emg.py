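"""Cough-EMG segment selection, DFT spectral amplitude, and group comparison.

The cough-activity statistic is the total spectral amplitude (TSA): the
sum of single-sided DFT amplitude bins between 40 and 500 Hz of a fixed-
duration segment.  Segments come in two conditions:

* *coughing segments*: for each two-cough cycle, the burst segment is
  located around the recorded time stamp by RMS-envelope thresholding;
  the first and last cycles are dropped, the mean duration (MD) of the
  rest is computed, and each retained segment is replaced by a window of
  duration ``1.2 * MD`` centered on its midpoint;
* *resting segments*: equal-duration windows tiled over the quiet rest
  period, keeping only those without visible firings (envelope below the
  onset threshold).

Mean TSA over the two conditions is compared with a paired test gated on
normality of the differences (Shapiro-Wilk): paired t-test when normal,
Wilcoxon signed-rank otherwise, one-sided coughing > resting by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy import stats

from .signal_core import SignalError, TimeSeries, slice_series

__all__ = [
    "EMGPreprocessConfig",
    "SegmentSelectionConfig",
    "CoughCycleSegment",
    "TSASummary",
    "TSAComparison",
    "preprocess_emg",
    "rms_envelope",
    "envelope_stats",
    "locate_cough_segment",
    "mean_duration",
    "extend_segments",
    "select_resting_segments",
    "amplitude_spectrum",
    "total_spectral_amplitude",
    "compare_tsa",
    "cough_tsa_analysis",
]


@dataclass(frozen=True)
class EMGPreprocessConfig:
    """EMG band-pass: 40-500 Hz Butterworth, zero-phase."""

    band: tuple[float, float] = (40.0, 500.0)
    filter_order: int = 4

    def validate(self, fs: float) -> None:
        lo, hi = self.band
        if not (0 < lo < hi < fs / 2):
            raise SignalError(f"band {self.band} outside (0, fs/2) for fs={fs}")


@dataclass(frozen=True)
class SegmentSelectionConfig:
    """Parameters of the automated segment-boundary identification.

    The envelope is a short-time RMS (window ``envelope_window`` s);
    activity is envelope above ``mu_rest + onset_k * sigma_rest`` where
    the rest statistics come from a designated quiet interval.  Active
    runs closer than ``merge_span`` are bridged so a two-cough pair forms
    one segment.
    """

    extension_factor: float = 1.2
    exclude_first_last: bool = True
    n_rest_segments: int = 5
    envelope_window: float = 0.05   # s
    onset_k: float = 5.0
    search_halfwidth: float = 2.0   # s around each time stamp
    merge_span: float = 0.5         # s

    def __post_init__(self) -> None:
        if self.extension_factor < 1.0:
            raise SignalError("extension_factor must be >= 1")
        if self.envelope_window <= 0 or self.search_halfwidth <= 0:
            raise SignalError("envelope_window and search_halfwidth must be > 0")


@dataclass(frozen=True)
class CoughCycleSegment:
    """One located two-cough segment (seconds, half-open interval)."""

    start: float
    end: float
    cycle_index: int = 0

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise SignalError(f"segment start {self.start} !< end {self.end}")

    @property
    def middle(self) -> float:
        return 0.5 * (self.start + self.end)

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class TSASummary:
    """Per-segment TSA values for one channel and their condition means."""

    rest_tsas: np.ndarray
    cough_tsas: np.ndarray
    band: tuple[float, float] = (40.0, 500.0)

    @property
    def mean_rest(self) -> float:
        return float(np.mean(self.rest_tsas))

    @property
    def mean_cough(self) -> float:
        return float(np.mean(self.cough_tsas))


@dataclass(frozen=True)
class TSAComparison:
    """Outcome of the normality-gated paired comparison."""

    test_name: str            # "paired-t" | "wilcoxon-signed-rank"
    statistic: float | None
    p_value: float | None
    direction: str            # "coughing>resting" | "resting>coughing" | "none"
    normal: bool
    shapiro_p: float


def preprocess_emg(ts: TimeSeries,
                   cfg: EMGPreprocessConfig = EMGPreprocessConfig()) -> TimeSeries:
    """Zero-phase band-pass; length preserved."""
    cfg.validate(ts.fs)
    sos = sps.butter(cfg.filter_order, cfg.band, btype="bandpass", fs=ts.fs,
                     output="sos")
    return ts.with_samples(sps.sosfiltfilt(sos, ts.samples))


def rms_envelope(ts: TimeSeries, window: float = 0.05) -> TimeSeries:
    """Short-time RMS envelope (centered window, edges truncated)."""
    w = max(1, round(window * ts.fs))
    kernel = np.ones(w)
    num = np.convolve(ts.samples**2, kernel, mode="same")
    den = np.convolve(np.ones(len(ts)), kernel, mode="same")
    return ts.with_samples(np.sqrt(num / den))


def envelope_stats(emg: TimeSeries, rest_interval: tuple[float, float],
                   cfg: SegmentSelectionConfig) -> tuple[float, float]:
    """(mean, sd) of the RMS envelope over the designated rest interval."""
    env = rms_envelope(slice_series(emg, *rest_interval), cfg.envelope_window)
    return float(np.mean(env.samples)), float(np.std(env.samples))


def _active_runs(mask: np.ndarray, fs: float, merge_span: float):
    m = mask.astype(np.int8)
    starts = np.flatnonzero(np.diff(np.r_[0, m]) == 1)
    stops = np.flatnonzero(np.diff(np.r_[m, 0]) == -1) + 1
    runs: list[list[int]] = []
    gap = merge_span * fs
    for a, b in zip(starts, stops):
        if runs and a - runs[-1][1] < gap:
            runs[-1][1] = b
        else:
            runs.append([a, b])
    return runs


def locate_cough_segment(emg: TimeSeries, stamp: float,
                         cfg: SegmentSelectionConfig,
                         rest_stats: tuple[float, float],
                         cycle_index: int = 0) -> CoughCycleSegment:
    """Identify one two-cough segment around a recorded time stamp.

    The RMS envelope over ``stamp ± search_halfwidth`` is thresholded at
    ``mu_rest + onset_k * sigma_rest``; activity gaps shorter than
    ``merge_span`` are bridged and the span from first to last active
    sample is the segment.
    """
    if not (emg.t0 <= stamp < emg.end):
        raise SignalError(f"stamp {stamp} s outside record")
    lo = max(emg.t0, stamp - cfg.search_halfwidth)
    hi = min(emg.end, stamp + cfg.search_halfwidth)
    win = slice_series(emg, lo, hi)
    env = rms_envelope(win, cfg.envelope_window)
    mu, sd = rest_stats
    mask = env.samples > mu + cfg.onset_k * sd
    runs = _active_runs(mask, win.fs, cfg.merge_span)
    if not runs:
        raise SignalError(f"no EMG activity found around stamp {stamp} s")
    # the segment is the merged activity overlapping the stamp, or failing
    # that the longest one in the search window
    best = None
    for a, b in runs:
        ta, tb = win.t0 + a / win.fs, win.t0 + b / win.fs
        if ta <= stamp <= tb:
            best = (ta, tb)
            break
    if best is None:
        a, b = max(runs, key=lambda r: r[1] - r[0])
        best = (win.t0 + a / win.fs, win.t0 + b / win.fs)
    return CoughCycleSegment(best[0], best[1], cycle_index)


def mean_duration(segments: list[CoughCycleSegment],
                  cfg: SegmentSelectionConfig = SegmentSelectionConfig()) -> float:
    """Mean duration (MD) of the interior segments.

    With ``exclude_first_last`` (the default) the first and last segments
    are dropped for stability before averaging.
    """
    segs = segments
    if cfg.exclude_first_last:
        if len(segments) < 3:
            raise SignalError("need >= 3 segments to exclude first and last")
        segs = segments[1:-1]
    return float(np.mean([s.duration for s in segs]))


def extend_segments(segments: list[CoughCycleSegment], md: float,
                    cfg: SegmentSelectionConfig,
                    record_span: tuple[float, float] | None = None,
                    ) -> list[tuple[float, float]]:
    """Replace each interior segment by a common-duration centered window.

    Each retained segment becomes a window of ``extension_factor * md``
    seconds centered on its middle point ("coughing segment").
    """
    segs = segments[1:-1] if cfg.exclude_first_last else segments
    half = 0.5 * cfg.extension_factor * md
    out = []
    for s in segs:
        w = (s.middle - half, s.middle + half)
        if record_span is not None and not (record_span[0] <= w[0] and
                                            w[1] <= record_span[1]):
            raise SignalError(f"coughing segment {w} clipped at record edge")
        out.append(w)
    return out


def select_resting_segments(rest: TimeSeries, duration: float, n: int,
                            cfg: SegmentSelectionConfig,
                            rest_stats: tuple[float, float] | None = None,
                            ) -> list[tuple[float, float]]:
    """First ``n`` stable equal-duration windows tiled over the rest period.

    A window is stable when its envelope maximum stays below the onset
    threshold — the automated stand-in for visually excluding segments
    with swallowing or inhalation firings.
    """
    if duration > rest.duration:
        raise SignalError(f"requested segment duration {duration} s exceeds "
                          f"rest period of {rest.duration} s")
    if rest_stats is None:
        rest_stats = envelope_stats(rest, (rest.t0, rest.end), cfg)
    mu, sd = rest_stats
    thr = mu + cfg.onset_k * sd
    env = rms_envelope(rest, cfg.envelope_window)
    out = []
    start = rest.t0
    while start + duration <= rest.end + 1e-9 and len(out) < n:
        seg_env = slice_series(env, start, start + duration)
        if float(np.max(seg_env.samples)) < thr:
            out.append((start, start + duration))
        start += duration
    if len(out) < n:
        raise SignalError(f"only {len(out)} stable resting segments found, "
                          f"need {n}")
    return out


def amplitude_spectrum(samples: np.ndarray, fs: float,
                       window: str = "rectangular",
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Single-sided DFT amplitude spectrum of one segment.

    ``A[k] = (2/N) |X[k]|`` for interior bins, ``(1/N) |X[k]|`` at DC and
    (for even N) Nyquist, so a unit sinusoid on the bin grid shows
    amplitude 1.  Rectangular (no) windowing is the default; ``"hann"``
    is available for leakage-sensitive use.
    """
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise SignalError("empty segment")
    if window == "hann":
        x = x * np.hanning(x.size)
    elif window != "rectangular":
        raise SignalError(f"unknown window {window!r}")
    n = x.size
    spec = np.fft.rfft(x)
    amps = np.abs(spec) / n
    amps[1:] *= 2.0
    if n % 2 == 0:
        amps[-1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return freqs, amps


def total_spectral_amplitude(freqs: np.ndarray, amps: np.ndarray,
                             f_lo: float = 40.0, f_hi: float = 500.0) -> float:
    """Sum of amplitude bins with ``f_lo <= f <= f_hi`` (inclusive)."""
    mask = (freqs >= f_lo) & (freqs <= f_hi)
    return float(np.sum(amps[mask]))


def segment_tsa(emg: TimeSeries, window: tuple[float, float],
                band: tuple[float, float] = (40.0, 500.0)) -> float:
    """TSA of one time window of a (preprocessed) EMG trace."""
    seg = slice_series(emg, *window)
    freqs, amps = amplitude_spectrum(seg.samples, seg.fs)
    return total_spectral_amplitude(freqs, amps, *band)


def compare_tsa(rest_tsas: np.ndarray, cough_tsas: np.ndarray,
                alpha: float = 0.05, alternative: str = "greater",
                ) -> TSAComparison:
    """Normality-gated paired comparison of coughing vs resting TSA.

    Shapiro-Wilk on the paired differences decides the test: paired
    t-test when p >= alpha, Wilcoxon signed-rank otherwise.  Default
    alternative is one-sided coughing > resting.
    """
    rest = np.asarray(rest_tsas, dtype=float)
    cough = np.asarray(cough_tsas, dtype=float)
    if rest.size != cough.size:
        raise SignalError("paired samples must have equal length")
    if rest.size < 3:
        raise SignalError("need >= 3 pairs")
    diffs = cough - rest
    if np.allclose(diffs, diffs[0]):
        shapiro_p = 1.0  # Shapiro-Wilk undefined for constant differences
    else:
        shapiro_p = float(stats.shapiro(diffs).pvalue)
    normal = shapiro_p >= alpha
    mean_diff = float(np.mean(diffs))
    if mean_diff > 0:
        direction = "coughing>resting"
    elif mean_diff < 0:
        direction = "resting>coughing"
    else:
        direction = "none"
    if normal:
        if np.allclose(diffs, diffs[0]) and diffs[0] == 0:
            return TSAComparison("paired-t", None, None, direction, normal,
                                 shapiro_p)
        res = stats.ttest_rel(cough, rest, alternative=alternative)
        return TSAComparison("paired-t", float(res.statistic),
                             float(res.pvalue), direction, normal, shapiro_p)
    if np.all(diffs == 0):
        return TSAComparison("wilcoxon-signed-rank", None, None, direction,
                             normal, shapiro_p)
    res = stats.wilcoxon(cough, rest, alternative=alternative)
    return TSAComparison("wilcoxon-signed-rank", float(res.statistic),
                         float(res.pvalue), direction, normal, shapiro_p)


def cough_tsa_analysis(emg: TimeSeries, stamps: np.ndarray,
                       rest_interval: tuple[float, float],
                       sel: SegmentSelectionConfig = SegmentSelectionConfig(),
                       pre: EMGPreprocessConfig = EMGPreprocessConfig(),
                       boundary_channel: TimeSeries | None = None,
                       alpha: float = 0.05,
                       ) -> tuple[TSASummary, TSAComparison, dict]:
    """Full per-channel cough analysis.

    Locates a segment per stamp (on ``boundary_channel`` when given — the
    protocol identifies boundaries on the reference EMG and reuses them
    for the capacitive channel), computes MD, builds coughing and resting
    windows, and compares their TSA distributions.
    """
    filt = preprocess_emg(emg, pre)
    bc = preprocess_emg(boundary_channel, pre) if boundary_channel is not None else filt
    rest_stats = envelope_stats(bc, rest_interval, sel)
    segments = [locate_cough_segment(bc, s, sel, rest_stats, i)
                for i, s in enumerate(np.asarray(stamps, dtype=float))]
    md = mean_duration(segments, sel)
    cough_windows = extend_segments(segments, md, sel,
                                    record_span=(emg.t0, emg.end))
    seg_duration = cough_windows[0][1] - cough_windows[0][0]
    rest_ts = slice_series(filt, *rest_interval)
    rest_windows = select_resting_segments(
        rest_ts, seg_duration, sel.n_rest_segments, sel,
        rest_stats=envelope_stats(filt, rest_interval, sel))
    cough_tsas = np.array([segment_tsa(filt, w, pre.band) for w in cough_windows])
    rest_tsas = np.array([segment_tsa(filt, w, pre.band) for w in rest_windows])
    summary = TSASummary(rest_tsas, cough_tsas, pre.band)
    comparison = compare_tsa(rest_tsas, cough_tsas, alpha=alpha)
    detail = {
        "segments": segments,
        "mean_duration": md,
        "cough_windows": cough_windows,
        "rest_windows": rest_windows,
    }
    return summary, comparison, detail
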