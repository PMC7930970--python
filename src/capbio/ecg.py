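"""R-wave detection and beat-matching metrics for capacitive ECG.

Pipeline: moving-average smoothing (20 ms) -> IIR band-pass (10-20 Hz) ->
finite differencing (10 ms lag), then fixed-threshold peak picking where
the threshold is 80 % of the mean amplitude of five assumed R-waves.
Detected trains are scored against a reference train by pairing beats in
time and comparing the RR interval (RRI) carried by each paired beat: a
test beat is correct only if its RRI agrees with the reference RRI within
±10 ms.  True negatives are not countable events here, so N_TN = 0 by
convention and accuracy is N_TP / (N_TP + N_FN + N_FP).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .signal_core import SignalError, TimeSeries

__all__ = [
    "PreprocessConfig",
    "RPeakTrain",
    "RRISeries",
    "DetectionCounts",
    "DetectionMetrics",
    "preprocess_ecg",
    "estimate_threshold",
    "detect_rpeaks",
    "compute_rri",
    "match_beats",
    "full_detection",
    "detection_metrics",
    "round_display",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Detector front-end parameters.

    ma_window : moving-average window, s (default 20 ms)
    band : band-pass corner frequencies, Hz (default 10-20 Hz)
    diff_interval : differencing lag, s (default 10 ms)
    filter_order : Butterworth order of the band-pass
    """

    ma_window: float = 0.020
    band: tuple[float, float] = (10.0, 20.0)
    diff_interval: float = 0.010
    filter_order: int = 4

    def validate(self, fs: float) -> None:
        lo, hi = self.band
        if not (0 < lo < hi < fs / 2):
            raise SignalError(f"band {self.band} outside (0, fs/2) for fs={fs}")
        if self.ma_window <= 0 or self.diff_interval <= 0:
            raise SignalError("ma_window and diff_interval must be positive")


@dataclass
class RPeakTrain:
    """Ordered R-wave event times (seconds) with detection polarity."""

    times: np.ndarray
    polarity: str = "positive"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise SignalError("R-peak times must be strictly increasing")
        if self.polarity not in ("positive", "negative"):
            raise SignalError(f"polarity must be positive|negative, got {self.polarity}")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class RRISeries:
    """RR intervals, each attached to the time of the latter beat."""

    intervals: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.intervals.size != self.times.size:
            raise SignalError("intervals and times must align")
        if self.intervals.size and np.any(self.intervals <= 0):
            raise SignalError("RR intervals must be positive")

    def __len__(self) -> int:
        return self.intervals.size


@dataclass(frozen=True)
class DetectionCounts:
    """TP/FP/FN/TN beat counts; N_TN is fixed at zero by convention."""

    n_tp: int
    n_fp: int
    n_fn: int
    n_tn: int = 0

    def __post_init__(self) -> None:
        if min(self.n_tp, self.n_fp, self.n_fn) < 0 or self.n_tn != 0:
            raise SignalError("counts must be non-negative with n_tn == 0")


@dataclass(frozen=True)
class DetectionMetrics:
    """Sensitivity, accuracy and positive predictive value in percent.

    A metric whose denominator is zero is undefined and stored as None.
    """

    p_sns: float | None
    p_acc: float | None
    p_ppv: float | None

    def rounded(self, ndigits: int = 1) -> "DetectionMetrics":
        """Display form: half-away-from-zero rounding to ``ndigits``."""
        rd = lambda v: None if v is None else round_display(v, ndigits)
        return DetectionMetrics(rd(self.p_sns), rd(self.p_acc), rd(self.p_ppv))


def round_display(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (the convention used for reported tables)."""
    scale = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * scale + 0.5) / scale, x)


def _centered_moving_average(x: np.ndarray, width: int) -> np.ndarray:
    # edges truncated to the available samples (window shrinks near ends)
    kernel = np.ones(width)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def preprocess_ecg(ts: TimeSeries, cfg: PreprocessConfig = PreprocessConfig()) -> TimeSeries:
    """Smooth, band-pass and difference an ECG trace.

    Output sample ``n`` is ``y[n] - y[n - d]`` where ``y`` is the
    band-passed moving average and ``d = round(diff_interval * fs)``;
    the leading ``d`` samples are zero so length is preserved.  The
    band-pass is zero-phase (forward-backward Butterworth) so extremum
    times stay aligned with the underlying R-waves.
    """
    cfg.validate(ts.fs)
    d = max(1, round(cfg.diff_interval * ts.fs))
    w = max(1, round(cfg.ma_window * ts.fs))
    if len(ts) <= d + w:
        raise SignalError("record too short for the preprocessing chain")
    x = _centered_moving_average(ts.samples, w)
    sos = sps.butter(cfg.filter_order, cfg.band, btype="bandpass", fs=ts.fs,
                     output="sos")
    x = sps.sosfiltfilt(sos, x)
    out = np.zeros_like(x)
    out[d:] = x[d:] - x[:-d]
    return ts.with_samples(out, label=ts.label + "_prep" if ts.label else "prep")


def _candidate_extrema(x: np.ndarray, fs: float, refractory: float):
    """Local extrema of each polarity separated by at least the refractory."""
    dist = max(1, round(refractory * fs))
    pos, _ = sps.find_peaks(x, distance=dist)
    neg, _ = sps.find_peaks(-x, distance=dist)
    return pos, neg


def _dominant_polarity(x: np.ndarray, pos: np.ndarray, neg: np.ndarray,
                       n_waves: int) -> str:
    def top_mean(idx, sign):
        if idx.size == 0:
            return -np.inf
        amps = sign * x[idx]
        return float(np.mean(np.sort(amps)[-min(n_waves, amps.size):]))

    return "positive" if top_mean(pos, 1.0) >= top_mean(neg, -1.0) else "negative"


def estimate_threshold(prep: TimeSeries, n_waves: int = 5, fraction: float = 0.8,
                       mode: str = "largest", seed: int | None = None,
                       refractory: float = 0.25,
                       polarity: str | None = None) -> float:
    """Detection threshold from the mean amplitude of assumed R-waves.

    Candidates are the local extrema of the dominant polarity separated by
    at least the refractory interval.  ``mode="random"`` draws ``n_waves``
    of them without replacement (seedable); ``mode="largest"`` takes the
    ``n_waves`` largest magnitudes and is deterministic.  The threshold is
    ``fraction`` times the mean candidate magnitude, signed by polarity
    (negative threshold means detect signal minima).
    """
    if mode not in ("largest", "random"):
        raise SignalError(f"unknown threshold mode {mode!r}")
    x = prep.samples
    pos, neg = _candidate_extrema(x, prep.fs, refractory)
    if polarity is None:
        polarity = _dominant_polarity(x, pos, neg, n_waves)
    idx = pos if polarity == "positive" else neg
    amps = np.abs(x[idx])
    if amps.size < n_waves:
        raise SignalError(
            f"only {amps.size} candidate extrema found, need {n_waves}")
    if mode == "largest":
        chosen = np.sort(amps)[-n_waves:]
    else:
        rng = np.random.default_rng(seed)
        chosen = rng.choice(amps, size=n_waves, replace=False)
    thr = fraction * float(np.mean(chosen))
    return thr if polarity == "positive" else -thr


def detect_rpeaks(prep: TimeSeries, threshold: float,
                  refractory: float = 0.25) -> RPeakTrain:
    """Fixed-threshold R-wave detection on a preprocessed trace.

    One detection is emitted at the extremum of each maximal run of
    samples beyond the threshold (below it when the threshold is
    negative).  Detections closer than the refractory interval to the
    previous kept one are merged, keeping the larger magnitude.
    """
    x = prep.samples
    if threshold >= 0:
        mask = x > threshold
        pick = np.argmax
    else:
        mask = x < threshold
        pick = np.argmin
    if not mask.any():
        return RPeakTrain(np.empty(0), "positive" if threshold >= 0 else "negative")
    m = mask.astype(np.int8)
    starts = np.flatnonzero(np.diff(np.r_[0, m]) == 1)
    stops = np.flatnonzero(np.diff(np.r_[m, 0]) == -1) + 1
    events = []  # (index, magnitude)
    for a, b in zip(starts, stops):
        i = a + pick(x[a:b])
        events.append((i, abs(x[i])))
    kept: list[tuple[int, float]] = []
    min_gap = refractory * prep.fs
    for i, mag in events:
        if kept and i - kept[-1][0] < min_gap:
            if mag > kept[-1][1]:
                kept[-1] = (i, mag)
        else:
            kept.append((i, mag))
    times = prep.t0 + np.array([i for i, _ in kept]) / prep.fs
    return RPeakTrain(times, "positive" if threshold >= 0 else "negative")


def compute_rri(train: RPeakTrain) -> RRISeries:
    """RR intervals between consecutive beats, attached to the latter beat."""
    t = train.times
    if t.size < 2:
        return RRISeries(np.empty(0), np.empty(0))
    return RRISeries(np.diff(t), t[1:])


def _greedy_pairs(test: np.ndarray, ref: np.ndarray, window: float) -> dict[int, int]:
    """Nearest-time greedy pairing of test to reference beats."""
    cands = []
    for j, t in enumerate(test):
        lo = np.searchsorted(ref, t - window)
        hi = np.searchsorted(ref, t + window, side="right")
        for i in range(lo, hi):
            cands.append((abs(t - ref[i]), j, i))
    cands.sort()
    pair: dict[int, int] = {}
    used_ref: set[int] = set()
    for _, j, i in cands:
        if j not in pair and i not in used_ref:
            pair[j] = i
            used_ref.add(i)
    return pair


def match_beats(test: RPeakTrain, ref: RPeakTrain, tol: float = 0.010,
                pairing_window: float = 0.15) -> DetectionCounts:
    """Score a detected train against a reference train via RRI agreement.

    Beats are first paired greedily by nearest time within
    ``pairing_window``.  Only RRI-bearing beats (those with a predecessor
    in their own train) are counted.  A paired test beat whose RRI agrees
    with the paired reference RRI within ``tol`` is a true positive; any
    other test beat is a false positive, and every reference beat not
    participating in a true positive is a false negative.  N_TN = 0.
    """
    tt, rt = test.times, ref.times
    pair = _greedy_pairs(tt, rt, pairing_window)
    tp = fp = 0
    ref_tp: set[int] = set()
    for j in range(1, tt.size):
        i = pair.get(j)
        ip = pair.get(j - 1)
        if i is None or ip is None or ip >= i or i == 0:
            fp += 1
            continue
        rri_test = tt[j] - tt[j - 1]
        rri_ref = rt[i] - rt[ip]
        if abs(rri_test - rri_ref) <= tol + 1e-12:
            tp += 1
            ref_tp.add(i)
        else:
            fp += 1
    fn = max(rt.size - 1, 0) - len(ref_tp)
    return DetectionCounts(n_tp=tp, n_fp=fp, n_fn=fn)


def full_detection(ts: TimeSeries, cfg: PreprocessConfig = PreprocessConfig(),
                   n_waves: int = 5, fraction: float = 0.8,
                   mode: str = "largest", seed: int | None = None,
                   refractory: float = 0.25,
                   polarity: str | None = None) -> RPeakTrain:
    """Preprocess, estimate the threshold, and detect in one call."""
    prep = preprocess_ecg(ts, cfg)
    thr = estimate_threshold(prep, n_waves=n_waves, fraction=fraction,
                             mode=mode, seed=seed, refractory=refractory,
                             polarity=polarity)
    return detect_rpeaks(prep, thr, refractory=refractory)


def detection_metrics(c: DetectionCounts) -> DetectionMetrics:
    """Sensitivity, accuracy and PPV (percent) from beat counts.

    P_SNS = 100 * TP / (TP + FN)
    P_ACC = 100 * (TP + TN) / (TP + TN + FN + FP)
    P_PPV = 100 * TP / (TP + FP)

    A zero denominator yields None for that metric, never 0.
    """
    def ratio(num: int, den: int) -> float | None:
        return None if den == 0 else 100.0 * num / den

    return DetectionMetrics(
        p_sns=ratio(c.n_tp, c.n_tp + c.n_fn),
        p_acc=ratio(c.n_tp + c.n_tn, c.n_tp + c.n_tn + c.n_fn + c.n_fp),
        p_ppv=ratio(c.n_tp, c.n_tp + c.n_fp),
    )
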