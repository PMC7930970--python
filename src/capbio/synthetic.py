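"""Synthetic paired-biosignal sessions emulating the pillow-electrode protocol.

A simulated session mirrors the laboratory protocol: a rest period of at
least two minutes, then seven "cough twice" cycles with a recorded time
stamp per cycle, then a second rest period.  Four channels are produced:

* ``ECG_ref`` — contact reference ECG built from Gaussian P/Q/R/S/T bumps
  placed on a stochastic RR-interval sequence (LF/HF sinusoidal
  modulation plus white RR jitter);
* ``cECG`` — the capacitive copy: optional first-order high-frequency
  attenuation (emulating stray-capacitance distortion, which can leave
  the T-wave taller than the R-wave), extra baseline wander and noise,
  plus post-cough wander after each cough cycle;
* ``EMG_ref`` / ``cEMG`` — background noise with band-limited (40-500 Hz)
  Gaussian bursts during each cough, the capacitive copy scaled and
  noised.

Ground truth (R-times, burst windows, cycle windows) is carried alongside
so every analysis stage can be scored without real recordings.  All
randomness in a session flows from one seeded generator: equal seeds give
bit-identical sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .ecg import RPeakTrain
from .signal_core import EventAnnotations, SignalError, TimeSeries

__all__ = [
    "ECGSimConfig",
    "CoughSimConfig",
    "SimSession",
    "t_dominant_profile",
    "simulate_rr_series",
    "synth_ecg",
    "synth_cecg",
    "synth_ecg_session",
    "synth_cough_session",
]

#: Gaussian bump layout of one beat: (offset s, width sigma s) per wave.
_WAVE_OFFSETS = {"p": -0.20, "q": -0.040, "r": 0.0, "s": 0.040, "t": 0.30}
_WAVE_WIDTHS = {"p": 0.035, "q": 0.010, "r": 0.012, "s": 0.010, "t": 0.055}


@dataclass(frozen=True)
class ECGSimConfig:
    """Parameters of the synthetic ECG and its capacitive distortion.

    Amplitudes are volts at the electrode (R-waves of roughly 100 uV, as
    the front end is designed for).  ``lf_mod``/``hf_mod`` are
    (frequency Hz, depth s) sinusoidal RR-interval modulations in the
    classic HRV LF and HF bands.  ``wander`` is (RMS amplitude V, corner
    Hz) low-pass-filtered baseline drift.  ``hf_attenuation`` is the
    corner (Hz) of a first-order low-pass applied to the capacitive copy,
    or None for no distortion.
    """

    mean_hr: float = 70.0          # bpm
    rr_sd: float = 0.02            # s
    lf_mod: tuple[float, float] = (0.1, 0.0)
    hf_mod: tuple[float, float] = (0.25, 0.0)
    r_amp: float = 100e-6          # V
    t_amp: float = 30e-6           # V
    p_amp: float = 10e-6           # V
    q_amp: float = -15e-6          # V
    s_amp: float = -20e-6          # V
    wave_widths: dict = field(default_factory=lambda: dict(_WAVE_WIDTHS))
    noise_sd: float = 0.0          # V
    wander: tuple[float, float] = (0.0, 0.3)
    hf_attenuation: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (20.0 < self.mean_hr < 240.0):
            raise SignalError(f"mean_hr must lie in (20, 240), got {self.mean_hr}")
        for name in ("r_amp", "t_amp", "p_amp"):
            if getattr(self, name) < 0:
                raise SignalError(f"{name} must be non-negative")


def t_dominant_profile(**overrides) -> ECGSimConfig:
    """Distorted capacitive-ECG profile with the T-wave exceeding the R-wave.

    Emulates the failure mode seen when stray capacitance attenuates high
    frequencies: a small residual R-wave, a dominant T-wave, noticeable
    noise and wander.  The fixed-threshold detector is expected to degrade
    on sessions generated with this profile.
    """
    cfg = ECGSimConfig(
        r_amp=35e-6, t_amp=110e-6, noise_sd=60e-6,
        wander=(25e-6, 0.4), hf_attenuation=12.0,
    )
    return replace(cfg, **overrides)


@dataclass(frozen=True)
class CoughSimConfig:
    """Layout and intensity of the two-cough protocol.

    Each cycle is two band-limited EMG bursts (``burst_band``, default
    40-500 Hz) of ``burst_duration`` seconds separated by
    ``intra_pair_gap``; cycles are ``inter_cycle_gap`` apart and framed by
    ``pre_rest``/``post_rest`` quiet periods.  ``cemg_scale`` attenuates
    the capacitive EMG copy relative to the reference.
    """

    n_cycles: int = 7
    burst_duration: float = 0.4     # s
    intra_pair_gap: float = 0.4     # s
    inter_cycle_gap: float = 4.0    # s
    burst_band: tuple[float, float] = (40.0, 500.0)
    burst_rms: float = 100e-6       # V
    rest_rms: float = 10e-6         # V
    post_cough_wander: float = 50e-6  # V, injected into cECG after each cycle
    cemg_scale: float = 0.6
    pre_rest: float = 120.0         # s
    post_rest: float = 120.0        # s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cycles < 3:
            raise SignalError("n_cycles must be >= 3 (first/last cycles are "
                              "excluded by the segment-selection rule)")
        if self.inter_cycle_gap <= 0:
            raise SignalError("inter_cycle_gap must be positive: cycles overlap")
        if self.burst_duration <= 0 or self.intra_pair_gap < 0:
            raise SignalError("burst_duration must be positive")


@dataclass
class SimSession:
    """One synthetic recording session with its ground truth."""

    ecg_ref: TimeSeries
    cecg: TimeSeries
    emg_ref: TimeSeries
    cemg: TimeSeries
    truth_rpeaks: RPeakTrain
    truth_burst_windows: list[tuple[float, float]]
    truth_cycle_windows: list[tuple[float, float]]
    annotations: EventAnnotations

    @property
    def channels(self) -> list[TimeSeries]:
        return [self.ecg_ref, self.cecg, self.emg_ref, self.cemg]


def simulate_rr_series(cfg: ECGSimConfig, duration: float,
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """Beat times over ``(0, duration]`` from the modulated RR model.

    RR at beat time t is ``60/mean_hr + lf_depth*sin(2*pi*f_lf*t)
    + hf_depth*sin(2*pi*f_hf*t) + N(0, rr_sd)``; draws below 0.25 s are
    resampled.  The first beat falls one RR interval after record start.
    """
    base = 60.0 / cfg.mean_hr
    if duration <= 3 * base:
        raise SignalError("duration must exceed three mean RR intervals")
    (f_lf, d_lf), (f_hf, d_hf) = cfg.lf_mod, cfg.hf_mod
    if d_lf + d_hf >= base:
        raise SignalError("modulation depths exceed the mean RR interval")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    beats = []
    t = 0.0
    while True:
        rr = (base + d_lf * np.sin(2 * np.pi * f_lf * t)
              + d_hf * np.sin(2 * np.pi * f_hf * t)
              + (rng.normal(0.0, cfg.rr_sd) if cfg.rr_sd > 0 else 0.0))
        while rr <= 0.25:
            rr = (base + d_lf * np.sin(2 * np.pi * f_lf * t)
                  + d_hf * np.sin(2 * np.pi * f_hf * t)
                  + rng.normal(0.0, cfg.rr_sd))
        if t + rr > duration:
            break
        t += rr
        beats.append(t)
    return np.asarray(beats)


def _add_bumps(x: np.ndarray, fs: float, centers: np.ndarray, amp: float,
               width: float) -> None:
    if amp == 0.0:
        return
    half = int(round(5 * width * fs))
    for c in centers:
        ic = int(round(c * fs))
        a, b = max(0, ic - half), min(x.size, ic + half + 1)
        if a >= b:
            continue
        tt = (np.arange(a, b) / fs) - c
        x[a:b] += amp * np.exp(-0.5 * (tt / width) ** 2)


def _lowpass_noise(n: int, fs: float, rms: float, corner: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Baseline-wander generator: white noise low-passed then RMS-scaled."""
    if rms <= 0:
        return np.zeros(n)
    raw = rng.standard_normal(n)
    sos = sps.butter(2, corner, btype="lowpass", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, raw)
    s = np.std(y)
    return y * (rms / s) if s > 0 else np.zeros(n)


def synth_ecg(beat_times: np.ndarray, cfg: ECGSimConfig, duration: float,
              fs: float = 10_000.0,
              rng: np.random.Generator | None = None,
              label: str = "ECG_ref") -> tuple[TimeSeries, RPeakTrain]:
    """Render an ECG trace from beat times; truth R-time = beat time."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = int(round(duration * fs))
    x = np.zeros(n)
    beat_times = np.asarray(beat_times, dtype=float)
    amps = {"p": cfg.p_amp, "q": cfg.q_amp, "r": cfg.r_amp,
            "s": cfg.s_amp, "t": cfg.t_amp}
    for wave, amp in amps.items():
        _add_bumps(x, fs, beat_times + _WAVE_OFFSETS[wave], amp,
                   cfg.wave_widths[wave])
    w_amp, w_corner = cfg.wander
    x += _lowpass_noise(n, fs, w_amp, w_corner, rng)
    if cfg.noise_sd > 0:
        x += rng.normal(0.0, cfg.noise_sd, n)
    return TimeSeries(x, fs, 0.0, label), RPeakTrain(beat_times)


def synth_cecg(ecg: TimeSeries, hf_attenuation: float | None = None,
               noise_sd: float = 0.0, wander: tuple[float, float] = (0.0, 0.3),
               rng: np.random.Generator | None = None,
               seed: int = 0) -> TimeSeries:
    """Capacitive copy of an ECG trace.

    Applies a single-pass first-order low-pass at ``hf_attenuation``
    (amplitude response 1/sqrt(1 + (f/fc)^2), the stray-capacitance
    distortion model) plus extra wander and white noise.  With no
    attenuation and no noise the copy equals the input.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    x = ecg.samples.copy()
    if hf_attenuation is not None:
        sos = sps.butter(1, hf_attenuation, btype="lowpass", fs=ecg.fs,
                         output="sos")
        x = sps.sosfilt(sos, x)
    w_amp, w_corner = wander
    if w_amp > 0:
        x = x + _lowpass_noise(x.size, ecg.fs, w_amp, w_corner, rng)
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, x.size)
    return TimeSeries(x, ecg.fs, ecg.t0, "cECG")


def synth_ecg_session(cfg: ECGSimConfig, duration: float = 120.0,
                      fs: float = 10_000.0,
                      ) -> tuple[TimeSeries, TimeSeries, RPeakTrain]:
    """Resting-period session: (ECG_ref, cECG, truth R-train).

    The reference channel is rendered clean; the capacitive channel
    carries the distortion described by ``cfg`` (``hf_attenuation``,
    ``noise_sd``, ``wander``).  Beats stop half a second before record end
    so no complex is truncated.
    """
    rng = np.random.default_rng(cfg.seed)
    beats = simulate_rr_series(cfg, duration - 0.5, rng=rng)
    clean = replace(cfg, noise_sd=0.0, wander=(0.0, cfg.wander[1]))
    ecg_ref, truth = synth_ecg(beats, clean, duration, fs, rng=rng)
    cecg = synth_cecg(ecg_ref, cfg.hf_attenuation, cfg.noise_sd, cfg.wander,
                      rng=rng)
    return ecg_ref, cecg, truth


def _bandlimited_burst(n: int, fs: float, band: tuple[float, float], rms: float,
                       rng: np.random.Generator) -> np.ndarray:
    raw = rng.standard_normal(n)
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, raw)
    s = np.std(y)
    y = y * (rms / s) if s > 0 else y
    # half-cosine tapers avoid clicks at the burst edges
    ramp = max(2, int(0.02 * fs))
    env = np.ones(n)
    env[:ramp] = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
    env[-ramp:] = env[:ramp][::-1]
    return y * env


def synth_cough_session(ecg_cfg: ECGSimConfig = ECGSimConfig(),
                        cough_cfg: CoughSimConfig = CoughSimConfig(),
                        fs: float = 10_000.0) -> SimSession:
    """Full protocol session: rest, n two-cough cycles, rest.

    One annotation stamp (label ``"two_cough"``) is placed at the midpoint
    of each cycle.  Post-cough baseline wander (a decaying sub-hertz
    oscillation) is injected into the capacitive ECG after each cycle.
    """
    cc = cough_cfg
    rng = np.random.default_rng(cc.seed)
    cycle_len = 2 * cc.burst_duration + cc.intra_pair_gap
    duration = (cc.pre_rest + cc.n_cycles * cycle_len
                + (cc.n_cycles - 1) * cc.inter_cycle_gap + cc.post_rest)
    n = int(round(duration * fs))
    nyq = fs / 2
    if cc.burst_band[1] >= nyq:
        raise SignalError(f"burst band {cc.burst_band} exceeds Nyquist {nyq}")

    # --- EMG channels ---------------------------------------------------
    emg = rng.normal(0.0, cc.rest_rms, n)
    cemg = rng.normal(0.0, cc.rest_rms, n)
    burst_windows: list[tuple[float, float]] = []
    cycle_windows: list[tuple[float, float]] = []
    stamps: list[tuple[float, str]] = []
    t_cursor = cc.pre_rest
    nb = int(round(cc.burst_duration * fs))
    for _ in range(cc.n_cycles):
        cycle_start = t_cursor
        for k in range(2):
            b0 = cycle_start + k * (cc.burst_duration + cc.intra_pair_gap)
            i0 = int(round(b0 * fs))
            burst = _bandlimited_burst(nb, fs, cc.burst_band, cc.burst_rms, rng)
            emg[i0:i0 + nb] += burst
            cemg[i0:i0 + nb] += cc.cemg_scale * burst
            burst_windows.append((b0, b0 + cc.burst_duration))
        cycle_end = cycle_start + cycle_len
        cycle_windows.append((cycle_start, cycle_end))
        stamps.append(((cycle_start + cycle_end) / 2, "two_cough"))
        t_cursor = cycle_end + cc.inter_cycle_gap

    # --- ECG channels ---------------------------------------------------
    ecg_rng = np.random.default_rng(rng.integers(2**31))
    beats = simulate_rr_series(ecg_cfg, duration - 0.5, rng=ecg_rng)
    clean = replace(ecg_cfg, noise_sd=0.0, wander=(0.0, ecg_cfg.wander[1]))
    ecg_ref, truth = synth_ecg(beats, clean, duration, fs, rng=ecg_rng)
    cecg = synth_cecg(ecg_ref, ecg_cfg.hf_attenuation, ecg_cfg.noise_sd,
                      ecg_cfg.wander, rng=ecg_rng)
    cx = cecg.samples
    if cc.post_cough_wander > 0:
        for _, cyc_end in cycle_windows:
            i0 = int(round(cyc_end * fs))
            span = int(round(3.0 * fs))
            i1 = min(n, i0 + span)
            tt = np.arange(i1 - i0) / fs
            phase = rng.uniform(0, 2 * np.pi)
            cx[i0:i1] += (cc.post_cough_wander
                          * np.sin(2 * np.pi * 0.8 * tt + phase)
                          * np.exp(-tt / 1.0))
    return SimSession(
        ecg_ref=ecg_ref,
        cecg=TimeSeries(cx, fs, 0.0, "cECG"),
        emg_ref=TimeSeries(emg, fs, 0.0, "EMG_ref"),
        cemg=TimeSeries(cemg, fs, 0.0, "cEMG"),
        truth_rpeaks=truth,
        truth_burst_windows=burst_windows,
        truth_cycle_windows=cycle_windows,
        annotations=EventAnnotations(stamps),
    )
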