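"""Frequency-domain heart-rate variability from detected R-peak trains.

The RRI tachogram is cubic-interpolated onto a uniform grid (default
8 Hz), its PSD is estimated by Welch's method, and each classic band —
VLF (DC-0.04 Hz), LF (0.04-0.15 Hz), HF (0.15-0.40 Hz), VHF
(0.40-3.00 Hz) — is summarized by the mean PSD over its bins (s^2/Hz).
Agreement between a capacitive and a reference recording is quantified
per band as the relative error rate ``100 * |ref - test| / ref`` percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .ecg import RPeakTrain, compute_rri
from .signal_core import SignalError, TimeSeries

__all__ = [
    "HRVBands",
    "BandPSD",
    "HRVComparison",
    "tachogram",
    "band_psd",
    "psd_error_rate",
]

_DEFAULT_BANDS = {
    "vlf": (0.0, 0.04),
    "lf": (0.04, 0.15),
    "hf": (0.15, 0.40),
    "vhf": (0.40, 3.00),
}


@dataclass(frozen=True)
class HRVBands:
    """Contiguous, non-overlapping frequency bands (Hz)."""

    bands: dict = field(default_factory=lambda: dict(_DEFAULT_BANDS))

    def __post_init__(self) -> None:
        edges = list(self.bands.values())
        for (lo, hi), (lo2, _) in zip(edges, edges[1:]):
            if not (lo < hi and hi == lo2):
                raise SignalError("bands must be increasing and contiguous")

    def names(self) -> list[str]:
        return list(self.bands)


@dataclass(frozen=True)
class BandPSD:
    """Mean PSD per band, s^2/Hz."""

    values: dict  # band name -> float

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def scaled(self, factor: float) -> dict:
        """Values multiplied by ``factor`` (e.g. 1e4 for display)."""
        return {k: v * factor for k, v in self.values.items()}


@dataclass(frozen=True)
class HRVComparison:
    """Per-band relative error rate in percent; None where ref is zero."""

    error_rate: dict  # band name -> float | None


def tachogram(rpeaks: RPeakTrain, resample_hz: float = 8.0) -> TimeSeries:
    """Uniformly resampled RRI series (cubic interpolation).

    Each RRI is attached to the latter beat time; the grid runs from the
    second beat to the last.  The mean is kept in the stored series (it
    is removed only inside spectral estimation).
    """
    if len(rpeaks) < 3:
        raise SignalError("tachogram needs at least 3 beats")
    rri = compute_rri(rpeaks)
    spline = CubicSpline(rri.times, rri.intervals)
    t0, t1 = rri.times[0], rri.times[-1]
    n = int(np.floor((t1 - t0) * resample_hz)) + 1
    grid = t0 + np.arange(n) / resample_hz
    return TimeSeries(spline(grid), resample_hz, float(t0), "rri")


def band_psd(tach: TimeSeries, bands: HRVBands = HRVBands(),
             nperseg: int = 256, overlap: float = 0.5) -> BandPSD:
    """Welch PSD of the tachogram, summarized as mean PSD per band.

    The DC bin is excluded: the VLF band starts at the first nonzero
    frequency bin.  An empty band (no bins) contributes 0.
    """
    x = tach.samples - np.mean(tach.samples)
    nps = min(nperseg, x.size)
    freqs, psd = sps.welch(x, fs=tach.fs, nperseg=nps,
                           noverlap=int(overlap * nps))
    values = {}
    for name, (lo, hi) in bands.bands.items():
        mask = (freqs > lo) & (freqs <= hi) & (freqs > 0)
        values[name] = float(np.mean(psd[mask])) if mask.any() else 0.0
    return BandPSD(values)


def psd_error_rate(ref: BandPSD, test: BandPSD) -> HRVComparison:
    """Per-band relative error: ``100 * |ref - test| / ref`` percent."""
    out = {}
    for name, r in ref.values.items():
        t = test.values[name]
        out[name] = None if r == 0 else 100.0 * abs(r - t) / r
    return HRVComparison(out)
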