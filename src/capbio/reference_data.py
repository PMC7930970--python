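"""Published reference values from the eight-subject pillow-electrode study.

These are the per-subject R-wave detection scores and the per-band HRV
PSD pairs reported by the proof-of-concept experiment the synthetic
pipeline emulates.  They serve as arithmetic inputs (e.g. recomputing
error rates from the printed PSD pairs) and as fixed points for the
metric formulas; they are not outputs of this package.

PSD values are stored as printed strings so the number of reported
decimals — and hence the rounding resolution of each printed value — is
preserved.
"""

from __future__ import annotations

from .ecg import DetectionCounts

__all__ = [
    "DETECTION_TABLE",
    "SUBJECT_E_COUNTS",
    "HRV_PSD_TABLE",
    "HRV_BAND_DECIMALS",
    "printed_decimals",
]

#: Per-subject detection scores: subject -> (P_SNS %, P_ACC %, P_PPV %, N_TP+N_FN).
DETECTION_TABLE: dict[str, tuple[float, float, float, int]] = {
    "A": (100.0, 100.0, 100.0, 163),
    "B": (100.0, 100.0, 100.0, 174),
    "C": (100.0, 100.0, 100.0, 172),
    "D": (92.5, 85.4, 91.8, 133),
    "E": (33.1, 14.3, 20.2, 118),
    "F": (100.0, 100.0, 100.0, 141),
    "G": (100.0, 100.0, 100.0, 122),
    "H": (100.0, 100.0, 100.0, 135),
}

#: Beat counts behind subject E's row (the worst case: T-waves taller than
#: R-waves, most R-waves missed, many T-waves detected instead).
SUBJECT_E_COUNTS = DetectionCounts(n_tp=39, n_fp=154, n_fn=79, n_tn=0)

#: HRV band PSD pairs, x1e-4 s^2/Hz, printed precision preserved:
#: subject -> band -> (reference ECG value, capacitive ECG value,
#: printed error rate %).  Six subjects: those with 100 % detection accuracy.
HRV_PSD_TABLE: dict[str, dict[str, tuple[str, str, str]]] = {
    "A": {"vlf": ("8.9283", "8.9286", "0.004"),
          "lf": ("62.607", "62.615", "0.014"),
          "hf": ("16.102", "16.098", "0.02"),
          "vhf": ("8.539", "8.531", "0.09")},
    "B": {"vlf": ("8.0537", "8.0543", "0.008"),
          "lf": ("54.646", "54.645", "0.002"),
          "hf": ("14.659", "14.657", "0.02"),
          "vhf": ("7.804", "7.811", "0.10")},
    "C": {"vlf": ("8.1603", "8.1624", "0.026"),
          "lf": ("56.258", "56.273", "0.027"),
          "hf": ("15.446", "15.435", "0.08"),
          "vhf": ("7.714", "7.747", "0.43")},
    "F": {"vlf": ("11.9863", "11.986", "0.002"),
          "lf": ("82.874", "82.879", "0.006"),
          "hf": ("23.857", "23.815", "0.17"),
          "vhf": ("11.395", "11.415", "0.17")},
    "G": {"vlf": ("15.3784", "15.378", "0.000"),
          "lf": ("105.311", "105.247", "0.061"),
          "hf": ("29.195", "29.141", "0.19"),
          "vhf": ("15.340", "15.299", "0.27")},
    "H": {"vlf": ("13.2398", "13.244", "0.028"),
          "lf": ("88.198", "88.259", "0.070"),
          "hf": ("23.870", "23.837", "0.14"),
          "vhf": ("12.350", "12.333", "0.14")},
}

#: Decimals of the printed error-rate column per band.
HRV_BAND_DECIMALS = {"vlf": 3, "lf": 3, "hf": 2, "vhf": 2}


def printed_decimals(s: str) -> int:
    """Number of decimal places in a printed numeric string."""
    return len(s.split(".")[1]) if "." in s else 0
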