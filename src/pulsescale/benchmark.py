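"""Benchmark time- and frequency-domain HRV features.

The 15 conventional features computed per 5-min window: nine
time-domain statistics of the RR intervals and their successive
differences, and six spectral features from a Lomb–Scargle periodogram
of the unevenly sampled RR series (VLF 0.0033–0.04 Hz, LF 0.04–0.15
Hz, HF 0.15–0.4 Hz, the standard short-term HRV bands). Lomb–Scargle
avoids the interpolation bias of resampling the beat-indexed series
onto a uniform grid.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.integrate import trapezoid
from scipy.signal import lombscargle

from .containers import InsufficientDataError, RRSeries

logger = logging.getLogger(__name__)

__all__ = [
    "time_domain_features",
    "frequency_domain_features",
    "benchmark_features",
    "FREQUENCY_BANDS",
    "TIME_DOMAIN_NAMES",
    "FREQUENCY_DOMAIN_NAMES",
]

#: (low, high) band edges in Hz
FREQUENCY_BANDS = {
    "vlf": (0.0033, 0.04),
    "lf": (0.04, 0.15),
    "hf": (0.15, 0.4),
}

TIME_DOMAIN_NAMES = (
    "mean_rr",
    "sdnn",
    "cv_rr",
    "rmssd",
    "pnn50",
    "mean_diff",
    "std_abs_diff",
    "mean_abs_diff",
    "norm_mean_abs_diff",
)

FREQUENCY_DOMAIN_NAMES = (
    "hf_power",
    "hf_nu",
    "lf_power",
    "lf_nu",
    "vlf_power",
    "lf_hf",
)


def time_domain_features(rr_window: RRSeries) -> dict[str, float]:
    """Nine time-domain statistics of one RR window.

    mean RR and SDNN in ms, their ratio (coefficient of variation),
    RMSSD, pNN50 (percentage of successive differences strictly above
    50 ms), and four statistics of the first-difference series: mean of
    the signed differences, std and mean of the absolute differences,
    and the latter normalized by the mean RR.
    """
    iv = rr_window.intervals
    if len(iv) < 2:
        raise InsufficientDataError("need at least 2 beats for time-domain features")
    diffs = np.diff(iv)
    abs_diffs = np.abs(diffs)
    mean_rr = float(np.mean(iv))
    sdnn = float(np.std(iv))
    mean_abs_diff = float(np.mean(abs_diffs))
    return {
        "mean_rr": mean_rr,
        "sdnn": sdnn,
        "cv_rr": sdnn / mean_rr,
        "rmssd": float(np.sqrt(np.mean(diffs**2))),
        "pnn50": float(100.0 * np.mean(abs_diffs > 50.0)),
        "mean_diff": float(np.mean(diffs)),
        "std_abs_diff": float(np.std(abs_diffs)),
        "mean_abs_diff": mean_abs_diff,
        "norm_mean_abs_diff": mean_abs_diff / mean_rr,
    }


def frequency_domain_features(
    rr_window: RRSeries, df: float = 0.0005
) -> dict[str, float]:
    """Six spectral features from the Lomb–Scargle periodogram.

    The mean-removed RR intervals against their beat times give band
    powers (trapezoid-integrated periodogram) in the VLF, LF and HF
    bands, the normalized powers nLF = LF/(LF+HF) and nHF = HF/(LF+HF),
    and the LF/HF ratio. A degenerate (constant) window yields zero
    powers and NaN for the normalized features and the ratio.
    """
    iv = rr_window.intervals
    t = rr_window.beat_times
    centered = iv - np.mean(iv)
    freqs = np.arange(FREQUENCY_BANDS["vlf"][0], FREQUENCY_BANDS["hf"][1] + df, df)
    if np.ptp(iv) == 0:
        psd = np.zeros_like(freqs)
    else:
        psd = lombscargle(t, centered, 2 * np.pi * freqs)
        # scale the raw periodogram to a one-sided density in ms^2/Hz
        psd = psd * 4.0 / len(iv)

    powers = {}
    for band, (lo, hi) in FREQUENCY_BANDS.items():
        mask = (freqs >= lo) & (freqs < hi)
        powers[band] = float(trapezoid(psd[mask], freqs[mask]))

    lf, hf, vlf = powers["lf"], powers["hf"], powers["vlf"]
    total = lf + hf
    if total <= 0 or hf == 0:
        logger.warning("degenerate spectrum: normalized powers/ratio undefined")
    return {
        "hf_power": hf,
        "hf_nu": hf / total if total > 0 else float("nan"),
        "lf_power": lf,
        "lf_nu": lf / total if total > 0 else float("nan"),
        "vlf_power": vlf,
        "lf_hf": lf / hf if hf > 0 else float("nan"),
    }


def benchmark_features(rr_window: RRSeries) -> dict[str, float]:
    """The full 15-feature benchmark block (time then frequency domain)."""
    feats = time_domain_features(rr_window)
    feats.update(frequency_domain_features(rr_window))
    return feats
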