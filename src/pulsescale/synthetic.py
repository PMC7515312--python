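"""Synthetic RR / ECG generator with workload-like class structure.

Emulates the statistical structure the analysis assumes of real
heart-beat data: a mean RR level, sinusoidal LF (0.1 Hz, sympathetic +
baroreflex band) and HF (0.25 Hz, respiratory band) modulation,
1/f^beta broadband noise, and optional injected beat artifacts
(out-of-range values and sudden jumps) for exercising the artifact
filters. The "high workload" class shifts the parameters the way
increased mental workload shifts real HRV: shorter mean RR, a raised
LF/HF power ratio, and a flatter noise spectrum.

All outputs are deterministic given (config, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .containers import DataError, ECGSignal, RRSeries

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticConfig",
    "high_workload_config",
    "colored_noise",
    "gen_rr",
    "gen_ecg",
    "inject_artifacts",
    "gen_labeled_dataset",
]

#: modulation frequencies (Hz) of the LF and HF sinusoids
LF_FREQ = 0.1
HF_FREQ = 0.25


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters for one class of synthetic RR series.

    mean_rr : baseline interval, ms (resting adult default 900 ms ~ 67 bpm).
    lf_amp, hf_amp : amplitudes (ms) of the 0.1 Hz and 0.25 Hz
        sinusoidal modulations; defaults give LF/HF power ratio 1.
    noise_sd : standard deviation (ms) of the broadband noise.
    spectral_exponent : beta of the 1/f^beta noise (1 = pink, the
        classic HRV broadband shape).
    artifact_rate : per-beat corruption probability in [0, 0.2).
    """

    mean_rr: float = 900.0
    lf_amp: float = 25.0
    hf_amp: float = 25.0
    noise_sd: float = 20.0
    spectral_exponent: float = 1.0
    artifact_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 280.0 <= self.mean_rr <= 1500.0:
            raise DataError("mean_rr must lie in the physiological range [280, 1500] ms")
        if self.lf_amp < 0 or self.hf_amp < 0 or self.noise_sd < 0:
            raise DataError("amplitudes must be non-negative")
        if not 0.0 <= self.artifact_rate < 0.2:
            raise DataError("artifact_rate must lie in [0, 0.2)")


def high_workload_config(
    base: SyntheticConfig = SyntheticConfig(),
    mean_shift: float = -0.08,
    lf_hf_factor: float = 1.5,
    beta_shift: float = -0.3,
) -> SyntheticConfig:
    """Shift a base config the way high mental workload shifts HRV.

    Mean RR drops by 8%, the LF/HF power ratio rises by a factor of
    1.5 (implemented by scaling the LF amplitude by its square root,
    since sinusoid power goes with amplitude squared), and the noise
    spectrum flattens (beta - 0.3).
    """
    return replace(
        base,
        mean_rr=base.mean_rr * (1 + mean_shift),
        lf_amp=base.lf_amp * float(np.sqrt(lf_hf_factor)),
        spectral_exponent=base.spectral_exponent + beta_shift,
    )


def colored_noise(
    n: int, beta: float, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """1/f^beta noise of length n, standardized to the given sd.

    White Gaussian noise is shaped in the frequency domain with
    amplitude proportional to f^(-beta/2) (DC removed), then rescaled.
    """
    if n < 2 or sd == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-beta / 2.0)
    shaped = np.fft.irfft(spectrum * shape, n)
    scale = shaped.std()
    return shaped / scale * sd if scale > 0 else np.zeros(n)


def gen_rr(
    config: SyntheticConfig, duration: float, seed: int = 0
) -> RRSeries:
    """Generate a synthetic RR series spanning ``duration`` seconds.

    Each interval is the baseline plus the LF and HF sinusoids
    evaluated at the beat time plus one colored-noise sample; beat
    times accumulate from the intervals themselves, so the modulation
    is sampled unevenly exactly as real HRV is.
    """
    if duration < 60:
        raise DataError("duration must be at least 60 s")
    rng = np.random.default_rng(seed)
    n_max = int(np.ceil(duration * 1000.0 / config.mean_rr * 1.5)) + 10
    noise = colored_noise(n_max, config.spectral_exponent, config.noise_sd, rng)

    intervals: list[float] = []
    beat_times: list[float] = []
    t = 0.0
    for i in range(n_max):
        rr = (
            config.mean_rr
            + config.lf_amp * np.sin(2 * np.pi * LF_FREQ * t)
            + config.hf_amp * np.sin(2 * np.pi * HF_FREQ * t)
            + noise[i]
        )
        if rr <= 0:
            raise DataError(
                "configuration produced a non-positive RR interval; "
                "reduce amplitudes or noise_sd"
            )
        t += rr / 1000.0
        intervals.append(rr)
        beat_times.append(t)
        if t >= duration:
            break
    return RRSeries(np.asarray(intervals), np.asarray(beat_times), clean=True)


def _qrs_template(fs: float, sigma: float = 0.010) -> np.ndarray:
    """Symmetric Gaussian R wave (sigma 10 ms), energy inside 4-40 Hz."""
    half = int(round(4 * sigma * fs))
    t = np.arange(-half, half + 1) / fs
    return np.exp(-0.5 * (t / sigma) ** 2)


def gen_ecg(
    rr: RRSeries,
    fs: float = 250.0,
    seed: int = 0,
    noise_sd: float = 0.0,
) -> tuple[ECGSignal, np.ndarray]:
    """Render an RR series as a synthetic ECG trace.

    A QRS-like template is placed at every beat time (including the
    beat that opens the first interval); optional white noise of the
    given standard deviation (template peak height is 1) is added. The
    trace is padded with 0.5 s of lead-in/out so no template is
    truncated at an edge.

    Returns the signal and the ground-truth peak times in seconds.
    """
    if fs < 100:
        raise DataError("sampling rate must be at least 100 Hz")
    rng = np.random.default_rng(seed)
    if len(rr) == 0:
        return ECGSignal(np.zeros(int(fs)), fs=fs), np.empty(0)
    origin = rr.beat_times[0] - rr.intervals[0] / 1000.0
    pad = 0.5
    peak_times = np.concatenate([[origin], rr.beat_times]) - origin + pad
    template = _qrs_template(fs)
    half = (len(template) - 1) // 2
    n = int(np.ceil((peak_times[-1] + pad) * fs)) + 1
    sig = np.zeros(n)
    for pt in peak_times:
        center = int(round(pt * fs))
        lo, hi = center - half, center + half + 1
        tlo, thi = max(0, lo), min(n, hi)
        sig[tlo:thi] += template[tlo - lo : thi - lo]
    if noise_sd > 0:
        sig = sig + rng.standard_normal(n) * noise_sd
    return ECGSignal(sig, fs=fs), peak_times


def inject_artifacts(
    rr: RRSeries, config: SyntheticConfig, seed: int = 0
) -> tuple[RRSeries, np.ndarray]:
    """Corrupt beats at the configured per-beat rate.

    Each corrupted beat gets, with equal probability, an out-of-range
    value (missed-beat-like 1600-2400 ms or spurious-detection-like
    150-270 ms) or a within-range sudden jump (x1.35, tripping the 20%
    rules). Beat timestamps are left untouched so recovery can be
    scored against them. Returns the corrupted series and the boolean
    corruption mask.
    """
    rng = np.random.default_rng(seed)
    iv = rr.intervals.copy()
    mask = rng.random(len(iv)) < config.artifact_rate
    for i in np.nonzero(mask)[0]:
        kind = rng.integers(0, 3)
        if kind == 0:
            iv[i] = rng.uniform(1600.0, 2400.0)
        elif kind == 1:
            iv[i] = rng.uniform(150.0, 270.0)
        else:
            iv[i] = iv[i] * 1.35
    return RRSeries(iv, beat_times=rr.beat_times, clean=False), mask


def gen_labeled_dataset(
    n_per_class: int,
    config_low: SyntheticConfig | None = None,
    config_high: SyntheticConfig | None = None,
    seed: int = 0,
    window_duration: float = 300.0,
):
    """Balanced labeled feature table from the two class generators.

    Generates ``n_per_class`` independent analysis windows per class
    (low workload = 0, high workload = 1), runs the full fused feature
    extraction (benchmark + isod + mPE on composite coarse graining
    and on sliding volatility; 129 features) on each, and returns
    ``(features: DataFrame, labels: ndarray)``. Identical class configs
    are allowed (for null calibration) but logged as degenerate.
    """
    # local import: features builds on every extraction module
    from .features import fused_feature_table

    if config_low is None:
        config_low = SyntheticConfig()
    if config_high is None:
        config_high = high_workload_config(config_low)
    if config_low == config_high:
        logger.warning("class configs are identical: labels carry no signal")

    seeds = np.random.SeedSequence(seed).generate_state(2 * n_per_class)
    windows = []
    labels = []
    for cls, config in ((0, config_low), (1, config_high)):
        for i in range(n_per_class):
            s = int(seeds[cls * n_per_class + i] % (2**31))
            windows.append(gen_rr(config, window_duration, seed=s))
            labels.append(cls)
    table = fused_feature_table(windows)
    return table, np.asarray(labels)
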