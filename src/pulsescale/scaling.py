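"""Series-scaling algorithms for multi-scale entropy analysis.

Five ways of producing a scale-s version of a series x(1..N):

* ``cg`` — coarse graining: mean over non-overlapping blocks of s.
* ``mavg`` — moving average: mean over a sliding window of s.
* ``comp_cg`` — composite coarse graining: the s offset coarse
  grainings (k = 1..s); entropies over members are averaged downstream.
* ``mom`` — second-moment coarse graining: block standard deviation
  (the "volatility" series).
* ``mavg_mom`` — sliding-window standard deviation, the short-series
  counterpart of ``mom``.

All standard deviations use the population convention (divide by s).
Trailing partial blocks of the block methods are discarded, so cg/mom
have length floor(N/s) and the moving variants length N - s + 1.
"""

from __future__ import annotations

import numpy as np

from .containers import InsufficientDataError, ScaledSeries

__all__ = [
    "coarse_grain",
    "moving_average_scale",
    "composite_grains",
    "moment_coarse_grain",
    "moment_moving_average",
    "scale_series",
    "SCALING_METHODS",
]


def _as_array(x) -> np.ndarray:
    arr = np.asarray(getattr(x, "values", getattr(x, "intervals", x)), dtype=float)
    if arr.ndim != 1:
        raise ValueError("expected a 1-D series")
    return arr


def _check_length(n: int, s: int, minimum: int) -> None:
    if s < 1:
        raise ValueError(f"scale must be >= 1, got {s}")
    if n < minimum:
        raise InsufficientDataError(
            f"series of length {n} too short for scale {s} (need >= {minimum})"
        )


def coarse_grain(x, s: int) -> ScaledSeries:
    """Non-overlapping block means: y_s(j) = mean(x[(j-1)s+1 .. js])."""
    arr = _as_array(x)
    _check_length(len(arr), s, s)
    n_blocks = len(arr) // s
    vals = arr[: n_blocks * s].reshape(n_blocks, s).mean(axis=1)
    return ScaledSeries(vals, scale=s, method="cg")


def moving_average_scale(x, s: int) -> ScaledSeries:
    """Sliding-window means of width s; length N - s + 1."""
    arr = _as_array(x)
    _check_length(len(arr), s, s)
    if s == 1:
        return ScaledSeries(arr.copy(), scale=1, method="mavg")
    vals = np.convolve(arr, np.ones(s) / s, mode="valid")
    return ScaledSeries(vals, scale=s, method="mavg")


def composite_grains(x, s: int) -> list[ScaledSeries]:
    """The s offset coarse grainings at scale s.

    Member k (1-based) averages blocks starting at offset k - 1, i.e.
    y_{k,s}(j) = mean(x[(j-1)s+k .. js+k-1]). Member 1 equals the plain
    coarse graining. Entropy over members is aggregated by the
    composite multi-scale entropy rule in the entropy module.
    """
    arr = _as_array(x)
    _check_length(len(arr), s, 2 * s)
    members = []
    for k in range(1, s + 1):
        shifted = arr[k - 1 :]
        n_blocks = len(shifted) // s
        vals = shifted[: n_blocks * s].reshape(n_blocks, s).mean(axis=1)
        members.append(ScaledSeries(vals, scale=s, method="comp_cg", grain_index=k))
    return members


def moment_coarse_grain(x, s: int) -> ScaledSeries:
    """Block standard deviations (population): the volatility series.

    At s = 1 every block holds a single point, so the output is
    identically zero; this degenerate scale is retained for feature-
    count fidelity and handled by the entropy estimators.
    """
    arr = _as_array(x)
    _check_length(len(arr), s, s)
    n_blocks = len(arr) // s
    vals = arr[: n_blocks * s].reshape(n_blocks, s).std(axis=1)
    return ScaledSeries(vals, scale=s, method="mom")


def moment_moving_average(x, s: int) -> ScaledSeries:
    """Sliding-window population standard deviation of width s."""
    arr = _as_array(x)
    _check_length(len(arr), s, s)
    if s == 1:
        return ScaledSeries(np.zeros(len(arr)), scale=1, method="mavg_mom")
    # std via the moving first and second moments
    m1 = np.convolve(arr, np.ones(s) / s, mode="valid")
    m2 = np.convolve(arr**2, np.ones(s) / s, mode="valid")
    var = np.maximum(m2 - m1**2, 0.0)
    return ScaledSeries(np.sqrt(var), scale=s, method="mavg_mom")


SCALING_METHODS = {
    "cg": coarse_grain,
    "mavg": moving_average_scale,
    "comp_cg": composite_grains,
    "mom": moment_coarse_grain,
    "mavg_mom": moment_moving_average,
}


def scale_series(x, s: int, method: str):
    """Dispatch to a scaling algorithm by name.

    Returns a single :class:`ScaledSeries` for all methods except
    ``comp_cg``, which returns the list of its s member series.
    """
    try:
        fn = SCALING_METHODS[method]
    except KeyError:
        raise ValueError(
            f"unknown scaling method {method!r}; choose from {sorted(SCALING_METHODS)}"
        ) from None
    return fn(x, s)
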