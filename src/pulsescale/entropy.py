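"""Entropy estimators and their multi-scale feature blocks.

Three estimators are provided:

* **Sample entropy (SampEn)** — the negative natural log of the
  conditional probability that templates of length m that match within
  a tolerance r (Chebyshev distance) still match at length m + 1.
* **Modified permutation entropy (mPE)** — Shannon entropy of the
  distribution of ordinal motifs of degree 3, with four extra symbols
  for motifs containing tied consecutive values, so plateaus in the
  instantaneous heart rate are represented rather than broken by an
  arbitrary tie rule.
* **Weighted modified permutation entropy (mPE_wt)** — the same motif
  distribution with each occurrence weighted by the variance of its
  embedded vector, folding amplitude information back in.

A multi-scale profile evaluates one estimator on one scaling algorithm
at scales 1..10; for composite coarse graining the per-scale value is
the mean entropy over the s member series (composite multi-scale
entropy, CMSE). All entropies are in nats.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .containers import InsufficientDataError, RRSeries
from .preprocessing import drr
from .scaling import SCALING_METHODS, composite_grains

logger = logging.getLogger(__name__)

__all__ = [
    "EntropyParams",
    "sample_entropy",
    "ordinal_symbolize_modified",
    "modified_pe",
    "weighted_modified_pe",
    "multiscale_profile",
    "entropy_feature_block",
    "ENTROPY_METHODS",
    "DEFAULT_SCALES",
]

DEFAULT_SCALES = tuple(range(1, 11))

#: symbol emitted for an all-equal triplet (outside the printed 10)
ALL_EQUAL_SYMBOL = 11


@dataclass(frozen=True)
class EntropyParams:
    """Estimator parameters.

    m_sampen : SampEn template length (default 2).
    r : SampEn tolerance as a fraction of the unscaled series' standard
        deviation (default 0.2); resolved to absolute units once per
        window and held fixed across scales.
    m_pe : ordinal motif degree; only 3 is supported (the modified
        symbol table is written for triplets).
    lag : ordinal embedding lag λ (default 1).
    """

    m_sampen: int = 2
    r: float = 0.2
    m_pe: int = 3
    lag: int = 1

    def __post_init__(self) -> None:
        if self.m_sampen < 1:
            raise ValueError("m_sampen must be >= 1")
        if self.r <= 0:
            raise ValueError("r must be positive")
        if self.m_pe != 3:
            raise ValueError("only motif degree m_pe=3 is supported")
        if self.lag < 1:
            raise ValueError("lag must be >= 1")


def _series_values(x) -> np.ndarray:
    return np.asarray(
        getattr(x, "values", getattr(x, "intervals", x)), dtype=float
    ).ravel()


def sample_entropy(
    x, params: EntropyParams = EntropyParams(), r_abs: float | None = None
) -> float:
    """Sample entropy, -log(N_{m+1} / N_m), in nats.

    N_m counts template pairs (i < j, self-matches excluded) of length
    m whose Chebyshev distance is strictly below the tolerance; N_{m+1}
    counts the same pairs extended by one sample. Both counts run over
    the N - m templates that admit an extension.

    Parameters
    ----------
    x : array-like or series container
    params : EntropyParams
    r_abs : float, optional
        Absolute tolerance. If omitted, resolved as ``params.r`` times
        the population standard deviation of ``x`` itself.

    Returns
    -------
    float
        SampEn in nats, or NaN (with a warning) when either count is
        zero and the estimate is undefined.
    """
    arr = _series_values(x)
    m = params.m_sampen
    if len(arr) < m + 2:
        raise InsufficientDataError(
            f"series of length {len(arr)} too short for SampEn with m={m}"
        )
    if r_abs is None:
        r_abs = params.r * float(np.std(arr))
    if r_abs < 0:
        raise ValueError("tolerance must be non-negative")

    n_templates = len(arr) - m  # every template has an (m+1)-extension
    dist = np.abs(arr[:, None] - arr[None, :])
    cheb = dist[:n_templates, :n_templates].copy()
    for k in range(1, m):
        np.maximum(cheb, dist[k : k + n_templates, k : k + n_templates], out=cheb)
    iu = np.triu_indices(n_templates, k=1)
    match_m = cheb[iu] < r_abs
    np.maximum(cheb, dist[m : m + n_templates, m : m + n_templates], out=cheb)
    match_m1 = cheb[iu] < r_abs

    n_m = int(match_m.sum())
    n_m1 = int(match_m1.sum())
    if n_m == 0 or n_m1 == 0:
        logger.warning(
            "SampEn undefined: N_m=%d, N_{m+1}=%d (returning NaN)", n_m, n_m1
        )
        return float("nan")
    return float(-np.log(n_m1 / n_m))


def ordinal_symbolize_modified(x, m_pe: int = 3, lag: int = 1) -> np.ndarray:
    """Map each embedded triplet to one of 11 ordinal symbols.

    For a triplet (a, b, c) = (X(i), X(i+λ), X(i+2λ)) the six strict
    rank orderings give symbols 1–6; tied consecutive values give the
    four extra symbols 7–10 (7: a=b<c, 8: a=b>c, 9: a>b=c, 10: a<b=c).
    Two configurations are not covered by those ten rules and are
    resolved by a fixed convention so the map is total: an all-equal
    triplet gets the dedicated symbol 11, and a tie between the outer
    values (a = c, b distinct) is broken as a < c before the strict
    lookup (yielding symbol 2 when b is a peak, 3 when b is a trough).
    """
    if m_pe != 3:
        raise ValueError("only motif degree 3 is supported")
    arr = _series_values(x)
    n_motifs = len(arr) - (m_pe - 1) * lag
    if n_motifs < 1:
        raise InsufficientDataError(
            f"series of length {len(arr)} admits no motif at lag {lag}"
        )
    a = arr[:n_motifs]
    b = arr[lag : lag + n_motifs]
    c = arr[2 * lag : 2 * lag + n_motifs]

    ab_eq = a == b
    bc_eq = b == c
    ac = np.where(a == c, -1, np.sign(a - c))  # outer tie counts as a < c

    symbols = np.select(
        [
            ab_eq & bc_eq,  # 11: all equal
            ab_eq & (b < c),  # 7
            ab_eq & (b > c),  # 8
            bc_eq & (a > b),  # 9
            bc_eq & (a < b),  # 10
            (a < b) & (b < c),  # 1
            (a < b) & (b > c) & (ac < 0),  # 2
            (a > b) & (b < c) & (ac < 0),  # 3
            (a < b) & (b > c) & (ac > 0),  # 4
            (a > b) & (b > c),  # 5
            (a > b) & (b < c) & (ac > 0),  # 6
        ],
        [ALL_EQUAL_SYMBOL, 7, 8, 9, 10, 1, 2, 3, 4, 5, 6],
        default=0,
    )
    assert not np.any(symbols == 0), "symbol table must be total"
    return symbols


def _symbol_probabilities(
    symbols: np.ndarray, weights: np.ndarray | None = None
) -> np.ndarray:
    """Relative (optionally weighted) frequencies over the observed symbols."""
    if weights is None:
        weights = np.ones(len(symbols))
    probs = np.bincount(symbols, weights=weights, minlength=ALL_EQUAL_SYMBOL + 1)[1:]
    total = float(probs.sum())
    if total <= 0:
        raise ValueError("total weight must be positive")
    return probs / total


def modified_pe(x, params: EntropyParams = EntropyParams()) -> float:
    """Modified permutation entropy: -sum p log p over observed motifs (nats).

    Not normalized by the log symbol count; a series dominated by one
    motif (e.g. strictly monotone) scores 0.
    """
    symbols = ordinal_symbolize_modified(x, params.m_pe, params.lag)
    p = _symbol_probabilities(symbols)
    nz = p[p > 0]
    return float(-np.sum(nz * np.log(nz)))


def weighted_modified_pe(x, params: EntropyParams = EntropyParams()) -> float:
    """Variance-weighted modified permutation entropy (nats).

    Each motif occurrence is weighted by the population variance of its
    embedded vector, so flat stretches of the series contribute little.
    On a constant series every weight is zero; the estimator then falls
    back to the unweighted frequencies (and logs a warning), which give
    entropy 0 for the single repeated symbol.
    """
    arr = _series_values(x)
    symbols = ordinal_symbolize_modified(arr, params.m_pe, params.lag)
    lag = params.lag
    n = len(symbols)
    emb = np.stack([arr[:n], arr[lag : lag + n], arr[2 * lag : 2 * lag + n]])
    weights = emb.var(axis=0)
    if weights.sum() <= 0:
        logger.warning("all motif weights are zero; falling back to unweighted mPE")
        p = _symbol_probabilities(symbols)
    else:
        p = _symbol_probabilities(symbols, weights)
    nz = p[p > 0]
    return float(-np.sum(nz * np.log(nz)))


ENTROPY_METHODS = {
    "sampen": sample_entropy,
    "mpe": modified_pe,
    "mpewt": weighted_modified_pe,
}


def multiscale_profile(
    x,
    scaling: str,
    entropy: str,
    params: EntropyParams = EntropyParams(),
    scales: tuple[int, ...] = DEFAULT_SCALES,
) -> np.ndarray:
    """Entropy of the scaled series at each scale.

    For ``comp_cg`` the per-scale value is the mean of the entropies of
    the s composite members (CMSE); for every other scaling it is the
    entropy of the single scaled series. For SampEn the tolerance is
    resolved on the unscaled input and held fixed across scales.
    Unreachable scales (series too short) yield NaN with a warning,
    never a silent zero.
    """
    if scaling not in SCALING_METHODS:
        raise ValueError(f"unknown scaling method {scaling!r}")
    if entropy not in ENTROPY_METHODS:
        raise ValueError(f"unknown entropy method {entropy!r}")
    arr = _series_values(x)
    kwargs = {}
    if entropy == "sampen":
        kwargs["r_abs"] = params.r * float(np.std(arr))
    ent_fn = ENTROPY_METHODS[entropy]

    out = np.full(len(scales), np.nan)
    for pos, s in enumerate(scales):
        try:
            if scaling == "comp_cg":
                members = composite_grains(arr, s)
                vals = [ent_fn(mem.values, params, **kwargs) for mem in members]
                out[pos] = float(np.mean(vals))
            else:
                scaled = SCALING_METHODS[scaling](arr, s)
                out[pos] = ent_fn(scaled.values, params, **kwargs)
        except InsufficientDataError:
            logger.warning("scale %d unreachable for series of length %d", s, len(arr))
    return out


def entropy_feature_block(
    rr_window: RRSeries,
    scaling: str,
    entropy: str,
    params: EntropyParams = EntropyParams(),
    scales: tuple[int, ...] = DEFAULT_SCALES,
) -> dict[str, float]:
    """The 24-feature multi-scale entropy block for one analysis window.

    Ten per-scale entropies for the RR series and ten for the dRR
    series, plus the mean and standard deviation across scales for each
    source. Cross-scale statistics skip NaN (unreachable) scales; a
    profile with more than 3 missing scales is flagged low-quality via
    a warning. Feature names follow
    ``{entropy}_{scaling}_{source}_{s<k>|mean|std}``.
    """
    sources = {"rr": rr_window.intervals, "drr": drr(rr_window).values}
    feats: dict[str, float] = {}
    for source, series in sources.items():
        profile = multiscale_profile(series, scaling, entropy, params, scales)
        n_missing = int(np.isnan(profile).sum())
        if n_missing > 3:
            logger.warning(
                "low-quality block: %d missing scales for %s/%s on %s",
                n_missing,
                entropy,
                scaling,
                source,
            )
        prefix = f"{entropy}_{scaling}_{source}"
        for s, val in zip(scales, profile):
            feats[f"{prefix}_s{s}"] = float(val)
        valid = profile[~np.isnan(profile)]
        feats[f"{prefix}_mean"] = float(np.mean(valid)) if valid.size else float("nan")
        feats[f"{prefix}_std"] = float(np.std(valid)) if valid.size else float("nan")
    return feats
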