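"""Inter-scale ordinal distance (isod) features.

A series is reduced to the distribution of its degree-3 ordinal motifs
(the six strict rank orderings; ties are broken toward "<" so the map
is total). The ordinal distance between two series is a scaled sum of
squared differences of their motif distributions,

    D = (m!/(m!-1)) * sum_j (p_x(pi_j) - p_y(pi_j))^2,

bounded by (m!/(m!-1)) * 2 = 2.4 for m = 3. The isod feature family
compares the moving-average-scaled versions of one heart-beat series
across scales: distances between anchor scales sx = 1..3 and all
sy = 1..10 (unordered pairs deduplicated), plus mean, standard
deviation and mean first difference of each anchor's distance profile,
computed for both the RR and the dRR series — 66 features in total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .containers import InsufficientDataError, RRSeries
from .entropy import EntropyParams
from .preprocessing import drr
from .scaling import moving_average_scale

logger = logging.getLogger(__name__)

__all__ = [
    "OrdinalDistribution",
    "pattern_distribution",
    "ordinal_distance",
    "isod_features",
    "ISOD_ANCHOR_SCALES",
    "ISOD_SCALES",
    "isod_pairs",
]

ISOD_ANCHOR_SCALES = (1, 2, 3)
ISOD_SCALES = tuple(range(1, 11))


@dataclass(frozen=True)
class OrdinalDistribution:
    """Relative frequencies over the m! = 6 strict ordinal motifs."""

    probs: np.ndarray
    m: int = 3
    lag: int = 1
    source: str | None = None
    scale: int | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", p)
        if p.shape != (6,):
            raise ValueError("expected 6 motif frequencies")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("frequencies must be non-negative and sum to 1")


def pattern_distribution(
    x, m: int = 3, lag: int = 1, source: str | None = None, scale: int | None = None
) -> OrdinalDistribution:
    """Motif distribution over the six strict orderings of (a, b, c).

    Ties between compared values are broken toward "<" before lookup,
    so every triplet maps to exactly one motif. Motif numbering follows
    the modified-PE table: 1: a<b<c, 2: a<b, b>c, a<c, 3: a>b, b<c,
    a<c, 4: a<b, b>c, a>c, 5: a>b>c, 6: a>b, b<c, a>c.
    """
    arr = np.asarray(getattr(x, "values", getattr(x, "intervals", x)), dtype=float)
    n_motifs = len(arr) - (m - 1) * lag
    if n_motifs < 1:
        raise InsufficientDataError(
            f"series of length {len(arr)} admits no motif of degree {m} at lag {lag}"
        )
    a = arr[:n_motifs]
    b = arr[lag : lag + n_motifs]
    c = arr[2 * lag : 2 * lag + n_motifs]
    # tie -> "<": "a below b" holds whenever a <= b
    ab = a <= b
    bc = b <= c
    ac = a <= c
    motif = np.select(
        [
            ab & bc,  # 1 (implies ac under tie-breaking)
            ab & ~bc & ac,  # 2
            ~ab & bc & ac,  # 3
            ab & ~bc & ~ac,  # 4
            ~ab & ~bc,  # 5
            ~ab & bc & ~ac,  # 6
        ],
        [1, 2, 3, 4, 5, 6],
        default=0,
    )
    counts = np.bincount(motif, minlength=7)[1:]
    return OrdinalDistribution(
        counts / counts.sum(), m=m, lag=lag, source=source, scale=scale
    )


def ordinal_distance(P: OrdinalDistribution, Q: OrdinalDistribution) -> float:
    """Scaled squared-difference distance between two motif distributions.

    Symmetric and zero iff the distributions coincide; bounded by 2.4
    for degree-3 motifs. Not a metric (no triangle inequality is
    claimed).
    """
    if P.m != Q.m or P.lag != Q.lag:
        raise ValueError("distributions must share motif degree and lag")
    m_fact = 6  # m! for m = 3
    return float(m_fact / (m_fact - 1) * np.sum((P.probs - Q.probs) ** 2))


def isod_pairs(
    anchors: tuple[int, ...] = ISOD_ANCHOR_SCALES,
    scales: tuple[int, ...] = ISOD_SCALES,
) -> list[tuple[int, int]]:
    """Deduplicated (sx, sy) scale pairs of the isod block.

    All pairs with sx an anchor, sy any scale, sx != sy; when both ends
    are anchors the unordered pair appears once (sx < sy). For anchors
    {1,2,3} and scales 1..10 this gives 9 + 8 + 7 = 24 pairs.
    """
    pairs = []
    for sx in anchors:
        for sy in scales:
            if sy == sx or (sy in anchors and sy < sx):
                continue
            pairs.append((sx, sy))
    return pairs


def isod_features(
    rr_window: RRSeries,
    params: EntropyParams = EntropyParams(),
) -> dict[str, float]:
    """The 66-feature inter-scale ordinal distance block for one window.

    For each source series (RR and dRR): moving-average scaling at
    scales 1..10, motif distribution of each scaled series, the 24
    deduplicated pairwise distances, and per-anchor statistics (mean,
    std, mean first difference of the distance profile over ascending
    sy). Unreachable scales yield NaN entries and a flagged block.
    Names: ``isod_{source}_s{sx}_s{sy}`` and
    ``isod_{source}_s{sx}_{mean|std|mdiff}``.
    """
    sources = {"rr": rr_window.intervals, "drr": drr(rr_window).values}
    feats: dict[str, float] = {}
    for source, series in sources.items():
        dists: dict[int, OrdinalDistribution | None] = {}
        for s in ISOD_SCALES:
            try:
                scaled = moving_average_scale(series, s)
                dists[s] = pattern_distribution(
                    scaled.values, params.m_pe, params.lag, source=source, scale=s
                )
            except InsufficientDataError:
                logger.warning("isod: scale %d unreachable on %s", s, source)
                dists[s] = None

        def dist(sx: int, sy: int) -> float:
            if dists[sx] is None or dists[sy] is None:
                return float("nan")
            return ordinal_distance(dists[sx], dists[sy])

        for sx, sy in isod_pairs():
            feats[f"isod_{source}_s{sx}_s{sy}"] = dist(sx, sy)
        for sx in ISOD_ANCHOR_SCALES:
            profile = np.array([dist(sx, sy) for sy in ISOD_SCALES if sy != sx])
            valid = profile[~np.isnan(profile)]
            prefix = f"isod_{source}_s{sx}"
            feats[f"{prefix}_mean"] = float(np.mean(valid)) if valid.size else float("nan")
            feats[f"{prefix}_std"] = float(np.std(valid)) if valid.size else float("nan")
            diffs = np.diff(profile)
            diffs = diffs[~np.isnan(diffs)]
            feats[f"{prefix}_mdiff"] = float(np.mean(diffs)) if diffs.size else float("nan")
    return feats
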