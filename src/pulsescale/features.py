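"""Feature extraction as scikit-learn transformers.

Each transformer maps a list of clean RR windows to a named feature
block (a DataFrame); they are stateless (fit is a no-op) and compose
with sklearn pipelines and FeatureUnion. ``fused_feature_table``
assembles the study's fused set in its canonical column order:
benchmark (15) + isod (66) + mPE on composite coarse graining (24) +
mPE on sliding volatility (24) = 129 features.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .benchmark import benchmark_features
from .containers import RRSeries
from .entropy import EntropyParams, entropy_feature_block
from .ordinal import isod_features

__all__ = [
    "BenchmarkFeatures",
    "EntropyFeatures",
    "IsodFeatures",
    "fused_feature_table",
]


class _BlockTransformer(TransformerMixin, BaseEstimator):
    """Base for row-per-window feature blocks."""

    def fit(self, X, y=None):
        if len(X) == 0:
            raise ValueError("need at least one window")
        self.n_features_in_ = 1  # windows, not columns
        self.feature_names_out_ = np.asarray(
            list(self._extract(X[0]).keys()), dtype=object
        )
        return self

    def transform(self, X) -> pd.DataFrame:
        rows = [self._extract(w) for w in X]
        df = pd.DataFrame(rows)
        if hasattr(self, "feature_names_out_"):
            df = df[list(self.feature_names_out_)]
        return df

    def get_feature_names_out(self, input_features=None):
        return self.feature_names_out_

    def _extract(self, window: RRSeries) -> dict[str, float]:
        raise NotImplementedError


class BenchmarkFeatures(_BlockTransformer):
    """The 15 conventional time- and frequency-domain HRV features."""

    def _extract(self, window: RRSeries) -> dict[str, float]:
        return benchmark_features(window)


class IsodFeatures(_BlockTransformer):
    """The 66 inter-scale ordinal distance features.

    Parameters
    ----------
    lag : ordinal embedding lag (default 1).
    """

    def __init__(self, lag: int = 1):
        self.lag = lag

    def _extract(self, window: RRSeries) -> dict[str, float]:
        return isod_features(window, EntropyParams(lag=self.lag))


class EntropyFeatures(_BlockTransformer):
    """One 24-feature multi-scale entropy block.

    Parameters
    ----------
    scaling : {'cg', 'mavg', 'comp_cg', 'mom', 'mavg_mom'}
    entropy : {'sampen', 'mpe', 'mpewt'}
    m_sampen, r, lag : estimator parameters (see EntropyParams).
    """

    def __init__(
        self,
        scaling: str = "comp_cg",
        entropy: str = "mpe",
        m_sampen: int = 2,
        r: float = 0.2,
        lag: int = 1,
    ):
        self.scaling = scaling
        self.entropy = entropy
        self.m_sampen = m_sampen
        self.r = r
        self.lag = lag

    def _params(self) -> EntropyParams:
        return EntropyParams(m_sampen=self.m_sampen, r=self.r, lag=self.lag)

    def _extract(self, window: RRSeries) -> dict[str, float]:
        return entropy_feature_block(window, self.scaling, self.entropy, self._params())


def fused_feature_table(windows: list[RRSeries]) -> pd.DataFrame:
    """Extract the fused 129-feature table from a list of windows.

    Column order: benchmark (15), isod (66), mPE + comp_cg (24),
    mPE + mavg_mom (24).
    """
    blocks = [
        BenchmarkFeatures(),
        IsodFeatures(),
        EntropyFeatures(scaling="comp_cg", entropy="mpe"),
        EntropyFeatures(scaling="mavg_mom", entropy="mpe"),
    ]
    frames = [b.fit(windows).transform(windows) for b in blocks]
    names = [n for f in frames for n in f.columns]
    if len(set(names)) != len(names):
        raise ValueError("feature name collision across blocks")
    return pd.concat(frames, axis=1)
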