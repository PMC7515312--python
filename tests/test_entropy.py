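"""Entropy estimators vs independent oracles, limits and invariances."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import pulsescale as ps
from pulsescale.containers import InsufficientDataError
from pulsescale.entropy import DEFAULT_SCALES

from _oracles import mpe_oracle, sampen_oracle, symbolize_oracle, wmpe_oracle


class TestSampleEntropy:
    def test_constant_series_zero(self):
        assert ps.sample_entropy(np.full(60, 7.0), r_abs=0.5) == 0.0

    def test_periodic_series_zero(self):
        """[1,2] repeated: every m-match extends to an (m+1)-match."""
        x = np.tile([1.0, 2.0], 100)
        assert ps.sample_entropy(x, r_abs=0.5 * np.std(x)) == 0.0

    @pytest.mark.parametrize("n", [100, 500])
    def test_matches_definitional_oracle(self, n, rng):
        """Exact agreement with explicit O(N^2) pair counting."""
        for _ in range(3):
            x = rng.uniform(size=n)
            r = 0.2 * float(np.std(x))
            got = ps.sample_entropy(x, r_abs=r)
            want = sampen_oracle(x, m=2, r=r)
            assert got == pytest.approx(want, abs=1e-12)

    def test_undefined_returns_nan(self):
        # widely spaced values, tiny tolerance: no template matches
        x = np.array([0.0, 10.0, 25.0, 47.0, 90.0, 160.0, 250.0])
        assert np.isnan(ps.sample_entropy(x, r_abs=1e-9))

    def test_too_short_raises(self):
        with pytest.raises(InsufficientDataError):
            ps.sample_entropy(np.array([1.0, 2.0, 3.0]))


class TestOrdinalSymbols:
    def test_printed_table_example(self):
        np.testing.assert_array_equal(
            ps.ordinal_symbolize_modified([4, 7, 9, 10, 6, 11, 3]), [1, 1, 4, 3, 4]
        )

    def test_monotone_and_tie_rows(self):
        assert set(ps.ordinal_symbolize_modified(np.arange(20.0))) == {1}
        np.testing.assert_array_equal(ps.ordinal_symbolize_modified([1, 1, 2]), [7])
        np.testing.assert_array_equal(ps.ordinal_symbolize_modified([2, 2, 1]), [8])
        np.testing.assert_array_equal(ps.ordinal_symbolize_modified([3, 1, 1]), [9])
        np.testing.assert_array_equal(ps.ordinal_symbolize_modified([1, 3, 3]), [10])
        np.testing.assert_array_equal(ps.ordinal_symbolize_modified([5, 5, 5]), [11])
        # outer tie resolved as "<"
        np.testing.assert_array_equal(ps.ordinal_symbolize_modified([2, 5, 2]), [2])
        np.testing.assert_array_equal(ps.ordinal_symbolize_modified([5, 2, 5]), [3])

    @given(seed=st.integers(0, 2**16), lag=st.integers(1, 3))
    def test_total_and_matches_oracle(self, seed, lag):
        """Every real triplet maps to exactly one symbol, agreeing with the
        exhaustive comparison-chain oracle (ties included)."""
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 5, size=50).astype(float)  # many ties
        got = ps.ordinal_symbolize_modified(x, lag=lag)
        assert got.tolist() == symbolize_oracle(x, lag=lag)


class TestModifiedPE:
    def test_monotone_zero(self):
        assert ps.modified_pe(np.arange(50.0)) == 0.0

    def test_hand_example(self):
        assert ps.modified_pe([4, 7, 9, 10, 6, 11, 3]) == pytest.approx(1.0549, abs=5e-5)

    def test_uniform_noise_approaches_log6(self, rng):
        x = rng.uniform(size=5000)
        assert ps.modified_pe(x) == pytest.approx(np.log(6), rel=0.05)

    @given(seed=st.integers(0, 2**16))
    def test_matches_counting_oracle(self, seed):
        x = np.random.default_rng(seed).normal(size=120)
        assert ps.modified_pe(x) == pytest.approx(mpe_oracle(x), abs=1e-12)

    @given(seed=st.integers(0, 2**16))
    def test_invariant_under_monotone_transform(self, seed):
        """Symbols depend only on rank order."""
        x = np.random.default_rng(seed).normal(size=150)
        y = np.exp(2.0 * x) + 5.0
        assert ps.modified_pe(x) == pytest.approx(ps.modified_pe(y), abs=1e-12)

    def test_bounded_by_log_symbol_count(self, rng):
        x = rng.integers(0, 3, size=400).astype(float)
        val = ps.modified_pe(x)
        assert 0 <= val <= np.log(11)


class TestWeightedModifiedPE:
    def test_monotone_zero(self):
        assert ps.weighted_modified_pe(np.arange(30.0)) == 0.0

    def test_equal_variance_vectors_reduce_to_unweighted(self):
        # alternating series: every embedded triplet has the same variance
        x = np.tile([0.0, 1.0], 40)
        assert ps.weighted_modified_pe(x) == pytest.approx(ps.modified_pe(x), abs=1e-12)

    def test_hand_example_matches_oracle(self):
        x = [4, 7, 9, 10, 6, 11, 3]
        assert ps.weighted_modified_pe(x) == pytest.approx(wmpe_oracle(x), abs=1e-12)

    @given(seed=st.integers(0, 2**16))
    def test_matches_weighted_oracle(self, seed):
        x = np.random.default_rng(seed).normal(size=120)
        assert ps.weighted_modified_pe(x) == pytest.approx(wmpe_oracle(x), abs=1e-12)

    def test_constant_series_falls_back(self):
        assert ps.weighted_modified_pe(np.full(30, 2.0)) == 0.0


class TestMultiscaleProfile:
    def test_composite_at_scale_one_equals_plain_entropy(self, rng):
        x = rng.normal(size=400)
        prof = ps.multiscale_profile(x, "comp_cg", "mpe")
        assert prof[0] == pytest.approx(ps.modified_pe(x), abs=1e-12)

    def test_cmse_is_mean_of_member_entropies(self, rng):
        x = rng.normal(size=300)
        prof = ps.multiscale_profile(x, "comp_cg", "mpe")
        for pos, s in enumerate(DEFAULT_SCALES):
            members = ps.composite_grains(x, s)
            want = np.mean([ps.modified_pe(m.values) for m in members])
            assert prof[pos] == pytest.approx(want, abs=1e-12)

    def test_constant_series_mpe_profile_zero(self):
        x = np.full(200, 800.0)
        for scaling in ("cg", "mavg", "comp_cg", "mom", "mavg_mom"):
            np.testing.assert_array_equal(
                ps.multiscale_profile(x, scaling, "mpe"), np.zeros(10)
            )

    def test_white_noise_sampen_profile_decreases(self):
        """Coarse-graining white noise lowers SampEn (classic multi-scale
        signature); majority vote over 20 seeds."""
        from scipy.stats import spearmanr

        wins = 0
        for seed in range(20):
            x = np.random.default_rng(seed).standard_normal(3000)
            prof = ps.multiscale_profile(x, "cg", "sampen")
            rho = spearmanr(np.arange(1, 11), prof).statistic
            wins += rho < 0
        assert wins > 10

    def test_short_series_yields_nan_sentinels(self):
        x = np.arange(12.0)
        prof = ps.multiscale_profile(x, "comp_cg", "mpe")
        assert np.isnan(prof[-1])  # scale 10 needs 2s = 20 points
        assert not np.isnan(prof[0])


class TestEntropyFeatureBlock:
    def test_block_shape_and_names(self, clean_window):
        block = ps.entropy_feature_block(clean_window, "comp_cg", "mpe")
        assert len(block) == 24
        assert sum(k.endswith("_mean") for k in block) == 2
        assert sum(k.endswith("_std") for k in block) == 2
        assert all(k.startswith("mpe_comp_cg_") for k in block)

    def test_cross_scale_mean_is_arithmetic_mean(self, clean_window):
        block = ps.entropy_feature_block(clean_window, "mavg", "mpe")
        per_scale = [block[f"mpe_mavg_rr_s{s}"] for s in range(1, 11)]
        assert block["mpe_mavg_rr_mean"] == pytest.approx(np.mean(per_scale))

    def test_constant_window_drr_features_zero(self):
        rr = ps.RRSeries(np.full(120, 800.0), clean=True)
        block = ps.entropy_feature_block(rr, "mavg", "mpe")
        for s in range(1, 11):
            assert block[f"mpe_mavg_drr_s{s}"] == 0.0
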