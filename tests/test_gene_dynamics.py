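import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from methyldyn import (
    AnalysisConfig,
    classify_gains,
    equal_increment_bound,
    extrapolate_linear,
    topn_overlap_association,
)
from methyldyn.gene_dynamics import montecarlo_association_null


class TestClassifyGains:
    def test_inclusive_alt_boundary(self):
        ref = pd.Series({"g1": 0.05, "g2": 0.10, "g3": 0.05})
        alt = pd.Series({"g1": 0.10, "g2": 0.90, "g3": 0.09})
        out = classify_gains(ref, alt)
        assert bool(out.loc["g1", "gained"])  # alt == 0.1 counts (>=)
        assert not bool(out.loc["g2", "gained"])  # ref must be strictly < 0.1
        assert not bool(out.loc["g3", "gained"])

    def test_undefined_levels_excluded(self):
        ref = pd.Series({"g1": 0.0, "g2": np.nan})
        alt = pd.Series({"g1": 0.5, "g2": 0.5})
        out = classify_gains(ref, alt)
        assert list(out.index) == ["g1"]

    def test_monotone_in_gain_threshold(self):
        rng = np.random.default_rng(0)
        ref = pd.Series(rng.uniform(0, 0.2, 500))
        alt = pd.Series(rng.uniform(0, 0.5, 500))
        counts = [
            classify_gains(ref, alt, AnalysisConfig(gain_high=t))["gained"].sum()
            for t in (0.05, 0.1, 0.2, 0.4)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_planted_gains_recovered(self, default_sim):
        from methyldyn import feature_levels

        samples, truth = default_sim
        genes = truth.genes()
        tab = feature_levels([samples["WT"], samples["9G-1"]], genes, "CHG")
        out = classify_gains(tab["WT"], tab["9G-1"])
        gained = set(out.index[out["gained"]])
        planted = set(truth.seeded_genes)
        # every seeded gene whose 9G spread pushed its gene-wide CHG level
        # past the threshold must be recovered, and nothing else
        expect = {
            g for g in planted
            if truth.spread_d[("9G-1", g)] / next(
                f.length for f in genes if f.feature_id == g
            ) * truth.config.spread_plateau_chg >= 0.1 * 1.15
        }
        assert expect <= gained
        assert gained <= planted


class TestAssociation:
    def test_expected_normalization_and_closed_form(self):
        rng = np.random.default_rng(1)
        idx = [f"g{i}" for i in range(20_000)]
        tables = {
            f"L{i}": pd.Series(rng.normal(size=20_000), index=idx) for i in range(4)
        }
        at = topn_overlap_association(tables, top_n=1000)
        assert at["expected"].sum() == pytest.approx(20_000)
        # expected(4) = G * p^4 with p = 0.05
        assert at.loc[4, "expected"] == pytest.approx(20_000 * 0.05**4)

    def test_expected_matches_montecarlo(self):
        rng = np.random.default_rng(2)
        G, L, n, draws = 2000, 4, 100, 200
        mc = montecarlo_association_null(G, L, n, draws, rng)
        idx = [f"g{i}" for i in range(G)]
        tables = {
            f"L{i}": pd.Series(rng.normal(size=G), index=idx) for i in range(L)
        }
        at = topn_overlap_association(tables, top_n=n)
        p = n / G
        for k in range(L + 1):
            var_per_draw = G * at["expected"][k] / G * (1 - at["expected"][k] / G)
            sigma = max(np.sqrt(var_per_draw / draws), 1e-9)
            assert abs(mc[k] - at["expected"][k]) < max(3 * sigma, 0.5)

    def test_independent_rankings_near_null(self):
        rng = np.random.default_rng(3)
        idx = [f"g{i}" for i in range(20_000)]
        tables = {
            f"L{i}": pd.Series(rng.normal(size=20_000), index=idx) for i in range(4)
        }
        at = topn_overlap_association(tables, top_n=1000)
        for k in range(5):
            e = at["expected"][k]
            sigma = np.sqrt(max(e * (1 - e / 20_000), 1e-9))
            assert abs(at["observed"][k] - e) <= 3 * sigma + 1

    def test_identical_rankings_maximal_association(self):
        rng = np.random.default_rng(4)
        idx = [f"g{i}" for i in range(5000)]
        base = pd.Series(rng.normal(size=5000), index=idx)
        at = topn_overlap_association({f"L{i}": base for i in range(4)}, top_n=1000)
        assert at["observed"][4] == 1000
        assert at["observed"][1] == at["observed"][2] == at["observed"][3] == 0

    def test_observed_sums_to_universe(self):
        rng = np.random.default_rng(5)
        idx = [f"g{i}" for i in range(1000)]
        tables = {
            f"L{i}": pd.Series(rng.normal(size=1000), index=idx) for i in range(3)
        }
        at = topn_overlap_association(tables, top_n=50)
        assert at["observed"].sum() == 1000

    def test_topn_larger_than_universe_errors(self):
        idx = ["a", "b"]
        tables = {"L1": pd.Series([1, 2], index=idx),
                  "L2": pd.Series([2, 1], index=idx)}
        with pytest.raises(ValueError):
            topn_overlap_association(tables, top_n=5)


class TestExtrapolation:
    def test_printed_arithmetic(self):
        assert extrapolate_linear(0.02, 0.04) == pytest.approx(0.18)

    def test_no_change_extrapolates_to_no_change(self):
        assert extrapolate_linear(0.3, 0.3) == pytest.approx(0.3)

    @given(
        st.floats(0, 1), st.floats(-0.1, 0.1), st.integers(1, 12)
    )
    @settings(deadline=None, max_examples=50)
    def test_exact_on_arithmetic_progressions(self, l1, d, factor):
        l2 = l1 + d
        target = l1 + (factor + 1) * d  # generation 2 + factor more steps
        assert extrapolate_linear(l1, l2, factor) == pytest.approx(target, abs=1e-9)

    def test_vectorized(self):
        a = np.array([0.0, 0.02])
        b = np.array([0.1, 0.04])
        assert np.allclose(extrapolate_linear(a, b), [0.8, 0.18])


class TestEqualIncrementBound:
    def test_eight_steps_gives_one_eighth(self):
        assert equal_increment_bound(8) == 0.125

    def test_single_step(self):
        assert equal_increment_bound(1) == 1.0

    def test_saturating_schedules_respect_bound(self):
        # any non-increasing increment schedule puts >= 1/n of the total
        # increase into the first step
        rng = np.random.default_rng(6)
        for _ in range(200):
            n = int(rng.integers(1, 10))
            inc = np.sort(rng.uniform(0.01, 1.0, n))[::-1]
            first_share = inc[0] / inc.sum()
            assert first_share >= equal_increment_bound(n) - 1e-12
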