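import numpy as np
import pandas as pd
import pytest

from methyldyn import (
    DMR,
    AnalysisConfig,
    FeatureAnnotation,
    MethylomeSample,
    call_dmrs,
    merge_condmrs,
    subtract_dmrs,
    window_levels,
)


def _sample(rows, **kw):
    df = pd.DataFrame(rows, columns=list(MethylomeSample.COLUMNS))
    return MethylomeSample(df, **kw)


def _flat(level, total=20, span=300, context="CG", step=10):
    return [
        ("chr1", p, "+", context, int(round(level * total)), total)
        for p in range(0, span, step)
    ]


class TestWindowLevels:
    def test_zero_anchored_tiling(self):
        s = _sample(_flat(0.5, span=250))
        w = window_levels(s, "CG")
        assert list(w["start"]) == [0, 100, 200]

    def test_level_and_total(self):
        s = _sample([("chr1", 10, "+", "CG", 10, 20), ("chr1", 60, "-", "CG", 2, 20)])
        w = window_levels(s, "CG")
        assert w["level"].iloc[0] == pytest.approx(0.3)
        assert w["total_obs"].iloc[0] == 40

    def test_empty_window_absent(self):
        s = _sample([("chr1", 250, "+", "CG", 1, 2)])
        w = window_levels(s, "CG")
        assert list(w["start"]) == [200]


class TestCallDmrs:
    def test_cg_threshold_inclusive(self):
        a = _sample(_flat(0.80))
        b = _sample(_flat(0.30))
        dmrs = call_dmrs(a, b, "CG")
        assert len(dmrs) == 3
        assert all(d.direction == "hypo" for d in dmrs)
        assert dmrs[0].delta == pytest.approx(-0.5)

    def test_chg_below_threshold_not_called(self):
        a = _sample(_flat(0.0, total=100, context="CHG"))
        b = _sample(_flat(0.29, total=100, context="CHG"))
        assert call_dmrs(a, b, "CHG") == []
        b2 = _sample(_flat(0.30, total=100, context="CHG"))
        assert len(call_dmrs(a, b2, "CHG")) == 3

    def test_eligibility_requires_min_obs_in_both(self):
        a = _sample(_flat(0.9, total=1))  # 30 obs/window in a, but...
        b = _sample(_flat(0.0, total=1, span=100))
        cfg = AnalysisConfig(min_obs=20)
        # window 0 has 10 obs in each sample -> ineligible
        assert call_dmrs(a, b, "CG", cfg) == []

    def test_chh_needs_explicit_delta(self):
        a = _sample(_flat(0.9, context="CHH"))
        b = _sample(_flat(0.0, context="CHH"))
        with pytest.raises(ValueError):
            call_dmrs(a, b, "CHH")
        assert len(call_dmrs(a, b, "CHH", AnalysisConfig(delta_chh=0.2))) == 3

    def test_self_comparison_empty(self):
        a = _sample(_flat(0.6))
        assert call_dmrs(a, a, "CG") == []

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(0)
        rows_a, rows_b = [], []
        for p in range(0, 5000, 10):
            rows_a.append(("chr1", p, "+", "CG", int(rng.integers(0, 21)), 20))
            rows_b.append(("chr1", p, "+", "CG", int(rng.integers(0, 21)), 20))
        a, b = _sample(rows_a), _sample(rows_b)
        counts = [
            len(call_dmrs(a, b, "CG", AnalysisConfig(delta_cg=t)))
            for t in (0.1, 0.3, 0.5, 0.7)
        ]
        assert counts == sorted(counts, reverse=True)


class TestSubtract:
    def _dmr(self, start):
        return DMR("chr1", start, start + 100, "CG", 0.8, 0.1)

    def test_disjoint_unchanged_identical_empty(self):
        a = [self._dmr(0), self._dmr(200)]
        b = [self._dmr(400)]
        assert subtract_dmrs(a, b) == a
        assert subtract_dmrs(a, a) == []

    def test_cardinality(self):
        rng = np.random.default_rng(1)
        a = [self._dmr(int(s) * 100) for s in rng.choice(100, 40, replace=False)]
        b = [self._dmr(int(s) * 100) for s in rng.choice(100, 40, replace=False)]
        inter = {d.key for d in a} & {d.key for d in b}
        assert len(subtract_dmrs(a, b)) == len(a) - len(inter)


class TestMergeCondmrs:
    def _dmr(self, start, chrom="chr1"):
        return DMR(chrom, start, start + 100, "CHG", 0.0, 0.4)

    def test_adjacent_merge(self):
        cons = merge_condmrs([self._dmr(0), self._dmr(100)])
        assert len(cons) == 1 and (cons[0].start, cons[0].end) == (0, 200)

    def test_single_window_gap_merges(self):
        cons = merge_condmrs([self._dmr(0), self._dmr(200)])
        assert len(cons) == 1 and (cons[0].start, cons[0].end) == (0, 300)

    def test_two_window_gap_breaks(self):
        cons = merge_condmrs([self._dmr(0), self._dmr(300)])
        assert len(cons) == 2

    def test_idempotent_spans(self):
        rng = np.random.default_rng(2)
        dmrs = [self._dmr(int(s) * 100) for s in rng.choice(60, 25, replace=False)]
        cons = merge_condmrs(dmrs)
        # no two spans mergeable again: gap between spans > one window
        starts = sorted((c.start, c.end) for c in cons)
        for (s1, e1), (s2, e2) in zip(starts, starts[1:]):
            assert s2 - e1 > 100

    def test_feature_assignment_largest_overlap_then_lexicographic(self):
        dmrs = [self._dmr(0), self._dmr(100), self._dmr(200)]
        feats = [
            FeatureAnnotation("zz", "chr1", 0, 120, "+"),
            FeatureAnnotation("aa", "chr1", 100, 300, "-"),
        ]
        cons = merge_condmrs(dmrs, feats)
        assert cons[0].feature_id == "aa" and cons[0].orientation == "-"
        # exact tie -> lexicographically smallest id
        feats_tie = [
            FeatureAnnotation("bb", "chr1", 0, 150, "+"),
            FeatureAnnotation("ab", "chr1", 150, 300, "-"),
        ]
        cons = merge_condmrs(dmrs, feats_tie)
        assert cons[0].feature_id == "ab"

    def test_min_bp_and_feature_filters(self):
        dmrs = [self._dmr(0), self._dmr(1000)]
        feats = [FeatureAnnotation("g", "chr1", 950, 1200, "+")]
        cons = merge_condmrs(dmrs, feats, min_bp=None, require_feature=True)
        assert [c.start for c in cons] == [1000]
        assert merge_condmrs(dmrs, feats, min_bp=500) == []


def test_planted_dmr_recovery(default_sim):
    """On synthetic data at coverage 20 the planted heterochromatic CG
    hypo-DMR windows (WT vs first mutant generation) are recovered almost
    perfectly by the thresholded window rule."""
    samples, truth = default_sim
    dmrs = call_dmrs(samples["WT"], samples["1G-1"], "CG")
    hypo = {d.key for d in dmrs if d.direction == "hypo"}
    planted = truth.planted_cg_hypo_windows
    tp = len(hypo & planted)
    assert tp / len(planted) >= 0.95
    assert tp / len(hypo) >= 0.95
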