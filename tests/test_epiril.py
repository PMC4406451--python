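import numpy as np
import pandas as pd
import pytest

from methyldyn import (
    FeatureAnnotation,
    MarkerTable,
    ProbeStatusTable,
    assign_features,
    hypomethylation_index,
    index_table,
    infer_haplotypes,
    local_global_correlation,
    select_target_probes,
    simulate_epirils,
)


def _table(statuses: dict[str, list[str]], n=None) -> ProbeStatusTable:
    n = n or len(next(iter(statuses.values())))
    probes = pd.DataFrame(
        {"chrom": "chr1", "start": np.arange(n) * 1000,
         "end": np.arange(n) * 1000 + 100}
    )
    return ProbeStatusTable(probes=probes, status=pd.DataFrame(statuses))


class TestTargetSelection:
    def test_m_in_wt_u_in_ddm1(self):
        t = _table({"WT": ["M", "M", "U", "I"], "ddm1": ["U", "I", "U", "U"]})
        assert list(select_target_probes(t, "WT", "ddm1")) == [0]

    def test_missing_parent_errors(self):
        t = _table({"WT": ["M"]})
        with pytest.raises(KeyError):
            select_target_probes(t, "WT", "ddm1")

    def test_matches_linear_scan(self):
        rng = np.random.default_rng(0)
        wt = rng.choice(["M", "I", "U"], 500)
        dd = rng.choice(["M", "I", "U"], 500)
        t = _table({"WT": list(wt), "ddm1": list(dd)})
        brute = [i for i in range(500) if wt[i] == "M" and dd[i] == "U"]
        assert list(select_target_probes(t, "WT", "ddm1")) == brute


class TestIndex:
    def test_status_values(self):
        t = _table({"WT": ["M"] * 4, "ddm1": ["U"] * 4,
                    "lineA": ["M", "M", "M", "M"],
                    "lineB": ["M", "M", "U", "U"],
                    "lineC": ["I", "I", "I", "I"]})
        targets = select_target_probes(t, "WT", "ddm1")
        assert hypomethylation_index(t, targets, "lineA").index == 0.0
        assert hypomethylation_index(t, targets, "lineB").index == 0.5
        assert hypomethylation_index(t, targets, "lineC").index == 0.5

    def test_parents_score_zero_and_one(self):
        t = _table({"WT": ["M", "M", "U"], "ddm1": ["U", "U", "U"]})
        targets = select_target_probes(t, "WT", "ddm1")
        assert hypomethylation_index(t, targets, "WT").index == 0.0
        assert hypomethylation_index(t, targets, "ddm1").index == 1.0

    def test_empty_targets_error(self):
        t = _table({"WT": ["U"], "ddm1": ["U"]})
        with pytest.raises(ValueError):
            hypomethylation_index(t, np.array([], dtype=int), "WT")

    def test_monotone_in_flipped_probes(self):
        base = ["M"] * 10
        t = _table({"WT": ["M"] * 10, "ddm1": ["U"] * 10,
                    **{f"l{k}": ["U"] * k + base[k:] for k in range(11)}})
        targets = select_target_probes(t, "WT", "ddm1")
        idx = [hypomethylation_index(t, targets, f"l{k}").index for k in range(11)]
        assert idx == sorted(idx)


class TestLocalGlobalCorrelation:
    def test_perfect_linear(self):
        lines = [f"l{i}" for i in range(10)]
        g = pd.Series(np.linspace(0, 1, 10), index=lines)
        r, p = local_global_correlation(2 * g + 0.1, g)
        assert r == pytest.approx(1.0)
        assert p < 1e-6

    def test_zero_variance_undefined(self):
        lines = [f"l{i}" for i in range(5)]
        g = pd.Series(np.linspace(0, 1, 5), index=lines)
        r, p = local_global_correlation(pd.Series(0.3, index=lines), g)
        assert np.isnan(r) and np.isnan(p)

    def test_too_few_lines_undefined(self):
        g = pd.Series([0.1, 0.9], index=["a", "b"])
        r, _ = local_global_correlation(g, g)
        assert np.isnan(r)


class TestHaplotypeInference:
    def _markers(self, states, line="l1", spacing=100):
        rows = [(line, "chr1", (i + 1) * spacing, s) for i, s in enumerate(states)]
        return MarkerTable(pd.DataFrame(rows, columns=["line", "chrom", "pos", "state"]))

    def test_concordant_and_discordant_intervals(self):
        hap = infer_haplotypes(self._markers(["ddm1", "ddm1", "WT"]), "l1")
        assert hap.segments["chr1"] == [(100, 200, "ddm1"), (200, 300, "unknown")]

    def test_all_concordant_single_segment(self):
        hap = infer_haplotypes(self._markers(["WT"] * 5), "l1")
        assert hap.segments["chr1"] == [(100, 500, "WT")]

    def test_duplicate_concordant_markers_invariant(self):
        a = infer_haplotypes(self._markers(["WT", "WT", "ddm1"]), "l1")
        b = infer_haplotypes(self._markers(["WT", "WT", "WT", "ddm1"]), "l1")
        # doubling a concordant marker does not change the labelling of
        # the shared span
        assert a.label_at("chr1", 150) == b.label_at("chr1", 150) == "WT"
        assert a.label_at("chr1", 250) == "unknown"

    def test_outside_markers_unknown(self):
        hap = infer_haplotypes(self._markers(["WT", "WT"]), "l1")
        assert hap.label_at("chr1", 50) == "unknown"
        assert hap.label_at("chr1", 900) == "unknown"


class TestAssignFeatures:
    def test_containment_rule(self):
        from methyldyn.epiril import HaplotypeMap

        hap = HaplotypeMap({"chr1": [(0, 1000, "WT"), (1000, 2000, "ddm1")]})
        feats = [
            FeatureAnnotation("inside_wt", "chr1", 100, 500, "+"),
            FeatureAnnotation("straddles", "chr1", 800, 1200, "+"),
            FeatureAnnotation("inside_dd", "chr1", 1100, 1900, "-"),
            FeatureAnnotation("off_map", "chr2", 0, 100, "+"),
        ]
        lab = assign_features(feats, hap)
        assert lab == {
            "inside_wt": "WT", "straddles": "unknown",
            "inside_dd": "ddm1", "off_map": "unknown",
        }


class TestSimulatedEpirils:
    def test_recovery_pipeline(self, default_sim):
        samples, truth = default_sim
        ep = simulate_epirils(truth, seed=77)
        tab = ep.probe_table
        targets = select_target_probes(tab, "WT", "ddm1")
        assert hypomethylation_index(tab, targets, "WT").index == 0.0
        assert hypomethylation_index(tab, targets, "ddm1").index == 1.0
        idx = index_table(tab, "WT", "ddm1", lines=ep.lines)["index"]
        err = (idx - ep.true_fraction.loc[ep.lines]).abs()
        # status noise perturbs the index by at most a few probes
        assert err.max() <= 0.03
        # planted trans effect: strong positive local-global correlation
        rs = [
            local_global_correlation(ep.local_change.loc[g], idx)[0]
            for g in ep.trans_genes
        ]
        assert min(rs) > 0.7
        # independent variable: near-zero correlation
        rng = np.random.default_rng(5)
        null = pd.Series(rng.normal(size=len(ep.lines)), index=ep.lines)
        r_null, p_null = local_global_correlation(null, idx)
        assert abs(r_null) < 0.3 and p_null > 0.001

    def test_haplotype_recovery_and_trans_gains_on_both(self, default_sim):
        samples, truth = default_sim
        ep = simulate_epirils(truth, seed=77)
        idx = index_table(ep.probe_table, "WT", "ddm1", lines=ep.lines)["index"]
        # a line with a mixed genome, like the focal epiRIL of the study
        line = (idx - 0.5).abs().idxmin()
        hap = infer_haplotypes(ep.markers, line)
        # inferred labels match truth away from breakpoints
        mismatch = total = 0
        for chrom, segs in ep.haplotype_truth[line].items():
            for s, e, lab in segs:
                for pos in range(s + 15_000, e - 15_000, 20_000):
                    inferred = hap.label_at(chrom, pos)
                    if inferred != "unknown":
                        total += 1
                        mismatch += inferred != lab
        assert total > 0 and mismatch / total < 0.05
        # planted trans gains occur on genes of both haplotype labels
        lab = assign_features(truth.genes(), hap)
        gained = [g for g in ep.trans_genes if ep.gains.loc[g, line]]
        labels = {lab[g] for g in gained}
        assert {"WT", "ddm1"} <= labels
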