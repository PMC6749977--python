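"""Cohort network: Spearman edges, hub permutation test, severity
stratification and the low-vs-high comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import riboshift as rs
from riboshift.cohort import CohortMatrix
from riboshift.errors import InputError


def _cohort_from_arrays(mrna, rpf, genes=None, patients=None):
    genes = genes or [f"g{i}" for i in range(mrna.shape[0])]
    patients = patients or [f"D{j}" for j in range(mrna.shape[1])]
    return CohortMatrix(pd.DataFrame(mrna, index=genes, columns=patients),
                        pd.DataFrame(rpf, index=genes, columns=patients))


class TestCorrelatePairs:
    def test_monotone_pair_gives_rho_one(self):
        n = 10
        x = np.linspace(10, 100, n)
        mrna = np.vstack([np.full(n, 50.0), np.full(n, 20.0)])
        rpf = np.vstack([x, 20.0 * np.exp(x / 40)])  # TE rises with RBP RPF
        cm = _cohort_from_arrays(mrna, rpf, genes=["rbp", "t"])
        edges = rs.correlate_pairs(cm, [("rbp", "t")])
        assert edges.loc[0, "rho"] == pytest.approx(1.0)

    def test_anti_monotone_gives_minus_one(self):
        n = 10
        x = np.linspace(10, 100, n)
        mrna = np.vstack([np.full(n, 50.0), np.full(n, 20.0)])
        rpf = np.vstack([x, 20.0 * np.exp(-x / 40)])
        cm = _cohort_from_arrays(mrna, rpf, genes=["rbp", "t"])
        edges = rs.correlate_pairs(cm, [("rbp", "t")])
        assert edges.loc[0, "rho"] == pytest.approx(-1.0)

    def test_five_point_pair_matches_hand_ranked_formula(self):
        rpf_rbp = np.array([3.0, 9.0, 1.0, 7.0, 5.0])
        te = np.array([2.0, 1.0, 5.0, 4.0, 3.0])
        mrna = np.vstack([np.full(5, 10.0), np.full(5, 10.0)])
        rpf = np.vstack([rpf_rbp, te * 10.0])
        cm = _cohort_from_arrays(mrna, rpf, genes=["rbp", "t"])
        edges = rs.correlate_pairs(cm, [("rbp", "t")])
        d = stats.rankdata(rpf_rbp) - stats.rankdata(te)
        rho_hand = 1 - 6 * (d**2).sum() / (5 * 24)
        assert edges.loc[0, "rho"] == pytest.approx(rho_hand)

    def test_spearman_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(20)
        n = 15
        x = rng.lognormal(1, 0.3, n)
        y = rng.lognormal(1, 0.3, n)
        mrna = np.vstack([np.full(n, 10.0)] * 2)
        cm1 = _cohort_from_arrays(mrna, np.vstack([x, y * 10]),
                                  genes=["rbp", "t"])
        # cube the RBP trajectory: strictly monotone transform
        cm2 = _cohort_from_arrays(mrna, np.vstack([x**3, y * 10]),
                                  genes=["rbp", "t"])
        r1 = rs.correlate_pairs(cm1, [("rbp", "t")]).loc[0, "rho"]
        r2 = rs.correlate_pairs(cm2, [("rbp", "t")]).loc[0, "rho"]
        assert r1 == pytest.approx(r2)

    def test_constant_vector_pair_is_skipped(self):
        n = 8
        mrna = np.vstack([np.full(n, 10.0), np.full(n, 10.0)])
        rpf = np.vstack([np.full(n, 30.0), np.arange(1.0, n + 1) * 10])
        cm = _cohort_from_arrays(mrna, rpf, genes=["rbp", "t"])
        assert len(rs.correlate_pairs(cm, [("rbp", "t")])) == 0


class TestHubTest:
    def test_planted_hub_recovered_with_few_false_decoys(self):
        cm, tr = rs.generate_cohort(n_patients=30, n_rbps=21,
                                    n_targets_per_hub=50, hub_strength=1.0,
                                    seed=21)
        pairs = [(r, t) for r, ts in tr.rbp_targets.items() for t in ts]
        edges = rs.correlate_pairs(cm, pairs)
        hubs = rs.hub_test(edges, cm, analyzed_genes=tr.target_genes,
                           n_perm=2000, seed=22)
        called = set(hubs.loc[hubs["hub"], "rbp"])
        assert tr.hub_rbps[0] in called
        assert len(called - set(tr.hub_rbps)) <= 1

    def test_fixed_seed_reproducibility(self):
        cm, tr = rs.generate_cohort(n_patients=20, n_rbps=5, seed=23)
        pairs = [(r, t) for r, ts in tr.rbp_targets.items() for t in ts]
        edges = rs.correlate_pairs(cm, pairs)
        a = rs.hub_test(edges, cm, analyzed_genes=tr.target_genes,
                        n_perm=1000, seed=24)
        b = rs.hub_test(edges, cm, analyzed_genes=tr.target_genes,
                        n_perm=1000, seed=24)
        pd.testing.assert_frame_equal(a, b)

    def test_null_cohort_p_values_are_spread_uniformly(self):
        cm, tr = rs.generate_cohort(n_patients=30, n_rbps=20,
                                    hub_strength=0.0, seed=25)
        pairs = [(r, t) for r, ts in tr.rbp_targets.items() for t in ts]
        edges = rs.correlate_pairs(cm, pairs)
        hubs = rs.hub_test(edges, cm, analyzed_genes=tr.target_genes,
                           n_perm=1000, seed=26)
        assert not hubs["hub"].any()
        assert hubs["empirical_p"].median() > 0.1


class TestStratifyPatients:
    def test_planted_marker_regimes_recover_extreme_groups(self):
        cm, tr = rs.generate_cohort(n_patients=30, seed=27,
                                    severity_separation=2.0)
        strat = rs.stratify_patients(cm.tpm_mrna.loc[tr.marker_genes])
        sev = tr.severity
        assert set(strat.index[strat["group"] == "low"]) == \
            set(sev.index[sev == 1])
        assert set(strat.index[strat["group"] == "high"]) == \
            set(sev.index[sev == 4])

    def test_single_level_groups_everyone_together(self):
        cm, tr = rs.generate_cohort(n_patients=10, seed=28)
        strat = rs.stratify_patients(cm.tpm_mrna.loc[tr.marker_genes],
                                     k_levels=1)
        assert (strat["severity"] == 1).all()

    def test_marker_column_order_does_not_change_severity(self):
        cm, tr = rs.generate_cohort(n_patients=20, seed=29)
        markers = cm.tpm_mrna.loc[tr.marker_genes]
        a = rs.stratify_patients(markers)
        b = rs.stratify_patients(markers.iloc[::-1])
        pd.testing.assert_series_equal(a["severity"], b["severity"])

    def test_identical_profiles_rejected(self):
        flat = pd.DataFrame(np.ones((3, 8)),
                            index=["m1", "m2", "m3"],
                            columns=[f"D{i}" for i in range(8)])
        with pytest.raises(InputError, match="structure"):
            rs.stratify_patients(flat)


class TestSeverityComparison:
    def _assignment(self, low, high):
        idx = low + high
        return pd.DataFrame({
            "severity": [1] * len(low) + [4] * len(high),
            "group": ["low"] * len(low) + ["high"] * len(high),
        }, index=pd.Index(idx, name="patient"))

    def test_identical_groups_give_p_near_one(self):
        vals = [10.0, 12.0, 9.0, 11.0]
        tpm = pd.DataFrame([vals + vals],
                           index=["rbp1"],
                           columns=[f"D{i}" for i in range(8)])
        assignment = self._assignment([f"D{i}" for i in range(4)],
                                      [f"D{i}" for i in range(4, 8)])
        out = rs.compare_rbp_by_severity(tpm, assignment)
        assert out.loc["rbp1", "p"] == pytest.approx(1.0)

    def test_three_sd_shift_is_detected(self):
        rng = np.random.default_rng(30)
        low = 10 ** rng.normal(1.0, 0.1, 8)
        high = 10 ** rng.normal(1.3, 0.1, 8)   # 3 pooled SD in log10
        tpm = pd.DataFrame([np.concatenate([low, high])], index=["rbp1"],
                           columns=[f"D{i}" for i in range(16)])
        assignment = self._assignment([f"D{i}" for i in range(8)],
                                      [f"D{i}" for i in range(8, 16)])
        assert rs.compare_rbp_by_severity(tpm, assignment).loc["rbp1", "p"] \
            < 0.05

    def test_swapping_groups_flips_t_keeps_p(self):
        rng = np.random.default_rng(31)
        tpm = pd.DataFrame([10 ** rng.normal(1, 0.2, 12)], index=["r"],
                           columns=[f"D{i}" for i in range(12)])
        a = self._assignment([f"D{i}" for i in range(6)],
                             [f"D{i}" for i in range(6, 12)])
        b = self._assignment([f"D{i}" for i in range(6, 12)],
                             [f"D{i}" for i in range(6)])
        ra = rs.compare_rbp_by_severity(tpm, a)
        rb = rs.compare_rbp_by_severity(tpm, b)
        assert ra.loc["r", "t"] == pytest.approx(-rb.loc["r", "t"])
        assert ra.loc["r", "p"] == pytest.approx(rb.loc["r", "p"])

    def test_empty_group_rejected(self):
        tpm = pd.DataFrame([[1.0, 2.0]], index=["r"], columns=["D0", "D1"])
        bad = pd.DataFrame({"severity": [2, 3], "group": ["mid", "mid"]},
                           index=pd.Index(["D0", "D1"], name="patient"))
        with pytest.raises(InputError):
            rs.compare_rbp_by_severity(tpm, bad)


class TestMarkerCorrelation:
    def test_identical_columns_give_rho_one(self):
        cm, tr = rs.generate_cohort(n_patients=20, seed=32)
        cm.tpm_mrna.loc["RBP01"] = cm.tpm_mrna.loc["MARK1"]
        table, _ = rs.marker_rbp_correlation(cm, ["RBP01"], ["MARK1"])
        assert table.loc[0, "rho"] == pytest.approx(1.0)

    def test_planted_dependence_on_four_of_five_markers(self):
        rng = np.random.default_rng(33)
        n = 30
        driver = rng.normal(1.0, 0.4, n)
        rows = {"rbp": 10 ** driver}
        for i in range(4):
            rows[f"m{i}"] = 10 ** (driver + rng.normal(0, 0.1, n))
        rows["m4"] = 10 ** rng.normal(1.0, 0.4, n)
        mrna = pd.DataFrame(rows, index=[f"D{i}" for i in range(n)]).T
        cm = CohortMatrix(mrna, mrna.copy())
        table, mean_sig = rs.marker_rbp_correlation(
            cm, ["rbp"], [f"m{i}" for i in range(5)])
        assert mean_sig == pytest.approx(4.0, abs=1.0)

    def test_display_filter_is_a_pure_postfilter(self):
        cm, tr = rs.generate_cohort(n_patients=30, seed=34)
        pairs = [(r, t) for r, ts in tr.rbp_targets.items() for t in ts]
        edges = rs.correlate_pairs(cm, pairs)
        shown = rs.filter_edges_for_display(edges, 0.45)
        assert (shown["rho"].abs() >= 0.45).all()
        assert len(shown) <= len(edges)
        # hub calls computed before and after filtering are identical because
        # the hub test never sees the display filter
        hubs = rs.hub_test(edges, cm, analyzed_genes=tr.target_genes,
                           n_perm=1000, seed=35)
        hubs2 = rs.hub_test(edges, cm, analyzed_genes=tr.target_genes,
                            n_perm=1000, seed=35)
        pd.testing.assert_frame_equal(hubs, hubs2)
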