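"""The negative-binomial interaction model: IRLS fits, Wald/LRT tests,
dispersion estimation and BH correction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, stats

import riboshift as rs
from riboshift.dte import (ALPHA_FLOOR, DesignSpec, GeneFit, bh_adjust,
                           call_dtegs, estimate_dispersion,
                           estimate_gene_dispersion, fit_gene,
                           lrt_across_time, nb_loglik, run_dte, wald_contrast)
from riboshift.errors import InputError, NumericalError
from riboshift.expression import CountTable


def _meta(n_patients=2, times=("0", "2h", "6h")):
    rows = []
    for p in range(n_patients):
        for t in times:
            for a in ("RNA", "RPF"):
                rows.append({"sample_id": f"P{p+1}_{t}_{a}",
                             "patient": f"P{p+1}", "time": t, "assay": a})
    meta = pd.DataFrame(rows).set_index("sample_id")
    meta["time"] = pd.Categorical(meta["time"], list(times), ordered=True)
    return meta


class TestDesignSpec:
    def test_reduced_is_full_minus_interaction(self):
        d = DesignSpec.from_meta(_meta())
        assert set(d.full.columns) - set(d.reduced.columns) == \
            set(d.interaction_cols)
        assert d.n_interaction == 2

    def test_rank_deficient_design_reports_columns(self):
        meta = _meta()
        meta["patient"] = meta["assay"]  # patient aliases assay -> collinear
        with pytest.raises(InputError, match="collinear"):
            DesignSpec.from_meta(meta)

    def test_rpf_contrast_is_rna_plus_te(self):
        d = DesignSpec.from_meta(_meta())
        for t in d.times[1:]:
            assert np.allclose(d.contrast(t, "rpf"),
                               d.contrast(t, "rna") + d.contrast(t, "te"))


class TestFitGene:
    def test_identical_rna_and_rpf_rows_give_zero_interaction(self):
        meta = _meta()
        d = DesignSpec.from_meta(meta)
        base = {"0": 100, "2h": 160, "6h": 250}
        y = np.array([base[t] for t in meta["time"]], dtype=float)
        sf = np.ones(len(meta))
        fit = fit_gene(y, d, sf, 1e-8)
        names = list(d.full.columns)
        for c in d.interaction_cols:
            assert abs(fit.beta[names.index(c)]) < 1e-6

    def test_planted_fourfold_rpf_change_recovers_two_log2(self):
        meta = _meta()
        d = DesignSpec.from_meta(meta)
        mu = []
        for t, a in zip(meta["time"], meta["assay"]):
            v = 1000.0
            if t == "2h" and a == "RPF":
                v *= 4.0
            mu.append(v)
        fit = fit_gene(np.array(mu), d, np.ones(len(meta)), 1e-8)
        lfc, _, _ = wald_contrast(fit, d.contrast("2h", "te"))
        assert lfc == pytest.approx(2.0, abs=1e-6)

    def test_irls_matches_direct_likelihood_maximization(self):
        """IRLS solution equals a brute-force numerical MLE (oracle)."""
        meta = _meta()
        d = DesignSpec.from_meta(meta)
        X = d.full.to_numpy(dtype=float)
        rng = np.random.default_rng(8)
        sf = np.exp(rng.normal(0, 0.1, size=len(meta)))
        alpha = 0.08
        for _ in range(3):
            beta_true = rng.normal(0, 0.5, size=X.shape[1])
            beta_true[0] = 5.0
            mu = sf * np.exp(X @ beta_true)
            y = rng.negative_binomial(1 / alpha, 1 / (1 + alpha * mu))
            fit = fit_gene(y, d, sf, alpha)

            def nll(b):
                m = np.exp(np.clip(X @ b + np.log(sf), -30, 30))
                return -nb_loglik(y.astype(float), m, alpha)

            res = optimize.minimize(nll, fit.beta + 0.05, method="BFGS",
                                    options={"gtol": 1e-10, "maxiter": 500})
            assert np.max(np.abs(fit.beta - res.x)) < 1e-4


class TestWald:
    def _fit(self, beta, cov, df=27):
        d = DesignSpec.from_meta(_meta())
        return GeneFit(beta=beta, cov=cov, loglik_full=0.0, loglik_reduced=0.0,
                       converged=True, alpha=0.1, design=d, df_resid=df)

    def test_zero_estimate_gives_p_one(self):
        p_dim = len(DesignSpec.from_meta(_meta()).full.columns)
        fit = self._fit(np.zeros(p_dim), np.eye(p_dim))
        c = np.zeros(p_dim)
        c[0] = 1.0
        _, _, p = wald_contrast(fit, c)
        assert p == pytest.approx(1.0)

    def test_t_quantile_recovers_nominal_level(self):
        p_dim = len(DesignSpec.from_meta(_meta()).full.columns)
        beta = np.zeros(p_dim)
        beta[0] = stats.t.ppf(0.975, 27)  # the 5% two-sided t threshold
        fit = self._fit(beta, np.eye(p_dim))
        c = np.zeros(p_dim)
        c[0] = 1.0
        _, _, p = wald_contrast(fit, c)
        assert p == pytest.approx(0.05, abs=1e-3)

    def test_zero_se_flags_undefined_p(self):
        p_dim = len(DesignSpec.from_meta(_meta()).full.columns)
        fit = self._fit(np.ones(p_dim), np.zeros((p_dim, p_dim)))
        c = np.zeros(p_dim)
        c[0] = 1.0
        _, se, p = wald_contrast(fit, c)
        assert se == 0.0 and np.isnan(p)


class TestLrt:
    def _fit(self, ll_full, ll_red):
        d = DesignSpec.from_meta(_meta())
        return GeneFit(beta=np.zeros(1), cov=np.eye(1), loglik_full=ll_full,
                       loglik_reduced=ll_red, converged=True, alpha=0.1,
                       design=d)

    def test_equal_likelihoods_give_p_one(self):
        assert lrt_across_time(self._fit(-10.0, -10.0)) == pytest.approx(1.0)

    def test_chi2_quantile(self):
        # stat 5.991 at df 2 sits at p = 0.05 (design here has 2 interactions)
        stat = stats.chi2.ppf(0.95, 2)
        assert lrt_across_time(self._fit(-10.0 + stat / 2, -10.0)) == \
            pytest.approx(0.05, abs=1e-6)

    def test_negative_statistic_raises(self):
        with pytest.raises(NumericalError):
            lrt_across_time(self._fit(-10.0, -9.0))


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_equal_and_single_p_unchanged(self):
        assert np.allclose(bh_adjust([0.3, 0.3, 0.3]), 0.3)
        assert bh_adjust([0.123])[0] == pytest.approx(0.123)

    def test_nan_propagates_without_affecting_m(self):
        out = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(out[1])
        assert np.allclose(out[[0, 2]], bh_adjust([0.01, 0.04]))

    def test_adjusted_at_least_raw_and_monotone(self):
        rng = np.random.default_rng(9)
        p = rng.random(50)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all() and (adj <= 1).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=40))
    @settings(deadline=None, derandomize=True)
    def test_step_up_properties_hold_for_arbitrary_inputs(self, pvals):
        adj = bh_adjust(pvals)
        p = np.asarray(pvals)
        assert (adj >= p - 1e-12).all()
        assert (adj <= 1.0 + 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-9).all()


class TestDispersion:
    def test_constant_counts_hit_the_floor(self, toy_design):
        y = np.full(toy_design.full.shape[0], 50.0)
        a = estimate_gene_dispersion(y, toy_design, np.ones(len(y)))
        assert a == pytest.approx(ALPHA_FLOOR)

    def test_poisson_data_estimates_near_zero(self):
        meta = _meta(n_patients=3, times=("0", "2h", "6h", "24h"))
        d = DesignSpec.from_meta(meta)
        rng = np.random.default_rng(10)
        sf = np.ones(len(meta))
        est = [estimate_gene_dispersion(rng.poisson(1000, size=len(meta)),
                                        d, sf) for _ in range(30)]
        assert np.median(est) <= 0.01

    def test_recovers_planted_dispersion(self):
        meta = _meta(n_patients=4, times=("0", "45min", "2h", "6h", "24h"))
        d = DesignSpec.from_meta(meta)
        rng = np.random.default_rng(11)
        sf = np.ones(len(meta))
        alpha = 0.1
        est = []
        for _ in range(40):
            mu = 800.0
            y = rng.negative_binomial(1 / alpha, 1 / (1 + alpha * mu),
                                      size=len(meta))
            est.append(estimate_gene_dispersion(y.astype(float), d, sf))
        assert 0.07 <= np.median(est) <= 0.13

    def test_too_few_residual_df_raises(self):
        meta = _meta(n_patients=2, times=("0", "2h"))
        d = DesignSpec.from_meta(meta)
        small = meta.iloc[: d.full.shape[1] + 1]
        d_small = DesignSpec.from_meta(small)
        y = np.arange(len(small), dtype=float) + 1
        with pytest.raises(InputError):
            estimate_gene_dispersion(y, d_small, np.ones(len(small)))


class TestCalls:
    def _result(self):
        per_time = pd.DataFrame({
            "gene": ["a", "a", "b", "b"],
            "time": ["2h", "6h", "2h", "6h"],
            "padj_te": [0.2, 0.04, 0.5, 0.6],
            "padj_rna": [0.9, 0.9, 0.5, 0.2],
        })
        per_gene = pd.DataFrame({"lrt_padj": [0.01, 0.9]},
                                index=pd.Index(["a", "b"], name="gene"))
        return per_time, per_gene

    def test_intersection_needs_both_tests(self):
        pt, pg = self._result()
        out = call_dtegs(pt, pg, 0.05, combine="intersection")
        assert bool(out.loc["a", "dteg"]) and not bool(out.loc["b", "dteg"])

    def test_union_and_single_rules(self):
        pt, pg = self._result()
        pg2 = pg.copy()
        pg2.loc["a", "lrt_padj"] = 0.9  # wald only
        assert bool(call_dtegs(pt, pg2, 0.05, "union").loc["a", "dteg"])
        assert not bool(call_dtegs(pt, pg2, 0.05, "lrt").loc["a", "dteg"])
        assert bool(call_dtegs(pt, pg2, 0.05, "wald").loc["a", "dteg"])

    def test_nothing_significant_gets_no_flag(self):
        pt, pg = self._result()
        out = call_dtegs(pt, pg, 0.001)
        assert not out["dteg"].any() and not out["dtg"].any()


class TestRunDte:
    def test_additivity_is_exact(self, small_dte):
        res, _ = small_dte
        pt = res.per_time.dropna(subset=["lfc_te"])
        assert np.allclose(pt["lfc_te"], pt["lfc_rpf"] - pt["lfc_rna"],
                           atol=1e-6)

    def test_qualitative_buffering_pattern(self):
        """Ribosome occupancy rising on flat transcripts yields positive dTE
        with non-significant dRNA (the translationally exclusive pattern)."""
        cfg = rs.SimConfig(n_genes=40, seed=4, depth_per_library=8e4,
                           class_proportions={"none": 0.5, "exclusive": 0.5})
        table, truth = rs.generate_counts(cfg)
        res = rs.run_dte(table)
        up = truth.genes.index[(truth.genes["class"] == "exclusive")
                               & (truth.genes["direction"] == "up")]
        pt = res.per_time[res.per_time["gene"].isin(set(up))]
        best = pt.loc[pt.groupby("gene")["padj_te"].idxmin()]
        assert (best["lfc_te"] > 0).mean() > 0.8
        assert (best["padj_rna"] > 0.05).mean() > 0.8

    def test_patient_effect_immunity(self):
        """Strong patient multipliers on null data do not inflate dTE false
        positives beyond the calibration band."""
        cfg = rs.SimConfig(n_genes=300, seed=12, patient_sd=1.0,
                           class_proportions={"none": 1.0})
        table, _ = rs.generate_counts(cfg)
        res = rs.run_dte(table)
        frac = (res.per_time["p_te"] < 0.05).mean()
        assert 0.02 <= frac <= 0.08
        assert res.per_gene["dteg"].sum() <= 3
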