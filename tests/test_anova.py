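import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gxe_acclim import (
    bh_fdr,
    fit_gene_anova,
    fit_region,
    generate_dataset,
    paired_t_equivalent,
    run_genomewide,
)
from gxe_acclim import test_with_pooling as apply_pooling
from gxe_acclim.anova import (
    AnovaDecomposition,
    by_fdr,
    decompose_matrix,
    decompose_region,
    pooled_tests,
)
from conftest import projection_ss_full, projection_ss_region

TERMS = ["T", "geo", "clone", "T_x_geo", "T_x_clone", "error"]


class TestDecomposition:
    def test_default_design_degrees_of_freedom(self, design):
        dec = decompose_matrix(np.zeros((1, 24)), design)
        assert dec.attrs["df"] == {
            "T": 1, "geo": 1, "clone": 2, "T_x_geo": 1, "T_x_clone": 2,
            "error": 16, "total": 23,
        }

    def test_constant_gene_all_ss_zero(self, design):
        dec = decompose_matrix(np.full((1, 24), 3.7), design)
        assert dec.iloc[0]["constant"]
        assert all(dec.iloc[0][f"SS_{t}"] == 0 for t in TERMS)

    def test_pure_temperature_effect_ss(self, design):
        """+0.5 at 28 C / -0.5 at 18 C: SS_T = 24 * 0.25 = 6, all else 0."""
        y = np.where(design.table["temperature"] == 28, 0.5, -0.5)[None, :]
        dec = decompose_matrix(y, design)
        assert dec.iloc[0]["SS_T"] == pytest.approx(6.0)
        for t in TERMS[1:]:
            assert dec.iloc[0][f"SS_{t}"] == pytest.approx(0.0, abs=1e-12)

    def test_ss_additivity_random_genes(self, design):
        y = np.random.default_rng(0).normal(size=(200, 24))
        dec = decompose_matrix(y, design)
        total = dec[[f"SS_{t}" for t in TERMS]].sum(axis=1)
        np.testing.assert_allclose(total, dec["SS_total"], rtol=1e-8)

    def test_matches_projection_oracle(self, design):
        """Closed-form balanced SS vs sequential indicator-matrix least squares."""
        rng = np.random.default_rng(1)
        for _ in range(20):
            y = rng.normal(size=24) + rng.normal() * design.x_temperature()
            dec = fit_gene_anova(y, design)
            oracle = projection_ss_full(y, design)
            for t in TERMS:
                assert dec.ss[t] == pytest.approx(oracle[t], rel=1e-8, abs=1e-8)

    def test_region_matches_projection_oracle(self, region_design):
        rng = np.random.default_rng(2)
        for _ in range(20):
            y = rng.normal(size=12)
            row = fit_region(y, region_design)
            oracle = projection_ss_region(y, region_design)
            for t in ("T", "clone", "T_x_clone", "error"):
                assert row[f"SS_{t}"] == pytest.approx(oracle[t], rel=1e-8, abs=1e-8)

    def test_region_degrees_of_freedom(self, region_design):
        dec = decompose_region(np.zeros((1, 12)), region_design)
        assert dec.attrs["df"] == {
            "T": 1, "clone": 1, "T_x_clone": 1, "error": 8, "total": 11
        }


class TestPooling:
    def _dec_with_interaction_p(self, design, target_p):
        """Construct a decomposition whose p_Txclone equals target_p exactly."""
        f_crit = stats.f.isf(target_p, 2, 16)
        ss = {"T": 4.0, "geo": 0.5, "clone": 1.0, "T_x_geo": 0.2,
              "T_x_clone": f_crit * 2.0, "error": 16.0}  # MS_error = 1
        return AnovaDecomposition(
            ss=ss,
            df={"T": 1, "geo": 1, "clone": 2, "T_x_geo": 1, "T_x_clone": 2,
                "error": 16, "total": 23},
            ss_total=sum(ss.values()), constant=False,
        )

    def test_pools_just_above_threshold(self, design):
        res = apply_pooling(self._dec_with_interaction_p(design, 0.21))
        assert res.pooled and res.den_df_T == 18

    def test_boundary_is_strict(self, design):
        """p_Txclone exactly 0.2 must NOT pool (rule is strictly P > 0.2)."""
        res = apply_pooling(self._dec_with_interaction_p(design, 0.2))
        assert res.p_T_x_clone == pytest.approx(0.2, rel=1e-9)
        assert not res.pooled and res.den_df_T == 2

    def test_pooled_f_matches_oracle(self, design):
        """A low-interaction gene: pooled F/p vs raw-SS F tail at (1, 18)."""
        rng = np.random.default_rng(3)
        y = 1.0 * design.x_temperature() + rng.normal(scale=0.3, size=24)
        dec = fit_gene_anova(y, design)
        res = apply_pooling(dec)
        oracle = projection_ss_full(y, design)
        if res.pooled:
            ms_pool = (oracle["T_x_clone"] + oracle["error"]) / 18
            p_expected = stats.f.sf(oracle["T"] / ms_pool, 1, 18)
        else:
            p_expected = stats.f.sf(oracle["T"] / (oracle["T_x_clone"] / 2), 1, 2)
        assert res.p_T == pytest.approx(p_expected, rel=1e-8)

    def test_pool_applies_to_T_only_leaves_interaction_unpooled(self, design):
        rng = np.random.default_rng(4)
        y = rng.normal(size=24)
        dec = fit_gene_anova(y, design)
        both = apply_pooling(dec, pool_applies_to="both")
        t_only = apply_pooling(dec, pool_applies_to="T")
        assert t_only.den_df_T_x_geo == 2
        if both.pooled:
            assert both.den_df_T_x_geo == 18

    def test_geo_tested_against_clone_ms(self, design):
        """F_geo = MS_geo / MS_clone(geo) on (1, 2) df."""
        rng = np.random.default_rng(5)
        y = rng.normal(size=24)
        res = apply_pooling(fit_gene_anova(y, design))
        o = projection_ss_full(y, design)
        assert res.p_geo == pytest.approx(
            stats.f.sf(o["geo"] / (o["clone"] / 2), 1, 2), rel=1e-8
        )

    def test_pooling_rate_converges_to_threshold(self, design):
        """With sigma_tclone = 0, the not-pooled fraction matches the 0.2 threshold."""
        expr, _ = generate_dataset(
            4000, class_proportions={"null": 1.0},
            noise={"sigma_e": 1.0, "sigma_clone": 0.0, "sigma_tclone": 0.0}, seed=10,
        )
        pt = pooled_tests(decompose_matrix(expr.to_numpy(), design))
        frac_not_pooled = 1.0 - pt["pooled"].mean()
        se = np.sqrt(0.2 * 0.8 / 4000)
        assert abs(frac_not_pooled - 0.2) < 3 * se


class TestRegionAndPairedT:
    def test_constant_gene(self, region_design):
        row = fit_region(np.full(12, 2.0), region_design)
        assert row["p_T"] == 1.0 and row["delta"] == 0.0

    def test_pure_effect_no_noise(self, region_design):
        y = np.where(region_design.table["temperature"] == 28, 1.0, -1.0)
        row = fit_region(y, region_design)
        assert row["delta"] == pytest.approx(2.0)
        assert row["p_T"] == pytest.approx(0.0, abs=1e-12)
        assert paired_t_equivalent(y[None, :], region_design)[0] == pytest.approx(0.0, abs=1e-12)

    def test_paired_t_identical_y_gives_p_one(self, region_design):
        t = region_design.table
        y = np.where(t["clone_id"] == t["clone_id"].iloc[0], 1.0, -1.0)
        assert paired_t_equivalent(y[None, :], region_design)[0] == pytest.approx(1.0, abs=1e-9)

    def test_paired_t_equals_scipy_paired_ttest(self, region_design):
        """The fully pooled F equals the square of the paired t on clone-mean pairs."""
        rng = np.random.default_rng(6)
        t = region_design.table
        y = rng.normal(size=12)
        p_pkg = paired_t_equivalent(y[None, :], region_design)[0]
        # oracle: one-way paired comparison with 12 obs, pairing replicates
        # within clone across temperatures leaves F_T on (1, 10)
        o = projection_ss_region(y, region_design)
        f = o["T"] / ((o["clone"] + o["T_x_clone"] + o["error"]) / 10)
        assert p_pkg == pytest.approx(stats.f.sf(f, 1, 10), rel=1e-10)

    def test_paired_t_null_uniformity(self, region_design):
        rng = np.random.default_rng(7)
        y = rng.normal(size=(10000, 12))
        p = paired_t_equivalent(y, region_design)
        ks = stats.kstest(p, "uniform")
        assert ks.pvalue > 0.01


class TestBhFdr:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    @pytest.mark.parametrize(
        "p, q",
        [([0.5], [0.5]), ([1.0, 1.0], [1.0, 1.0]), ([], [])],
        ids=["single", "all-ones", "empty"],
    )
    def test_edge_vectors(self, p, q):
        np.testing.assert_allclose(bh_fdr(p), q)

    def test_nan_excluded_from_m(self):
        q = bh_fdr([0.01, np.nan, 0.02])
        assert np.isnan(q[1])
        np.testing.assert_allclose(q[[0, 2]], [0.02, 0.02])  # m = 2, not 3

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(8)
        p = rng.uniform(size=500) ** 2
        q_sm = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(bh_fdr(p), q_sm, rtol=1e-10)

    def test_q_never_below_p(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=1000)
        assert (bh_fdr(p) >= p - 1e-12).all()

    def test_by_variant_more_conservative(self):
        p = np.random.default_rng(10).uniform(size=50)
        assert (by_fdr(p) >= bh_fdr(p) - 1e-12).all()


@pytest.fixture(scope="module")
def null_decomposition(design):
    expr, _ = generate_dataset(
        8000, class_proportions={"null": 1.0},
        noise={"sigma_e": 1.0, "sigma_clone": 0.0, "sigma_tclone": 0.0}, seed=20,
    )
    return decompose_matrix(expr.to_numpy(), design)


class TestNullCalibration:
    def test_unpooled_branch_sampling_distribution_uniform(self, design, null_decomposition):
        from gxe_acclim.anova import _f_pvalue

        dec = null_decomposition
        p = _f_pvalue(dec["SS_T"], 1, dec["SS_T_x_clone"], 2)
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_pooled_branch_sampling_distribution_uniform(self, design, null_decomposition):
        from gxe_acclim.anova import _f_pvalue

        dec = null_decomposition
        p = _f_pvalue(dec["SS_T"], 1, dec["SS_T_x_clone"] + dec["SS_error"], 18)
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_pooled_branch_as_it_occurs_uniform(self, design, null_decomposition):
        pt = pooled_tests(null_decomposition)
        p = pt.loc[pt["pooled"], "p_T"]
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_pretest_selection_makes_unpooled_branch_conservative(self, null_decomposition):
        """Genes routed to the unpooled branch were selected for a large
        interaction MS, so their conditional p_T is stochastically larger
        than uniform: a property of conditional pooling, not a defect."""
        pt = pooled_tests(null_decomposition)
        p = pt.loc[~pt["pooled"], "p_T"]
        assert p.mean() > 0.5


class TestRunGenomewide:
    def test_all_null_fdr_control(self, design):
        expr, _ = generate_dataset(
            5000, class_proportions={"null": 1.0},
            noise={"sigma_e": 1.0, "sigma_clone": 0.0, "sigma_tclone": 0.0}, seed=21,
        )
        res = run_genomewide(expr, design)
        assert (res.genes["q_T"] < 0.05).mean() <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 5000)
        for origin in ("N", "S"):
            assert (res.region(origin)["q_T"] < 0.05).mean() <= 0.06

    def test_s_only_effects_concentrate_in_s_margin(self, design):
        """Genes plastic only in the South fill the (N:ns, S:up/down) cells."""
        expr, truth = generate_dataset(
            500,
            class_proportions={"null": 0.8, "gxe_baldwin": 0.2},
            effect_ranges={"gxe_baldwin": {"tau": (0.5, 0.5), "tau_gamma": (0.5, 0.5)}},
            noise={"sigma_e": 0.2, "sigma_clone": 0.0, "sigma_tclone": 0.0}, seed=22,
        )
        # tau = tau_gamma => Delta_N = 0 exactly, Delta_S = +-2
        res = run_genomewide(expr, design)
        rn, rs = res.region("N"), res.region("S")
        n_planted = int((truth.table["true_class"] == "gxe_baldwin").sum())
        s_called = (rs["direction"] != "ns").sum()
        # recovery is capped by the region pooling rate: unpooled genes face a
        # 1-df denominator that cannot reach BH significance
        assert s_called >= 0.75 * n_planted
        assert (rn["direction"] != "ns").mean() < 0.02

    def test_single_gene_pure_T_significant_both_regions(self, design):
        expr, _ = generate_dataset(
            200, class_proportions={"T_only": 1.0},
            effect_ranges={"T_only": {"tau": (1.0, 1.0)}},
            noise={"sigma_e": 0.1, "sigma_clone": 0.0, "sigma_tclone": 0.0}, seed=23,
        )
        res = run_genomewide(expr, design)
        rn, rs = res.region("N"), res.region("S")
        sign_match = np.sign(rn["delta"]) == np.sign(rs["delta"])
        called_both = (rn["direction"] != "ns") & (rs["direction"] != "ns")
        assert called_both.mean() > 0.95
        assert sign_match[called_both].all()

    def test_power_recovery_of_temperature_effects(self, design):
        """tau=1, sigma_e=0.25, sigma_clone=sigma_tclone=0.1: every planted
        temperature gene that pools is recovered at q < 0.05; overall
        recovery is capped by the pooling rate, because genes routed to the
        unpooled 2-df denominator cannot beat the BH threshold even with a
        large effect."""
        expr, truth = generate_dataset(
            5000, class_proportions={"null": 0.9, "T_only": 0.1},
            effect_ranges={"T_only": {"tau": (1.0, 1.0)}},
            noise={"sigma_e": 0.25, "sigma_clone": 0.1, "sigma_tclone": 0.1}, seed=24,
        )
        res = run_genomewide(expr, design)
        merged = res.genes.merge(truth.table[["gene_id", "true_class"]], on="gene_id")
        planted = merged[merged["true_class"] == "T_only"]
        pooled = planted[planted["pooled"]]
        assert (pooled["q_T"] < 0.05).mean() >= 0.99
        recovery = (planted["q_T"] < 0.05).mean()
        assert recovery >= planted["pooled"].mean() - 0.02

    def test_power_recovery_with_no_interaction_variance(self, design):
        """With sigma_tclone = 0 the pooling pre-test still diverts ~20% of
        genes (its calibrated false-alarm rate) to the powerless branch, so
        overall recovery sits near 80%, with full recovery among pooled genes."""
        expr, truth = generate_dataset(
            5000, class_proportions={"null": 0.9, "T_only": 0.1},
            effect_ranges={"T_only": {"tau": (1.0, 1.0)}},
            noise={"sigma_e": 0.25, "sigma_clone": 0.1, "sigma_tclone": 0.0}, seed=24,
        )
        res = run_genomewide(expr, design)
        merged = res.genes.merge(truth.table[["gene_id", "true_class"]], on="gene_id")
        planted = merged[merged["true_class"] == "T_only"]
        assert (planted.loc[planted["pooled"], "q_T"] < 0.05).mean() >= 0.99
        assert (planted["q_T"] < 0.05).mean() >= 0.75

    def test_constant_genes_carried_with_flags(self, design):
        expr, _ = generate_dataset(10, seed=25)
        vals = expr.values.copy()
        vals.iloc[0] = 5.0
        from gxe_acclim import ExpressionMatrix

        res = run_genomewide(ExpressionMatrix(vals), design)
        row = res.genes.iloc[0]
        assert row["constant"] and row["p_T"] == 1.0 and np.isnan(row["q_T"])
        # constant gene excluded from BH's m: remaining q finite
        assert res.genes["q_T"].iloc[1:].notna().all()
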