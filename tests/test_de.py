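"""Moderated time-course differential expression."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import floratime as ft
from floratime.containers import ExpressionMatrix, make_design
from floratime.de import (
    ModelFit,
    call_degs,
    fit_linear_model,
    global_f_test,
    moderate_variances,
    trigamma_inverse,
    window_pairs,
    windowed_contrasts,
)

from _oracles import groupwise_mean_var


def matrix_from_values(values, time_points, n_reps):
    """Build a one-gene-per-row ExpressionMatrix from a dense array."""
    design = make_design(time_points, n_reps)
    genes = pd.Index([f"g{i}" for i in range(len(values))], name="gene")
    return ExpressionMatrix(M=pd.DataFrame(values, index=genes, columns=design.index),
                            design=design)


class TestLinearFit:
    def test_coefficient_is_replicate_mean(self):
        em = matrix_from_values([[1.0, 0.0, 1.2, 0.0, 0.8, 0.0]], [0, 1], 3)
        fit = fit_linear_model(em)
        assert fit.coef.loc["g0", 0] == pytest.approx(1.0)

    def test_equal_replicates_zero_variance(self):
        em = matrix_from_values([[2.0, 1.0, 2.0, 1.0, 2.0, 1.0]], [0, 1], 3)
        fit = fit_linear_model(em)
        assert fit.s2["g0"] == pytest.approx(0.0)
        assert fit.df["g0"] == 4

    def test_matches_bruteforce_group_statistics(self, rng):
        tp = [0.0, 1.0, 3.0, 7.0]
        em = matrix_from_values(rng.normal(size=(40, 12)), tp, 3)
        fit = fit_linear_model(em)
        times = em.array_times().to_numpy()
        for g in em.genes:
            means, s2, df = groupwise_mean_var(em.M.loc[g].to_numpy(), times)
            for t in tp:
                assert fit.coef.loc[g, t] == pytest.approx(means[t], abs=1e-12)
            assert fit.s2[g] == pytest.approx(s2, abs=1e-12)
            assert fit.df[g] == df

    def test_untestable_genes_reported(self):
        em = matrix_from_values([[1.0, 2.0]], [0, 1], 1)  # single replicate
        fit = fit_linear_model(em)
        assert fit.untestable == ["g0"]


class TestModeration:
    def test_no_spread_limit_gives_prior_equal_to_common_value(self):
        em = matrix_from_values(
            np.tile([[0.0, 1.0, 0.0, -1.0, 0.0, 0.0]], (60, 1)), [0, 1], 3
        )
        mfit = moderate_variances(fit_linear_model(em))
        assert np.isinf(mfit.d0)
        common = fit_linear_model(em).s2.iloc[0]
        assert mfit.s0_sq == pytest.approx(common)
        np.testing.assert_allclose(mfit.s2_post, common)

    def test_shrinkage_bounds(self, rng):
        cfg = ft.SimConfig(n_genes=400, seed=3)
        expr, _ = ft.generate_timecourse(cfg)
        mfit = moderate_variances(fit_linear_model(expr))
        lo = np.minimum(mfit.s2, mfit.s0_sq)
        hi = np.maximum(mfit.s2, mfit.s0_sq)
        assert ((mfit.s2_post >= lo - 1e-12) & (mfit.s2_post <= hi + 1e-12)).all()
        # an outlier variance is pulled strictly between prior and itself
        big = mfit.s2.idxmax()
        assert mfit.s0_sq < mfit.s2_post[big] < mfit.s2[big]

    def test_hyperparameter_recovery_from_scaled_invchisq(self):
        """(d0, s0^2) recovered within 15 % on 5000 simulated variances."""
        d0, s0_sq, d_g, n = 4.0, 0.05, 20, 5000
        r = np.random.default_rng(101)
        s2 = s0_sq * sps.f.rvs(d_g, d0, size=n, random_state=r)
        genes = pd.Index([f"g{i}" for i in range(n)])
        fit = ModelFit(
            coef=pd.DataFrame(np.zeros((n, 2)), index=genes, columns=[0.0, 1.0]),
            n_per_group=pd.DataFrame(np.full((n, 2), (d_g + 2) // 2), index=genes,
                                     columns=[0.0, 1.0]),
            s2=pd.Series(s2, index=genes),
            df=pd.Series(float(d_g), index=genes),
            untestable=[],
        )
        mfit = moderate_variances(fit)
        assert mfit.d0 == pytest.approx(d0, rel=0.15)
        assert mfit.s0_sq == pytest.approx(s0_sq, rel=0.15)

    def test_all_zero_variances_rejected(self):
        em = matrix_from_values(np.tile([[1.0, 2.0, 1.0, 2.0]], (60, 1)), [0, 1], 2)
        with pytest.raises(ValueError, match="zero"):
            moderate_variances(fit_linear_model(em))

    def test_trigamma_inverse_roundtrip(self):
        from scipy.special import polygamma

        for y in (1e-5, 0.01, 0.5, 2.0, 1e6):
            x = trigamma_inverse(y)
            assert float(polygamma(1, x)) == pytest.approx(y, rel=1e-6)


class TestGlobalF:
    def test_flat_gene_has_zero_f(self):
        # g0: identical coefficients at both time-points (within-group noise only)
        em_flat = matrix_from_values([[0.9, 0.9, 1.0, 1.0, 1.1, 1.1]], [0, 1], 3)
        tab = global_f_test(moderate_variances_ok(em_flat))
        assert tab.loc["g0", "F"] == pytest.approx(0.0)
        assert tab.loc["g0", "pvalue"] == pytest.approx(1.0)

    def test_null_pvalues_uniform(self):
        """Flat archetypes (fc_scale = 0): raw F p-values are uniform."""
        cfg = ft.SimConfig(n_genes=2000, fc_scale=0.0, seed=51)
        expr, _ = ft.generate_timecourse(cfg)
        ftab = ft.TimecourseDE(expr).fit().f_test()
        ks = sps.kstest(ftab["pvalue"], "uniform")
        assert ks.pvalue > 0.01

    def test_large_shift_detected(self):
        cfg = ft.SimConfig(n_genes=500, fc_scale=0.0, noise_prior=(np.inf, 0.04), seed=52)
        expr, _ = ft.generate_timecourse(cfg)
        expr.M.iloc[0, expr.array_times().to_numpy() == 13.0] += 10 * 0.2
        ftab = ft.TimecourseDE(expr).fit().f_test()
        assert ftab["padj"].iloc[0] < 1e-6


class TestWindowedContrasts:
    def test_pair_enumeration_on_sparse_grid(self):
        grid = [0, 1, 2, 3, 4, 5, 7, 9, 11, 13]
        pairs = window_pairs(grid, 2.0)
        want = [(0, 1), (0, 2), (1, 2), (1, 3), (2, 3), (2, 4), (3, 4), (3, 5),
                (4, 5), (5, 7), (7, 9), (9, 11), (11, 13)]
        assert [(int(a), int(b)) for a, b in pairs] == want
        assert len(pairs) == 13

    def test_zero_window_empty_table(self, de_results):
        table = windowed_contrasts(de_results.fit_, window=0.0)
        assert len(table) == 0

    def test_negative_window_rejected(self, de_results):
        with pytest.raises(ValueError):
            windowed_contrasts(de_results.fit_, window=-1.0)

    def test_equal_coefficients_give_t_zero_p_one(self):
        # both time-point means are 1.0 -> the contrast is exactly null
        em = matrix_from_values([[1.0, 1.0, 0.8, 0.8, 1.2, 1.2]], [0, 1], 3)
        table = windowed_contrasts(moderate_variances_ok(em), window=2.0)
        row = table[table.gene == "g0"].iloc[0]
        assert row["t"] == pytest.approx(0.0)
        assert row["pvalue"] == pytest.approx(1.0)


def moderate_variances_ok(em):
    """Moderation for tiny fixtures: pad with noise genes so the prior fits."""
    rng = np.random.default_rng(0)
    extra = pd.DataFrame(
        rng.normal(0, 0.3, size=(80, em.M.shape[1])),
        index=pd.Index([f"pad{i}" for i in range(80)], name="gene"),
        columns=em.M.columns,
    )
    big = ExpressionMatrix(M=pd.concat([em.M, extra]), design=em.design)
    return moderate_variances(fit_linear_model(big))


class TestCallDegs:
    def make_table(self, padj, lfc):
        return pd.DataFrame(
            {"gene": ["g"], "time_i": [0.0], "time_j": [1.0], "log2fc": [lfc],
             "t": [1.0], "pvalue": [padj], "padj": [padj]}
        )

    def test_passing_both_thresholds(self):
        out = call_degs(self.make_table(0.005, np.log2(1.8)))
        assert bool(out.loc["g", "is_deg"])

    def test_fold_change_below_cutoff(self):
        out = call_degs(self.make_table(0.005, np.log2(1.6)))
        assert not bool(out.loc["g", "is_deg"])

    def test_fold_change_threshold_inclusive(self):
        """FC exactly 1.7 with adjusted p 0.009 is called ('1.7 or greater')."""
        out = call_degs(self.make_table(0.009, np.log2(1.7)))
        assert bool(out.loc["g", "is_deg"])

    def test_direction_follows_best_contrast_sign(self):
        out = call_degs(self.make_table(0.001, -1.0))
        assert out.loc["g", "direction"] == "down"

    def test_monotone_in_thresholds(self, de_results):
        """Lowering alpha or raising fc_min never adds DEGs."""
        ct = de_results.windowed_contrasts()
        base = set(call_degs(ct, 0.01, 1.7).query("is_deg").index)
        stricter_alpha = set(call_degs(ct, 0.001, 1.7).query("is_deg").index)
        stricter_fc = set(call_degs(ct, 0.01, 2.5).query("is_deg").index)
        assert stricter_alpha <= base
        assert stricter_fc <= base


class TestModelResultsSurface:
    def test_summary_mentions_key_quantities(self, de_results):
        text = de_results.summary()
        assert "prior df" in text and "DEGs" in text

    def test_per_contrast_pooling_option(self, de_results):
        g = windowed_contrasts(de_results.fit_, pooling="global")
        p = windowed_contrasts(de_results.fit_, pooling="per_contrast")
        assert len(g) == len(p)
        assert not np.allclose(g["padj"], p["padj"])

    def test_from_dataframe_constructor(self, sim_small):
        _, expr, _ = sim_small
        res = ft.TimecourseDE.from_dataframe(expr.M, expr.design).fit()
        assert res.d0 > 0
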