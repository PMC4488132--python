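"""Synthetic-study generator: determinism, planted structure, raw arrays."""

import numpy as np
import pandas as pd
import pytest

import floratime as ft
from floratime.preprocess import background_subtract, compute_ma
from floratime.simulate import (
    archetype_profiles,
    default_plan,
    dye_bias_shape,
    simulate_proteome,
)


class TestConfigValidation:
    def test_rejects_non_increasing_time_grid(self):
        with pytest.raises(ValueError, match="increasing"):
            ft.SimConfig(time_points=(0, 1, 1, 2))

    @pytest.mark.parametrize("kw", [{"frac_de": 0.0}, {"frac_de": 1.5},
                                    {"n_genes": 0}, {"n_archetypes": 0}])
    def test_rejects_bad_counts_and_fractions(self, kw):
        with pytest.raises(ValueError):
            ft.SimConfig(**kw)


class TestTimecourse:
    def test_seed_determinism(self):
        cfg = ft.SimConfig(n_genes=120, seed=42)
        e1, t1 = ft.generate_timecourse(cfg)
        e2, t2 = ft.generate_timecourse(cfg)
        pd.testing.assert_frame_equal(e1.M, e2.M)
        pd.testing.assert_frame_equal(t1.table, t2.table)

    def test_zero_noise_limit_replicates_identical(self):
        cfg = ft.SimConfig(n_genes=60, noise_prior=(np.inf, 0.0), seed=5)
        expr, truth = ft.generate_timecourse(cfg)
        r1 = expr.replicate_matrix(1)
        for r in (2, 3):
            np.testing.assert_allclose(expr.replicate_matrix(r).to_numpy(), r1.to_numpy())
        np.testing.assert_allclose(r1.to_numpy(), truth.profiles.loc[r1.index].to_numpy())

    def test_flat_genes_have_zero_profile(self, sim_small):
        _, _, truth = sim_small
        flat = truth.table.index[~truth.table.is_de]
        assert (truth.profiles.loc[flat].to_numpy() == 0).all()
        assert (truth.table.is_de == (truth.table.archetype != 0)).all()

    def test_frac_de_realised(self):
        cfg = ft.SimConfig(n_genes=2000, frac_de=0.3, seed=9)
        _, truth = ft.generate_timecourse(cfg)
        assert int(truth.table.is_de.sum()) == round(0.3 * 2000)

    def test_variance_law_of_large_numbers(self):
        """Empirical per-gene variance approaches the drawn sigma^2 (200 reps)."""
        cfg = ft.SimConfig(n_genes=40, time_points=(0.0, 1.0), n_replicates=200, seed=13)
        expr, truth = ft.generate_timecourse(cfg)
        times = expr.array_times().to_numpy()
        emp = np.zeros(len(expr.genes))
        df = 0
        for t in np.unique(times):
            block = expr.M.loc[:, times == t].to_numpy()
            emp += ((block - block.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
            df += block.shape[1] - 1
        emp /= df
        rel = np.abs(emp / truth.table.sigma2.to_numpy() - 1)
        assert np.mean(rel) < 0.10
        assert np.corrcoef(emp, truth.table.sigma2)[0, 1] > 0.95

    def test_archetypes_are_centred_unit_peak(self):
        prof = archetype_profiles(ft.simulate.DEFAULT_TIME_GRID, 15)
        np.testing.assert_allclose(prof.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(np.abs(prof).max(axis=1), 1, atol=1e-12)


class TestRawTwoChannel:
    def test_identity_configuration_roundtrip(self):
        """One probe/gene, no background, no bias, no probe noise -> exact M."""
        cfg = ft.SimConfig(n_genes=80, seed=21)
        expr, truth = ft.generate_timecourse(cfg)
        raw = ft.generate_raw_two_channel(
            cfg, truth, expr, probes_per_gene=1, background_level=0.0,
            bias_amplitude=0.0, probe_noise_sd=0.0, n_negative_controls=10,
        )
        M, _ = compute_ma(background_subtract(raw))
        gene_M = M.loc[~raw.is_control.to_numpy()]
        gene_M.index = [p[:-3] for p in gene_M.index]  # strip _p1
        np.testing.assert_allclose(
            gene_M.loc[expr.genes].to_numpy(), expr.M.to_numpy(), atol=1e-9
        )

    def test_negative_controls_sit_below_gene_probes(self):
        cfg = ft.SimConfig(n_genes=150, seed=22)
        expr, truth = ft.generate_timecourse(cfg)
        raw = ft.generate_raw_two_channel(cfg, truth, expr)
        corrected = background_subtract(raw)
        ctl = corrected.red_fg.loc[raw.is_control.to_numpy()].to_numpy()
        gene = corrected.red_fg.loc[~raw.is_control.to_numpy()].to_numpy()
        assert np.nanmean(ctl) < np.nanpercentile(gene, 5)

    def test_dye_bias_slope_recovered_on_null_genes(self):
        cfg = ft.SimConfig(n_genes=400, frac_de=0.25, seed=23)
        expr, truth = ft.generate_timecourse(cfg)
        b = 0.4
        raw = ft.generate_raw_two_channel(
            cfg, truth, expr, bias_amplitude=b, probe_noise_sd=0.0,
            background_level=0.0,
        )
        M, A = compute_ma(background_subtract(raw))
        null_genes = set(truth.table.index[~truth.table.is_de])
        rows = raw.probe_gene.isin(null_genes).to_numpy()
        x = dye_bias_shape(A.loc[rows].to_numpy().ravel())
        y = M.loc[rows].to_numpy().ravel()
        slope = np.polyfit(x, y, 1)[0]
        assert slope == pytest.approx(b, rel=0.10)

    def test_seed_determinism(self, sim_small):
        cfg, expr, truth = sim_small
        r1 = ft.generate_raw_two_channel(cfg, truth, expr)
        r2 = ft.generate_raw_two_channel(cfg, truth, expr)
        pd.testing.assert_frame_equal(r1.red_fg, r2.red_fg)


class TestAnnotations:
    def test_null_planting_is_homogeneous(self):
        cfg = ft.SimConfig(n_genes=3000, frac_de=0.75, n_archetypes=5, seed=31)
        _, truth = ft.generate_timecourse(cfg)
        plan = ft.AnnotationPlan(bound_layers={"NULL": ft.LayerPlan(0.2, {})})
        ann = ft.generate_annotations(cfg, truth, plan)
        fracs = [
            np.mean([g in ann.bound_sets["NULL"] for g in truth.table.index[truth.table.cluster == c]])
            for c in range(1, 6)
        ]
        assert max(fracs) - min(fracs) < 0.05

    def test_planted_odds_ratio_realised(self):
        """Empirical OR within 25 % of the request for clusters >= 200 genes."""
        cfg = ft.SimConfig(n_genes=4000, frac_de=0.75, n_archetypes=10, seed=32)
        _, truth = ft.generate_timecourse(cfg)
        plan = ft.AnnotationPlan(bound_layers={"L": ft.LayerPlan(0.1, {1: 4.0, 2: 4.0})})
        ann = ft.generate_annotations(cfg, truth, plan)
        bound = ann.bound_sets["L"]
        for c in (1, 2):
            members = truth.table.index[truth.table.cluster == c]
            rest = truth.table.index[truth.table.cluster != c]
            p1 = np.mean([g in bound for g in members])
            p0 = np.mean([g in bound for g in rest])
            orat = (p1 / (1 - p1)) / (p0 / (1 - p0))
            assert 4.0 * 0.75 < orat < 4.0 * 1.25

    def test_infeasible_odds_ratio_names_layer(self, sim_small):
        cfg, _, truth = sim_small
        plan = ft.AnnotationPlan(bound_layers={"BAD": ft.LayerPlan(0.1, {1: np.inf})})
        with pytest.raises(ValueError, match="BAD"):
            ft.generate_annotations(cfg, truth, plan)

    def test_family_pairwise_identity(self, rng):
        fams = [["a", "b", "c"]]
        prot = simulate_proteome(["a", "b", "c"], fams, identity=0.95, rng=rng,
                                 length_range=(200, 200))
        for x, y in (("a", "b"), ("a", "c"), ("b", "c")):
            ident = np.mean([u == v for u, v in zip(prot[x], prot[y])])
            assert ident >= 0.9

    def test_planted_cluster_peaks_in_designated_tissue(self, sim_annotated):
        cfg, _, truth, ann = sim_annotated
        for cid, tissue in list(ann.tissue_of_cluster.items())[:5]:
            members = [g for g in truth.table.index[truth.table.cluster == cid]
                       if g in ann.atlas.index]
            hits = np.mean([ann.atlas.loc[g].idxmax() == tissue for g in members])
            assert hits > 0.9

    def test_truth_table_extended_with_layers(self, sim_annotated):
        _, _, truth, ann = sim_annotated
        assert "paralog_family" in truth.table.columns
        assert any(col.startswith("bound_") for col in truth.table.columns)
        # family ids partition their members
        fam = truth.table.paralog_family
        for fid, members in ann.paralog_families.items():
            assert set(fam.index[fam == fid]) == set(members)
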