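"""Peak-to-gene assignment, the resampling enrichment null, term enrichment."""

import numpy as np
import pandas as pd
import pytest

from floratime.setscan import (
    GeneModel,
    GenomicInterval,
    assign_peaks_to_genes,
    go_enrichment,
    list_overlap_test,
    resampling_set_enrichment,
)

from _oracles import hypergeom_mean_sd


# ----------------------------------------------------------------------
# strand-aware regulatory window (-3 kb / +1 kb)
# ----------------------------------------------------------------------
GENES = [
    GeneModel("gplus", "c1", 10000, 12000, "+"),
    GeneModel("gminus", "c1", 30000, 32000, "-"),
    GeneModel("gplus_edge", "c2", 1000, 2000, "+"),     # window clipped at 0
    GeneModel("gminus_edge", "c2", 50000, 52000, "-"),
    GeneModel("gplus_far", "c3", 100000, 102000, "+"),
    GeneModel("gother", "c9", 10000, 12000, "+"),       # different chromosome
]


class TestPeakAssignment:
    @pytest.mark.parametrize(
        "peak,expected",
        [
            (GenomicInterval("c1", 8000, 8500), {"gplus"}),        # 2 kb upstream, + strand
            (GenomicInterval("c1", 13500, 13600), set()),          # > 1 kb downstream of gplus
            (GenomicInterval("c1", 12500, 12900), {"gplus"}),      # within +1 kb downstream
            (GenomicInterval("c1", 33500, 33600), {"gminus"}),     # upstream on - strand
            (GenomicInterval("c1", 6500, 6900), set()),            # ends 3.1 kb upstream
            (GenomicInterval("c1", 6990, 7000), set()),            # abuts window edge (half-open)
            (GenomicInterval("c1", 6990, 7001), {"gplus"}),        # one bp inside the window
            (GenomicInterval("c1", 28500, 28900), set()),          # 1.1 kb 5' of gminus *end* rule
        ],
    )
    def test_window_rule(self, peak, expected):
        assert set(assign_peaks_to_genes([peak], GENES).genes) == expected

    def test_minus_strand_downstream_side(self):
        # for '-' genes the window is [start - 1 kb, end + 3 kb)
        assert set(assign_peaks_to_genes([GenomicInterval("c1", 29200, 29300)], GENES).genes) == {
            "gminus"
        }

    def test_one_peak_annotates_multiple_genes(self):
        genes = [
            GeneModel("a", "c1", 10000, 12000, "+"),
            GeneModel("b", "c1", 13000, 15000, "+"),
        ]
        peak = GenomicInterval("c1", 12100, 12300)  # downstream of a, upstream of b
        assert set(assign_peaks_to_genes([peak], genes).genes) == {"a", "b"}

    def test_window_clipped_at_zero(self):
        assert "gplus_edge" in assign_peaks_to_genes(
            [GenomicInterval("c2", 0, 100)], GENES
        )

    def test_chromosome_namespace_respected(self):
        assert "gother" not in assign_peaks_to_genes(
            [GenomicInterval("c1", 8000, 8500)], GENES
        )

    def test_invariant_under_peak_order_and_splitting(self):
        peaks = [
            GenomicInterval("c1", 8000, 8500),
            GenomicInterval("c1", 33500, 33600),
            GenomicInterval("c3", 99000, 99500),
        ]
        a = assign_peaks_to_genes(peaks, GENES)
        b = assign_peaks_to_genes(list(reversed(peaks)), GENES)
        halves = [
            GenomicInterval("c1", 8000, 8250), GenomicInterval("c1", 8250, 8500),
            GenomicInterval("c1", 33500, 33550), GenomicInterval("c1", 33550, 33600),
            GenomicInterval("c3", 99000, 99250), GenomicInterval("c3", 99250, 99500),
        ]
        c = assign_peaks_to_genes(halves, GENES)
        assert a.genes == b.genes == c.genes

    def test_malformed_interval_rejected(self):
        with pytest.raises(ValueError, match="malformed"):
            GenomicInterval("c1", 500, 500)


# ----------------------------------------------------------------------
# resampling null
# ----------------------------------------------------------------------
class TestResampling:
    universe = [f"g{i}" for i in range(1000)]

    def test_saturated_annotation_degenerate(self):
        res = resampling_set_enrichment({1: self.universe[:50]}, self.universe,
                                        self.universe, seed=0)
        row = res.loc[1]
        assert row.p_obs == 1.0 and row.null_mean == 1.0 and row.null_sd == 0.0
        assert not row.significant and row.degenerate

    def test_empty_annotation_not_significant(self):
        res = resampling_set_enrichment({1: self.universe[:50]}, [], self.universe, seed=0)
        assert res.loc[1].p_obs == 0.0 and not res.loc[1].significant

    def test_planted_enrichment_flagged_with_analytic_z(self):
        """60 % annotated cluster vs 10 % universe: z near the hypergeometric value."""
        rng = np.random.default_rng(1)
        universe = [f"g{i}" for i in range(5000)]
        cluster = universe[:300]
        annot = set(cluster[:180]) | set(rng.choice(universe[300:], 470, replace=False))
        res = resampling_set_enrichment({1: cluster}, annot, universe, n_iter=100, seed=2)
        _, sd = hypergeom_mean_sd(5000, len(annot), 300)
        z_expected = (0.6 - len(annot) / 5000) / sd
        assert res.loc[1].significant and res.loc[1].direction == "enriched"
        assert res.loc[1].z == pytest.approx(z_expected, rel=0.3)

    def test_null_matches_hypergeometric_moments(self):
        universe = [f"g{i}" for i in range(2000)]
        annot = set(universe[:200])
        res = resampling_set_enrichment({1: universe[-300:]}, annot, universe,
                                        n_iter=100, seed=3)
        mean, sd = hypergeom_mean_sd(2000, 200, 300)
        assert abs(res.loc[1].null_mean - mean) < 3 * sd / np.sqrt(100)
        assert res.loc[1].null_sd == pytest.approx(sd, rel=0.25)

    def test_depletion_direction(self):
        universe = [f"g{i}" for i in range(2000)]
        annot = set(universe[500:])  # cluster drawn from unannotated genes
        res = resampling_set_enrichment({1: universe[:300]}, annot, universe, seed=4)
        assert res.loc[1].direction == "depleted" and res.loc[1].significant

    def test_cluster_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside the universe"):
            resampling_set_enrichment({1: ["zzz"]}, [], self.universe, seed=0)

    def test_cluster_exceeding_universe_rejected(self):
        # a cluster bigger than the universe necessarily has genes outside it
        with pytest.raises(ValueError):
            resampling_set_enrichment({1: self.universe}, [], self.universe[:10], seed=0)

    def test_seed_determinism(self):
        a = resampling_set_enrichment({1: self.universe[:100]}, self.universe[:50],
                                      self.universe, seed=5)
        b = resampling_set_enrichment({1: self.universe[:100]}, self.universe[:50],
                                      self.universe, seed=5)
        pd.testing.assert_frame_equal(a, b)


# ----------------------------------------------------------------------
# term enrichment and list overlap
# ----------------------------------------------------------------------
class TestTermEnrichment:
    def test_enriched_term_found(self):
        universe = [f"g{i}" for i in range(100)]
        cluster = universe[:20]
        term_map = {"hit": set(cluster[:15]), "miss": set(universe[50:60])}
        out = go_enrichment(cluster, universe, term_map, alpha=0.05)
        assert bool(out.loc["hit", "significant"])
        assert not bool(out.loc["miss", "significant"])
        assert (out["padj"] >= out["pvalue"] - 1e-15).all()

    def test_disjoint_term_p_one(self):
        universe = [f"g{i}" for i in range(40)]
        out = go_enrichment(universe[:10], universe, {"t": set(universe[20:30])})
        assert out.loc["t", "pvalue"] == pytest.approx(1.0)

    def test_zero_universe_terms_skipped(self):
        universe = [f"g{i}" for i in range(40)]
        out = go_enrichment(universe[:10], universe, {"ghost": {"nope"}})
        assert out.attrs["skipped_terms"] == ["ghost"]

    def test_by_adjustment_used(self):
        universe = [f"g{i}" for i in range(60)]
        term_map = {f"t{i}": set(universe[i * 5:(i + 1) * 5]) for i in range(4)}
        out = go_enrichment(universe[:15], universe, term_map)
        from floratime.stats import adjust_pvalues

        by = adjust_pvalues(out["pvalue"].to_numpy(), method="by")
        np.testing.assert_allclose(out["padj"].to_numpy(), by)


class TestListOverlap:
    def test_expected_and_tail(self):
        from math import comb

        universe = [f"g{i}" for i in range(100)]
        res = list_overlap_test(universe[:10], universe[9:19], universe)
        assert res.overlap == 1
        assert res.expected == pytest.approx(1.0)
        assert res.pvalue == pytest.approx(1 - comb(90, 10) / comb(100, 10), rel=1e-9)

    def test_disjoint_lists_large_p(self):
        universe = [f"g{i}" for i in range(100)]
        res = list_overlap_test(universe[:10], universe[50:60], universe)
        assert res.pvalue >= 0.5

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            list_overlap_test([], [], [])
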