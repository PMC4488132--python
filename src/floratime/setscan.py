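"""Gene-set machinery: peak-to-gene assignment, the resampling enrichment
null, Fisher/BY term enrichment and generic gene-list overlap tests.

The resampling null asks, for each cluster of co-expressed genes, whether
the fraction of its members carrying an annotation (bound by a
transcription factor, having a paralog, ...) is unusual compared with
equally sized random gene sets drawn from a reference universe; clusters
beyond three standard deviations of the random draws are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .stats import adjust_pvalues, fisher_enrichment_p, hypergeom_overlap, OverlapResult

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "GeneSet",
    "assign_peaks_to_genes",
    "resampling_set_enrichment",
    "go_enrichment",
    "list_overlap_test",
]


@dataclass(frozen=True)
class GenomicInterval:
    """0-based, half-open genomic interval (BED dialect)."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"malformed interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )


@dataclass(frozen=True)
class GeneModel:
    """Transcribed region of a gene, 0-based half-open, with strand."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"gene {self.gene_id}: need 0 <= start < end")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")

    def regulatory_window(self, upstream: int, downstream: int) -> tuple:
        """Half-open window from ``upstream`` bp 5' of the transcribed region
        to ``downstream`` bp 3' of it, clipped at zero."""
        if self.strand == "+":
            lo, hi = self.start - upstream, self.end + downstream
        else:
            lo, hi = self.start - downstream, self.end + upstream
        return max(lo, 0), hi


@dataclass(frozen=True)
class GeneSet:
    label: str
    genes: frozenset

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(self.genes))

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, g) -> bool:
        return g in self.genes


def assign_peaks_to_genes(
    peaks: Iterable[GenomicInterval],
    genes: Iterable[GeneModel],
    upstream: int = 3000,
    downstream: int = 1000,
    label: str = "bound",
) -> GeneSet:
    """Genes whose regulatory window overlaps at least one peak.

    The window runs from ``upstream`` bp 5' of the transcribed region to
    ``downstream`` bp 3' of it (strand-aware, half-open overlap, clipped at
    zero); a peak may annotate several genes.
    """
    peaks = list(peaks)
    by_chrom: dict = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append((p.start, p.end))
    for chrom in by_chrom:
        arr = np.array(by_chrom[chrom])
        by_chrom[chrom] = (arr[:, 0], arr[:, 1])
    bound = set()
    for gm in genes:
        if gm.chrom not in by_chrom:
            continue
        lo, hi = gm.regulatory_window(upstream, downstream)
        starts, ends = by_chrom[gm.chrom]
        if np.any((starts < hi) & (ends > lo)):  # half-open overlap
            bound.add(gm.gene_id)
    return GeneSet(label=label, genes=frozenset(bound))


def resampling_set_enrichment(
    clusters: Mapping[int, Iterable[str]],
    annot: Iterable[str],
    universe: Iterable[str],
    n_iter: int = 100,
    seed: int | None = None,
    sd_mult: float = 3.0,
) -> pd.DataFrame:
    """Monte-Carlo enrichment of an annotated gene set within each cluster.

    For each cluster of size ``n_c`` the observed annotated fraction is
    compared with the fractions in ``n_iter`` random draws of ``n_c`` genes
    (without replacement) from ``universe``.  A cluster is flagged
    significant when ``|p_obs - mean| > sd_mult * sd``; ``z`` is reported for
    threshold-minded users, with sign giving enrichment vs. depletion.
    Degenerate nulls (``sd == 0``) are never significant and are flagged as
    such.
    """
    if n_iter < 2:
        raise ValueError("n_iter must be >= 2")
    universe = pd.Index(pd.unique(pd.Series(list(universe))))
    annot_set = set(annot)
    annot_mask = universe.isin(annot_set)
    rng = np.random.default_rng(seed)
    rows = []
    for cid in sorted(clusters):
        members = pd.Index(pd.unique(pd.Series(list(clusters[cid]))))
        outside = members.difference(universe)
        if len(outside):
            raise ValueError(
                f"cluster {cid}: genes outside the universe, e.g. {list(outside[:3])}"
            )
        n_c = len(members)
        if n_c == 0:
            continue
        if n_c > len(universe):
            raise ValueError(f"cluster {cid} larger than the universe")
        p_obs = sum(g in annot_set for g in members) / n_c
        draws = np.empty(n_iter)
        for it in range(n_iter):
            idx = rng.choice(len(universe), size=n_c, replace=False)
            draws[it] = annot_mask[idx].mean()
        mu = float(draws.mean())
        sd = float(draws.std(ddof=1))
        degenerate = sd == 0.0
        z = (p_obs - mu) / sd if sd > 0 else 0.0
        significant = (not degenerate) and abs(p_obs - mu) > sd_mult * sd
        rows.append(
            {
                "cluster": cid,
                "n": n_c,
                "p_obs": p_obs,
                "null_mean": mu,
                "null_sd": sd,
                "z": z,
                "significant": significant,
                "direction": "enriched" if p_obs >= mu else "depleted",
                "degenerate": degenerate,
                "n_iter": n_iter,
            }
        )
    out = pd.DataFrame(rows).set_index("cluster")
    out.attrs["seed"] = seed
    out.attrs["sd_mult"] = sd_mult
    out.attrs["universe_size"] = len(universe)
    return out


def go_enrichment(
    cluster_genes: Iterable[str],
    universe: Iterable[str],
    term_map: Mapping[str, Iterable[str]],
    alpha: float = 0.05,
    alternative: str = "greater",
) -> pd.DataFrame:
    """Per-term Fisher exact enrichment with Benjamini–Yekutieli adjustment.

    Terms are first intersected with the universe; terms with zero universe
    members are skipped and reported in ``result.attrs['skipped_terms']``.
    Significance: BY-adjusted p < ``alpha``.
    """
    universe = set(universe)
    cluster = set(cluster_genes)
    if not cluster <= universe:
        raise ValueError("cluster genes must be a subset of the universe")
    n_u, n_c = len(universe), len(cluster)
    rows, skipped = [], []
    for term, members in term_map.items():
        members = set(members) & universe
        if not members:
            skipped.append(term)
            continue
        a = len(cluster & members)
        b = n_c - a
        c = len(members) - a
        d = n_u - n_c - c
        odds = (a * d) / (b * c) if b * c > 0 else np.inf
        p = float(fisher_enrichment_p(a, b, c, d, alternative=alternative))
        rows.append(
            {
                "term": term,
                "n_cluster_annot": a,
                "n_cluster": n_c,
                "n_universe_annot": len(members),
                "n_universe": n_u,
                "odds_ratio": odds,
                "pvalue": p,
            }
        )
    if rows:
        out = pd.DataFrame(rows).set_index("term")
        out["padj"] = adjust_pvalues(out["pvalue"].to_numpy(), method="by")
        out["significant"] = out["padj"] < alpha
        out = out.sort_values("padj")
    else:
        out = pd.DataFrame(
            columns=[
                "n_cluster_annot", "n_cluster", "n_universe_annot", "n_universe",
                "odds_ratio", "pvalue", "padj", "significant",
            ]
        )
    out.attrs["skipped_terms"] = skipped
    return out


def list_overlap_test(list_a, list_b, universe) -> OverlapResult:
    """Significance of the overlap of two gene lists within a universe.

    Upper-tail hypergeometric p for an overlap at least as large as
    observed; the expected overlap under independence is |A|*|B|/|U|.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    a = set(list_a)
    b = set(list_b)
    if not (a <= universe and b <= universe):
        raise ValueError("both lists must be subsets of the universe")
    return hypergeom_overlap(len(a & b), len(a), len(b), len(universe))
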