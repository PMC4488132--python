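"""Mapping co-expression clusters onto a tissue expression atlas.

For every cluster the table reports which tissue group holds each member
gene's expression maximum (and, for comparison, minimum), as percentages of
the cluster's atlas-covered, untied genes.  Genes absent from the atlas and
genes whose extreme value is tied across tissues are tallied separately
rather than attributed to an arbitrary tissue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["TissueExtremeTable", "group_atlas_samples", "map_extreme_tissue"]


@dataclass
class TissueExtremeTable:
    """Per cluster x tissue group: % of genes with their max / min there."""

    max_pct: pd.DataFrame      # clusters x tissue groups
    min_pct: pd.DataFrame
    covered: pd.Series         # untied, atlas-covered genes per cluster
    absent: pd.Series          # cluster genes missing from the atlas
    ties_max: pd.Series
    ties_min: pd.Series

    def top_tissue(self, cluster_id: int, which: str = "max") -> str:
        row = (self.max_pct if which == "max" else self.min_pct).loc[cluster_id]
        return row.idxmax()


def group_atlas_samples(
    atlas: pd.DataFrame, sample_to_group, reducer: str = "mean"
) -> pd.DataFrame:
    """Collapse individual atlas samples into tissue groups (mean per group)."""
    mapping = pd.Series(sample_to_group)
    unmapped = [c for c in atlas.columns if c not in mapping.index]
    if unmapped:
        raise ValueError(f"samples without a group: {unmapped[:5]}")
    if reducer != "mean":
        raise ValueError("only the 'mean' reducer is supported")
    return atlas.T.groupby(mapping.reindex(atlas.columns).to_numpy()).mean().T


def map_extreme_tissue(clusters, atlas: pd.DataFrame) -> TissueExtremeTable:
    """Locate each cluster gene's highest- and lowest-expressing tissue group.

    ``clusters`` is a mapping cluster id -> gene list (or a
    ``ClusterAssignment``).  Percentages are over covered, untied genes;
    clusters with zero atlas coverage are reported empty with a warning.
    """
    if hasattr(clusters, "as_dict"):
        clusters = clusters.as_dict()
    if atlas.shape[1] < 2:
        raise ValueError("atlas needs >= 2 tissue groups")
    tissues = atlas.columns
    cluster_ids = sorted(clusters)
    max_pct = pd.DataFrame(0.0, index=cluster_ids, columns=tissues)
    min_pct = pd.DataFrame(0.0, index=cluster_ids, columns=tissues)
    covered_n = pd.Series(0, index=cluster_ids, dtype=int)
    absent_n = pd.Series(0, index=cluster_ids, dtype=int)
    ties_max_n = pd.Series(0, index=cluster_ids, dtype=int)
    ties_min_n = pd.Series(0, index=cluster_ids, dtype=int)

    vals_all = atlas.to_numpy()
    row_of = {g: i for i, g in enumerate(atlas.index)}
    for cid in cluster_ids:
        genes = list(clusters[cid])
        rows = [row_of[g] for g in genes if g in row_of]
        absent_n[cid] = len(genes) - len(rows)
        if not rows:
            warnings.warn(f"cluster {cid}: no genes covered by the atlas", stacklevel=2)
            continue
        vals = vals_all[rows]
        finite = np.isfinite(vals).all(axis=1)
        vals = vals[finite]
        absent_n[cid] += int((~finite).sum())
        if vals.shape[0] == 0:
            warnings.warn(f"cluster {cid}: no genes covered by the atlas", stacklevel=2)
            continue
        vmax = vals.max(axis=1)
        vmin = vals.min(axis=1)
        tie_max = (vals == vmax[:, None]).sum(axis=1) > 1
        tie_min = (vals == vmin[:, None]).sum(axis=1) > 1
        ties_max_n[cid] = int(tie_max.sum())
        ties_min_n[cid] = int(tie_min.sum())
        ok_max = ~tie_max
        ok_min = ~tie_min
        covered_n[cid] = int(ok_max.sum())
        if ok_max.any():
            counts = np.bincount(vals[ok_max].argmax(axis=1), minlength=len(tissues))
            max_pct.loc[cid] = 100.0 * counts / ok_max.sum()
        if ok_min.any():
            counts = np.bincount(vals[ok_min].argmin(axis=1), minlength=len(tissues))
            min_pct.loc[cid] = 100.0 * counts / ok_min.sum()
    return TissueExtremeTable(
        max_pct=max_pct, min_pct=min_pct, covered=covered_n, absent=absent_n,
        ties_max=ties_max_n, ties_min=ties_min_n,
    )
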