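"""Co-expression clustering of differentially expressed genes.

Profiles are replicate-averaged per time-point and z-scored across
time-points per gene (shape, not level), then grouped by Euclidean k-means.
The elbow curve (explained variance BSS/TSS over a k range) carries an
automated maximum-distance-to-chord suggestion, but the suggestion is
advisory: the number of clusters remains an explicit user choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .containers import ExpressionMatrix

__all__ = ["ScaledProfileMatrix", "ClusterAssignment", "ElbowCurve",
           "zscore_profiles", "kmeans_cluster", "elbow_curve"]


@dataclass
class ScaledProfileMatrix:
    """Gene x time-point z-score profiles (each row mean 0, SD 1, ddof=1)."""

    profiles: pd.DataFrame
    dropped: list = field(default_factory=list)  # constant-profile genes

    @property
    def genes(self) -> pd.Index:
        return self.profiles.index

    def to_numpy(self) -> np.ndarray:
        return self.profiles.to_numpy()


@dataclass
class ClusterAssignment:
    """Gene -> cluster id in 1..k, labels ordered by descending cluster size."""

    labels: pd.Series              # gene -> cluster id
    centroids: pd.DataFrame        # cluster id x time-point mean z-profile
    k: int
    bss_tss: float
    seed: int | None
    n_init: int

    def members(self, cluster_id: int) -> pd.Index:
        return self.labels.index[self.labels == cluster_id]

    def as_dict(self) -> dict:
        return {int(c): self.members(int(c)).tolist() for c in range(1, self.k + 1)}

    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


def zscore_profiles(matrix: ExpressionMatrix, genes) -> ScaledProfileMatrix:
    """Replicate-average per time-point, then z-score each gene across time.

    Genes with a constant profile (zero SD) cannot be scaled; they are
    dropped and listed in ``result.dropped``.
    """
    genes = pd.Index(genes)
    if len(genes) == 0:
        raise ValueError("empty gene list")
    avg = matrix.subset_genes(genes).replicate_average()
    mean = avg.mean(axis=1)
    sd = avg.std(axis=1, ddof=1)
    constant = sd <= 0
    z = avg.sub(mean, axis=0).div(sd.where(~constant), axis=0)
    return ScaledProfileMatrix(
        profiles=z[~constant], dropped=avg.index[constant].tolist()
    )


def _relabel_by_size(raw_labels: np.ndarray, k: int):
    """Map raw k-means labels to 1..k by descending cluster size (stable ties)."""
    sizes = np.bincount(raw_labels, minlength=k)
    order = np.argsort(-sizes, kind="stable")
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(1, k + 1)
    return remap[raw_labels], remap


def kmeans_cluster(
    scaled: ScaledProfileMatrix, k: int = 15, seed: int | None = None, n_init: int = 25
) -> ClusterAssignment:
    """Euclidean k-means on z-score profiles, best of ``n_init`` restarts.

    k-means++ seeding; deterministic for a fixed seed.  Cluster ids are
    arbitrary labels relabelled 1..k by descending size, so downstream
    comparisons should use label-invariant scores.
    """
    X = scaled.to_numpy()
    n = X.shape[0]
    if not (1 <= k <= n):
        raise ValueError(f"k must lie in [1, {n}], got {k}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
    tss = float(((X - X.mean(axis=0)) ** 2).sum())
    bss_tss = 1.0 - km.inertia_ / tss if tss > 0 else 0.0
    new_labels, remap = _relabel_by_size(km.labels_, k)
    centroids = np.empty_like(km.cluster_centers_)
    centroids[remap - 1] = km.cluster_centers_
    return ClusterAssignment(
        labels=pd.Series(new_labels, index=scaled.genes, name="cluster"),
        centroids=pd.DataFrame(
            centroids, index=pd.RangeIndex(1, k + 1, name="cluster"),
            columns=scaled.profiles.columns,
        ),
        k=k,
        bss_tss=max(bss_tss, 0.0),
        seed=seed,
        n_init=n_init,
    )


@dataclass
class ElbowCurve:
    """Explained variance (BSS/TSS) per k, with an advisory elbow suggestion."""

    table: pd.DataFrame        # columns: k, bss_tss
    suggested_k: int

    def plot(self, ax=None):  # pragma: no cover - thin display helper
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.table["k"], self.table["bss_tss"], marker="o")
        ax.axvline(self.suggested_k, ls="--", color="grey")
        ax.set_xlabel("k")
        ax.set_ylabel("BSS / TSS")
        ax.set_title(f"elbow suggestion: k = {self.suggested_k}")
        return ax


def _max_distance_to_chord(k: np.ndarray, y: np.ndarray) -> int:
    """k at maximum perpendicular distance to the chord joining the endpoints."""
    x0, y0 = k[0], y[0]
    x1, y1 = k[-1], y[-1]
    dx, dy = x1 - x0, y1 - y0
    norm = np.hypot(dx, dy)
    if norm == 0:
        return int(k[0])
    dist = np.abs(dy * (k - x0) - dx * (y - y0)) / norm
    return int(k[int(np.argmax(dist))])


def elbow_curve(
    scaled: ScaledProfileMatrix, k_range=range(2, 201), seed: int | None = None,
    n_init: int = 10,
) -> ElbowCurve:
    """BSS/TSS over a range of k (best of restarts per k).

    The suggested k maximises the perpendicular distance to the chord
    joining the curve's endpoints; it is advisory only — the cluster count
    is chosen by the analyst.
    """
    X = scaled.to_numpy()
    ks = [k for k in k_range if 1 <= k <= X.shape[0]]
    if not ks:
        raise ValueError("k_range contains no feasible k")
    tss = float(((X - X.mean(axis=0)) ** 2).sum())
    rows = []
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
        rows.append({"k": k, "bss_tss": max(1.0 - km.inertia_ / tss, 0.0) if tss > 0 else 0.0})
    table = pd.DataFrame(rows)
    suggestion = _max_distance_to_chord(
        table["k"].to_numpy(dtype=float), table["bss_tss"].to_numpy()
    )
    return ElbowCurve(table=table, suggested_k=suggestion)
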