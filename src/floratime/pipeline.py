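"""End-to-end orchestration of the time-course analysis.

Stages: preprocess (raw two-channel arrays -> filtered M matrix) ->
moderated windowed differential expression -> k-means co-expression
clustering -> tissue-atlas mapping -> resampling enrichment of bound-gene
and paralog sets -> term enrichment.  Stages communicate through plain TSV
contracts so any stage can also be run standalone on user data; stages
whose inputs are absent are skipped and logged.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .atlas import map_extreme_tissue
from .cluster import kmeans_cluster, zscore_profiles
from .containers import ExpressionMatrix
from .de import TimecourseDE
from .paralogs import find_paralogs
from .preprocess import preprocess_two_channel
from .setscan import assign_peaks_to_genes, go_enrichment, resampling_set_enrichment
from .simulate import (
    AnnotationPlan,
    SimConfig,
    default_plan,
    generate_annotations,
    generate_raw_two_channel,
    generate_timecourse,
)
from . import io as ftio

log = logging.getLogger("floratime")

__all__ = ["RunConfig", "ResultsBundle", "run_pipeline"]


@dataclass
class RunConfig:
    """All inputs and thresholds of a pipeline run.

    Exactly one of ``synthetic`` (a :class:`SimConfig`) or ``inputs``
    (paths: expression/design or raw tables, atlas, peaks, gene_models,
    terms, proteome) must be provided.  The thresholds carry the study's
    defaults: windowed contrasts within 2 d, DEGs at adjusted p < 0.01 and
    fold change >= 1.7, k = 15 clusters, enrichment nulls of 100 random
    sets with a 3-SD rule, paralog hits at E <= 1e-20 with 80 % query
    coverage, top 5 per query, term enrichment at BY-adjusted p < 0.05.
    """

    synthetic: SimConfig | None = None
    inputs: dict = field(default_factory=dict)
    annotation_plan: AnnotationPlan | None = None
    alpha: float = 0.01
    fc_min: float = 1.7
    window: float = 2.0
    k: int = 15
    n_init: int = 25
    n_iter: int = 100
    sd_mult: float = 3.0
    e_max: float = 1e-20
    cov_min: float = 0.80
    top_n: int = 5
    go_alpha: float = 0.05
    loess_span: float = 0.3
    min_arrays: int = 1
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (not self.inputs):
            raise ValueError("provide exactly one of synthetic SimConfig or input paths")
        checks = [
            0 < self.alpha < 1, self.fc_min >= 1, self.window >= 0, self.k >= 1,
            self.n_iter >= 2, self.sd_mult > 0, self.e_max > 0,
            0 < self.cov_min <= 1, self.top_n >= 1, 0 < self.go_alpha < 1,
            0 < self.loess_span <= 1, self.min_arrays >= 1,
        ]
        if not all(checks):
            raise ValueError("threshold out of range in RunConfig")

    def content_hash(self) -> str:
        def enc(o):
            if isinstance(o, SimConfig):
                return asdict(o)
            if isinstance(o, AnnotationPlan):
                return repr(o)
            if isinstance(o, Path):
                return str(o)
            return str(o)

        payload = json.dumps(asdict(self), sort_keys=True, default=enc)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ResultsBundle:
    """Everything a run produces, plus provenance sufficient to re-run it."""

    expression: ExpressionMatrix | None = None
    f_table: pd.DataFrame | None = None
    contrasts: pd.DataFrame | None = None
    deg_table: pd.DataFrame | None = None
    clusters: object = None
    tissue_table: object = None
    enrichment: dict = field(default_factory=dict)     # layer -> {universe -> DataFrame}
    go_tables: dict = field(default_factory=dict)      # cluster id -> DataFrame
    paralog_map: object = None
    truth: object = None
    annotations: object = None
    de_results: object = None
    preprocess_report: dict = field(default_factory=dict)
    skipped: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    # ------------------------------------------------------------------
    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        if self.expression is not None:
            ftio.write_expression(
                self.expression, out / "expression_M.tsv", out / "design.tsv",
                a_path=out / "expression_A.tsv",
            )
        for name, df in (
            ("f_test.tsv", self.f_table),
            ("contrasts.tsv", self.contrasts),
            ("degs.tsv", self.deg_table),
        ):
            if df is not None:
                ftio.write_table(df, out / name)
        if self.clusters is not None:
            ftio.write_table(self.clusters.labels.to_frame(), out / "clusters.tsv")
            ftio.write_table(self.clusters.centroids, out / "cluster_centroids.tsv")
        if self.tissue_table is not None:
            ftio.write_table(self.tissue_table.max_pct, out / "tissue_max_pct.tsv")
            ftio.write_table(self.tissue_table.min_pct, out / "tissue_min_pct.tsv")
        for layer, per_universe in self.enrichment.items():
            for uni, df in per_universe.items():
                ftio.write_table(df, out / f"enrichment_{layer}_{uni}.tsv")
        if self.go_tables:
            combined = pd.concat(
                {cid: df for cid, df in self.go_tables.items()}, names=["cluster", "term"]
            )
            ftio.write_table(combined, out / "go_enrichment.tsv")
        if self.paralog_map is not None:
            ftio.write_table(
                pd.DataFrame(self.paralog_map.to_records()).set_index("gene")
                if self.paralog_map.to_records()
                else pd.DataFrame(columns=["rank", "paralog", "score", "coverage", "evalue"]),
                out / "paralogs.tsv",
            )
        if self.truth is not None:
            ftio.write_table(self.truth.table, out / "truth.tsv", index_label="gene")
        ftio.write_json(
            {"provenance": self.provenance, "skipped": self.skipped,
             "preprocess": {k: v for k, v in self.preprocess_report.items() if k != "removed_genes"}},
            out / "run_summary.json",
        )


def _child_seeds(seed: int, n: int) -> list:
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s % (2**31 - 1)) for s in state]


def run_pipeline(config: RunConfig) -> ResultsBundle:
    """Execute the full analysis described by ``config``.

    Synthetic mode generates the study (expression + raw arrays +
    annotations) from the master seed, so the run is fully deterministic;
    real-input mode reads the TSV/BED/GMT/FASTA contracts and skips any
    stage whose inputs are absent.
    """
    t0 = time.time()
    bundle = ResultsBundle()
    seeds = _child_seeds(config.seed, 4)
    log.info("run config hash %s, seed %d", config.content_hash(), config.seed)

    # ----------------------------------------------------------- inputs
    if config.synthetic is not None:
        sim = config.synthetic
        expr_true, truth = generate_timecourse(sim)
        raw = generate_raw_two_channel(sim, truth, expr_true)
        plan = config.annotation_plan or default_plan(sim)
        annotations = generate_annotations(sim, truth, plan)
        bundle.truth = truth
        bundle.annotations = annotations
        em, prep_report = preprocess_two_channel(
            raw, span=config.loess_span, min_arrays=config.min_arrays
        )
        bundle.preprocess_report = prep_report
        atlas = annotations.atlas
        peaks = annotations.peaks
        gene_models = annotations.gene_models
        term_map = annotations.term_map
        proteome = annotations.proteome
        peak_layers = sorted({p.name for p in peaks if p.name and p.name != "decoy"})
    else:
        paths = config.inputs
        em = ftio.read_expression(
            paths["expression"], paths["design"], paths.get("A")
        )
        atlas = ftio.read_table(paths["atlas"]) if "atlas" in paths else None
        peaks = ftio.read_bed6(paths["peaks"]) if "peaks" in paths else None
        gene_models = (
            ftio.read_gene_models(paths["gene_models"]) if "gene_models" in paths else None
        )
        term_map = ftio.read_gmt(paths["terms"]) if "terms" in paths else None
        proteome = ftio.read_fasta(paths["proteome"]) if "proteome" in paths else None
        peak_layers = (
            sorted({p.name for p in peaks if p.name}) if peaks is not None else []
        )
    bundle.expression = em

    # ------------------------------------------------- differential expression
    try:
        results = TimecourseDE(em).fit()
    except Exception as exc:
        raise RuntimeError(f"stage 'de' failed: {exc}") from exc
    bundle.de_results = results
    bundle.f_table = results.f_test(alpha=config.alpha)
    bundle.contrasts = results.windowed_contrasts(window=config.window)
    bundle.deg_table = results.call_degs(alpha=config.alpha, fc_min=config.fc_min,
                                         window=config.window)
    deg_genes = bundle.deg_table.index[bundle.deg_table["is_deg"]]
    log.info("%d DEGs of %d genes", len(deg_genes), len(em.genes))

    # --------------------------------------------------------- clustering
    if len(deg_genes) >= config.k:
        scaled = zscore_profiles(em, deg_genes)
        bundle.clusters = kmeans_cluster(
            scaled, k=config.k, seed=seeds[0], n_init=config.n_init
        )
        cluster_map = bundle.clusters.as_dict()
    else:
        bundle.skipped.append("cluster: fewer DEGs than k")
        cluster_map = None

    # ----------------------------------------------------------- atlas map
    if cluster_map is not None and atlas is not None:
        bundle.tissue_table = map_extreme_tissue(cluster_map, atlas)
    elif atlas is None:
        bundle.skipped.append("atlas: no atlas matrix provided")

    # --------------------------------------------------- set enrichments
    universes = None
    if cluster_map is not None:
        clustered_genes = [g for genes in cluster_map.values() for g in genes]
        universes = {"degs": clustered_genes, "all_genes": em.genes.tolist()}
    if cluster_map is not None and peaks is not None and gene_models is not None:
        for i, layer in enumerate(peak_layers):
            layer_peaks = [p for p in peaks if p.name == layer]
            bound = assign_peaks_to_genes(layer_peaks, gene_models, label=layer)
            bundle.enrichment[layer] = {
                uni: resampling_set_enrichment(
                    cluster_map, bound.genes, genes, n_iter=config.n_iter,
                    seed=seeds[1] + i, sd_mult=config.sd_mult,
                )
                for uni, genes in universes.items()
            }
    elif peaks is None or gene_models is None:
        bundle.skipped.append("setscan/bound: no peaks or gene models provided")

    if proteome is not None and cluster_map is not None:
        bundle.paralog_map = find_paralogs(
            proteome, e_max=config.e_max, cov_min=config.cov_min, top_n=config.top_n
        )
        with_paralogs = bundle.paralog_map.genes_with_paralogs
        bundle.enrichment["paralog"] = {
            uni: resampling_set_enrichment(
                cluster_map, with_paralogs, genes, n_iter=config.n_iter,
                seed=seeds[2], sd_mult=config.sd_mult,
            )
            for uni, genes in universes.items()
        }
    elif proteome is None:
        bundle.skipped.append("paralogs: no proteome provided")

    if term_map is not None and cluster_map is not None:
        universe = universes["degs"]
        for cid, members in cluster_map.items():
            bundle.go_tables[cid] = go_enrichment(
                members, universe, term_map, alpha=config.go_alpha
            )
    elif term_map is None:
        bundle.skipped.append("go: no term annotations provided")

    # ----------------------------------------------------------- provenance
    import scipy
    import sklearn
    import statsmodels

    bundle.provenance = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "child_seeds": seeds,
        "thresholds": {
            k: getattr(config, k)
            for k in ("alpha", "fc_min", "window", "k", "n_iter", "sd_mult",
                      "e_max", "cov_min", "top_n", "go_alpha", "loess_span", "min_arrays")
        },
        "versions": {
            "floratime": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "scikit-learn": sklearn.__version__,
            "statsmodels": statsmodels.__version__,
        },
        "runtime_s": round(time.time() - t0, 2),
    }
    for skip in bundle.skipped:
        log.info("skipped %s", skip)

    if config.outdir:
        bundle.write(config.outdir)
    return bundle
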