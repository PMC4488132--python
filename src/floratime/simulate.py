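"""Synthetic study generator.

Emulates a 14-time-point, 3-replicate, two-channel common-reference
time-course of developing floral buds: per-gene temporal archetypes with
gene-specific noise variances drawn from a scaled inverse-chi-square prior,
raw two-channel probe intensities with additive background and an
intensity-dependent dye bias, and a matching annotation universe — tissue
atlas, transcription-factor binding peaks with gene models, term
annotations, and a proteome containing planted paralog families — all tied
to a ground-truth table so every downstream stage can be scored.

Randomness is split into independent child streams (expression, raw arrays,
annotations, sequences) derived from the master seed, so each layer can be
regenerated on its own.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, make_design
from .setscan import GeneModel, GenomicInterval

__all__ = [
    "SimConfig",
    "TruthTable",
    "AnnotationBundle",
    "LayerPlan",
    "AnnotationPlan",
    "default_plan",
    "generate_timecourse",
    "generate_raw_two_channel",
    "generate_annotations",
    "simulate_proteome",
    "archetype_profiles",
    "dye_bias_shape",
    "DEFAULT_TIME_GRID",
]

#: Day values of the 14 collection time-points: dense 0.5-d sampling over the
#: early, morphologically dynamic phase, widening to 1-d and then 2-d
#: intervals as buds approach anthesis at day 13.
DEFAULT_TIME_GRID = (0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 5.0, 7.0, 9.0, 11.0, 13.0)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


# ----------------------------------------------------------------------
# configuration and truth
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the synthetic time course.

    ``noise_prior`` is ``(d0, s0_sq)``: per-gene variances are drawn from a
    scaled inverse-chi-square with prior degrees of freedom ``d0`` and prior
    scale ``s0_sq`` (``d0 = inf`` gives every gene the same variance).
    ``fc_scale`` sets the typical |log2-ratio| amplitude of a non-flat
    archetype.
    """

    n_genes: int = 2000
    time_points: tuple = DEFAULT_TIME_GRID
    n_replicates: int = 3
    n_archetypes: int = 15
    frac_de: float = 0.3
    noise_prior: tuple = (4.0, 0.05)
    fc_scale: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        tp = np.asarray(self.time_points, dtype=float)
        if tp.ndim != 1 or len(tp) < 2 or np.any(np.diff(tp) <= 0):
            raise ValueError("time_points must be strictly increasing, length >= 2")
        if not (0 < self.frac_de <= 1):
            raise ValueError("frac_de must lie in (0, 1]")
        if self.n_archetypes < 1:
            raise ValueError("n_archetypes must be >= 1")
        for name in ("n_genes", "n_replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        d0, s0_sq = self.noise_prior
        if not (d0 > 0) or s0_sq < 0:
            raise ValueError("noise_prior must satisfy d0 > 0 and s0_sq >= 0")

    def rng_streams(self) -> dict:
        ss = np.random.SeedSequence(self.seed)
        names = ("expression", "raw", "annotations", "sequences")
        children = ss.spawn(len(names))
        return {n: np.random.default_rng(c) for n, c in zip(names, children)}


@dataclass
class TruthTable:
    """Ground truth of the simulation.

    ``table`` is indexed by gene with columns ``archetype`` (0 = flat null),
    ``is_de``, ``cluster`` (planted co-expression cluster, equal to the
    archetype id), ``sigma2`` (true noise variance) and ``amplitude``;
    annotation layers append bound-by flags, ``paralog_family`` and
    ``terms``.  ``profiles`` holds the true per-time-point mean M values.
    """

    table: pd.DataFrame
    profiles: pd.DataFrame

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    def max_windowed_log2fc(self, window: float = 2.0) -> pd.Series:
        """Per gene, the largest true |log2 FC| over time-point pairs within ``window`` days."""
        t = self.profiles.columns.to_numpy(dtype=float)
        best = np.zeros(len(self.profiles))
        vals = self.profiles.to_numpy()
        for i in range(len(t)):
            for j in range(i + 1, len(t)):
                if t[j] - t[i] <= window + 1e-9:
                    best = np.maximum(best, np.abs(vals[:, j] - vals[:, i]))
        return pd.Series(best, index=self.profiles.index, name="max_windowed_log2fc")


# ----------------------------------------------------------------------
# temporal archetypes
# ----------------------------------------------------------------------
def _bump(u: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((u - center) / width) ** 2)


def _sigmoid(u: np.ndarray, center: float, rate: float = 0.05) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(u - center) / rate))


def _template_bank():
    """Smooth bump / ramp / switch / bimodal temporal shapes.

    The shapes mimic the profile classes seen across a flower time course:
    transient waves peaking at successive stages, early-only and late-only
    expression, sustained activation or repression from a given stage, and
    bimodal (early + late) profiles.  Rapidly changing shapes come first so
    that small archetype banks consist of genes the windowed-contrast scan
    is designed to detect; the two slow monotone ramps close the bank.
    """
    return [
        lambda u: _bump(u, 0.10, 0.07),                     # earliest transient wave
        lambda u: _bump(u, 0.30, 0.07),
        lambda u: _bump(u, 0.50, 0.07),
        lambda u: _bump(u, 0.70, 0.07),
        lambda u: _bump(u, 0.90, 0.07),                     # anthesis-specific wave
        lambda u: -_bump(u, 0.25, 0.10),                    # early-intermediate dip
        lambda u: -_bump(u, 0.60, 0.10),                    # intermediate dip
        lambda u: _sigmoid(u, 0.25),                        # switched on early, stays on
        lambda u: 1.0 - _sigmoid(u, 0.55),                  # switched off mid-course
        lambda u: _bump(u, 0.12, 0.06) + _bump(u, 0.80, 0.06),   # bimodal early+late
        lambda u: -_bump(u, 0.15, 0.06) - _bump(u, 0.75, 0.06),  # bimodal repression
        lambda u: _sigmoid(u, 0.75),                        # late activation switch
        lambda u: _bump(u, 0.42, 0.18),                     # broad intermediate plateau
        lambda u: u,                                        # slow steady rise to maturity
        lambda u: 1.0 - u,                                  # slow decline from initiation
    ]


def archetype_profiles(time_points, n_archetypes: int) -> np.ndarray:
    """Archetype mean profiles, rows centred to mean 0 and scaled to max |.| = 1.

    Row ``a`` (0-based) is archetype id ``a + 1``; archetype 0 (flat null)
    is not included.  Beyond 15 archetypes, additional bumps are interleaved.
    """
    t = np.asarray(time_points, dtype=float)
    u = (t - t[0]) / (t[-1] - t[0])
    bank = _template_bank()
    while len(bank) < n_archetypes:  # extra evenly spaced bumps if requested
        k = len(bank) - 14
        bank.append(lambda u, c=(k * 0.618) % 1.0: _bump(u, c, 0.09))
    rows = []
    for f in bank[:n_archetypes]:
        v = f(u)
        v = v - v.mean()
        peak = np.max(np.abs(v))
        rows.append(v / peak if peak > 0 else v)
    return np.asarray(rows)


# ----------------------------------------------------------------------
# expression time course
# ----------------------------------------------------------------------
def generate_timecourse(config: SimConfig):
    """Simulate the M-value time course.

    Returns ``(ExpressionMatrix, TruthTable)``.  Per gene, array and
    replicate, ``M = archetype(t) + eps`` with ``eps ~ N(0, sigma_g^2)`` and
    ``sigma_g^2`` drawn from the scaled inverse-chi-square noise prior; flat
    (null) genes have an identically zero mean profile.
    """
    rng = config.rng_streams()["expression"]
    n = config.n_genes
    tp = np.asarray(config.time_points, dtype=float)
    genes = pd.Index([f"G{i:05d}" for i in range(1, n + 1)], name="gene")

    n_de = int(round(config.frac_de * n))
    arch = np.zeros(n, dtype=int)
    de_idx = rng.choice(n, size=n_de, replace=False)
    # balanced assignment over archetypes, then shuffled within the DE genes
    labels = np.resize(np.arange(1, config.n_archetypes + 1), n_de)
    rng.shuffle(labels)
    arch[de_idx] = labels

    amplitude = np.zeros(n)
    amplitude[de_idx] = config.fc_scale * rng.uniform(0.75, 1.25, size=n_de)

    d0, s0_sq = config.noise_prior
    if math.isinf(d0):
        sigma2 = np.full(n, float(s0_sq))
    else:
        sigma2 = d0 * s0_sq / rng.chisquare(d0, size=n)

    templates = archetype_profiles(tp, config.n_archetypes)
    profiles = np.zeros((n, len(tp)))
    mask = arch > 0
    profiles[mask] = amplitude[mask, None] * templates[arch[mask] - 1]

    design = make_design(tp, config.n_replicates)
    t_of_array = design["time_point"].to_numpy()
    t_index = np.searchsorted(tp, t_of_array)
    mean_mat = profiles[:, t_index]
    noise = rng.standard_normal((n, len(design))) * np.sqrt(sigma2)[:, None]
    M = pd.DataFrame(mean_mat + noise, index=genes, columns=design.index)

    truth = TruthTable(
        table=pd.DataFrame(
            {
                "archetype": arch,
                "is_de": mask,
                "cluster": arch,
                "sigma2": sigma2,
                "amplitude": amplitude,
            },
            index=genes,
        ),
        profiles=pd.DataFrame(profiles, index=genes, columns=pd.Index(tp, name="time_point")),
    )
    return ExpressionMatrix(M=M, design=design), truth


# ----------------------------------------------------------------------
# raw two-channel arrays
# ----------------------------------------------------------------------
def dye_bias_shape(A: np.ndarray) -> np.ndarray:
    """Unit-amplitude intensity-dependent bias shape (the classic MA 'banana').

    The injected bias is ``amplitude * dye_bias_shape(A)``; regressing null-gene
    M on this shape recovers the amplitude.
    """
    return np.sin(2.0 * np.pi * (np.asarray(A, dtype=float) - 7.0) / 6.0)


def generate_raw_two_channel(
    config: SimConfig,
    truth: TruthTable,
    expr: ExpressionMatrix,
    *,
    probes_per_gene: int = 2,
    background_level: float = 50.0,
    background_cv: float = 0.1,
    bias_amplitude: float = 0.3,
    probe_noise_sd: float = 0.05,
    n_negative_controls: int = 200,
    background_genes=(),
):
    """Expand the M-value time course into raw two-channel probe intensities.

    Per probe and array the sample (red) and common-reference (green)
    channels are reconstructed from the gene's M value plus (a) an additive
    background, (b) an intensity-dependent dye bias ``bias_amplitude *
    dye_bias_shape(A)`` affecting every probe, and (c) probe-level noise on
    M.  A block of negative-control probes sits at background level, and
    genes listed in ``background_genes`` are forced to control-like
    intensities (useful for testing the low-expression filter).

    With ``probes_per_gene=1``, zero background, zero bias and zero probe
    noise, recomputing M from the raw channels reproduces the input exactly.
    """
    from .preprocess import RawArraySet  # local import to avoid a cycle

    rng = config.rng_streams()["raw"]
    genes = expr.genes
    arrays = expr.arrays
    n_genes, n_arrays = len(genes), len(arrays)
    bg_set = set(background_genes)
    unknown = bg_set - set(genes)
    if unknown:
        raise KeyError(f"background_genes not in expression matrix: {sorted(unknown)[:5]}")

    probe_ids, probe_gene = [], []
    for g in genes:
        for k in range(1, probes_per_gene + 1):
            probe_ids.append(f"{g}_p{k}")
            probe_gene.append(g)
    ctl_ids = [f"NC{i:04d}" for i in range(1, n_negative_controls + 1)]
    all_ids = pd.Index(probe_ids + ctl_ids, name="probe")
    is_control = np.zeros(len(all_ids), dtype=bool)
    is_control[len(probe_ids):] = True
    gene_of_probe = pd.Series(probe_gene + [None] * n_negative_controls, index=all_ids)

    base = rng.normal(10.0, 1.0, size=n_genes)                    # gene log2 intensity
    probe_offset = rng.normal(0.0, 0.3, size=len(probe_ids))      # probe affinity
    gene_row = {g: i for i, g in enumerate(genes)}
    gi = np.fromiter((gene_row[g] for g in probe_gene), dtype=int)

    A_true = base[gi] + probe_offset                               # (n_probes,)
    M_true = expr.M.to_numpy()[gi]                                 # (n_probes, n_arrays)
    M_obs = (
        M_true
        + bias_amplitude * dye_bias_shape(A_true)[:, None]
        + (rng.standard_normal(M_true.shape) * probe_noise_sd if probe_noise_sd > 0 else 0.0)
    )
    red = np.power(2.0, A_true[:, None] + M_obs / 2.0)
    green = np.power(2.0, A_true[:, None] - M_obs / 2.0)

    # near-background signal for negative controls and forced-background genes
    eps_scale = max(background_level, 1.0) * 0.02
    ctl_red = eps_scale * rng.exponential(1.0, size=(n_negative_controls, n_arrays))
    ctl_green = eps_scale * rng.exponential(1.0, size=(n_negative_controls, n_arrays))
    if bg_set:
        rows = np.isin(np.asarray(probe_gene), sorted(bg_set))
        red[rows] = eps_scale * 0.01 * rng.exponential(1.0, size=(rows.sum(), n_arrays))
        green[rows] = eps_scale * 0.01 * rng.exponential(1.0, size=(rows.sum(), n_arrays))

    signal_red = np.vstack([red, ctl_red])
    signal_green = np.vstack([green, ctl_green])
    if background_level > 0:
        bg = background_level * np.clip(
            1.0 + background_cv * rng.standard_normal((len(all_ids), n_arrays)), 0.0, None
        )
    else:
        bg = np.zeros((len(all_ids), n_arrays))

    def df(x):
        return pd.DataFrame(x, index=all_ids, columns=arrays)

    return RawArraySet(
        probe_gene=gene_of_probe,
        is_control=pd.Series(is_control, index=all_ids),
        red_fg=df(signal_red + bg),
        red_bg=df(bg),
        green_fg=df(signal_green + bg),
        green_bg=df(bg),
        design=expr.design,
    )


# ----------------------------------------------------------------------
# annotations
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class LayerPlan:
    """Planting plan for one annotation layer.

    ``background_rate`` is the annotated fraction among genes outside the
    target clusters; ``odds_ratios`` maps planted cluster id -> requested
    odds ratio of annotation relative to background (1 = no planting).
    """

    background_rate: float = 0.1
    odds_ratios: dict = field(default_factory=dict)


@dataclass(frozen=True)
class AnnotationPlan:
    bound_layers: dict = field(default_factory=dict)     # label -> LayerPlan
    paralog: LayerPlan = field(default_factory=lambda: LayerPlan(0.2))
    term_layers: dict = field(default_factory=dict)      # term id -> LayerPlan
    tissues: tuple = ("meristem", "sepal", "petal", "stamen", "pollen", "ovule", "leaf", "root")
    tissue_of_cluster: dict = field(default_factory=dict)  # cluster id -> tissue
    paralog_identity: float = 0.9
    family_size_range: tuple = (2, 5)
    atlas_coverage: float = 1.0
    n_decoy_peaks: int = 200


def default_plan(config: SimConfig) -> AnnotationPlan:
    """Planting plan emulating the study's annotation layers.

    Two transcription factors with stage-specific binding enriched in the
    early-activated clusters, one unplanted (null) factor, four planted
    terms, and paralog families enriched in early clusters; every planted
    cluster peaks in a designated tissue of the atlas.
    """
    k = config.n_archetypes
    c = lambda *ids: {i: 4.0 for i in ids if i <= k}
    tissues = ("meristem", "sepal", "petal", "stamen", "pollen", "ovule", "leaf", "root")
    return AnnotationPlan(
        bound_layers={
            "TFA@2d": LayerPlan(0.10, c(1, 2)),
            "TFA@8d": LayerPlan(0.10, c(2, 3)),
            "TFB@4d": LayerPlan(0.10, c(1, 4)),
            "TFC@4d": LayerPlan(0.10, {}),  # unplanted control layer
        },
        paralog=LayerPlan(0.20, c(1, 2)),
        term_layers={
            "T0001": LayerPlan(0.05, {1: 6.0} if k >= 1 else {}),
            "T0002": LayerPlan(0.05, {2: 6.0} if k >= 2 else {}),
            "T0003": LayerPlan(0.05, {3: 6.0} if k >= 3 else {}),
            "T0004": LayerPlan(0.05, {}),
            "T0005": LayerPlan(0.10, {}),
        },
        tissues=tissues,
        tissue_of_cluster={i: tissues[(i - 1) % len(tissues)] for i in range(1, k + 1)},
    )


@dataclass
class AnnotationBundle:
    """Synthetic annotation universe matched to the expression genes."""

    atlas: pd.DataFrame                    # gene x tissue group
    peaks: list                            # GenomicInterval, labelled by layer
    gene_models: list                      # GeneModel
    term_map: dict                         # term id -> set of genes
    proteome: dict                         # gene id -> amino-acid sequence
    bound_sets: dict                       # layer label -> set of genes (ground truth)
    paralog_families: dict                 # family id -> list of genes
    tissue_of_cluster: dict

    def __post_init__(self) -> None:
        universe = set(self.atlas.index) | set(self.proteome)
        for term, members in self.term_map.items():
            extra = set(members) - universe
            if extra:
                raise ValueError(f"term {term} annotates unknown genes: {sorted(extra)[:5]}")
        bad = [
            (g, s) for g, s in self.proteome.items() if set(s) - set(AMINO_ACIDS)
        ]
        if bad:
            raise ValueError(f"non-standard residues in sequences for {bad[0][0]}")


def _plant_layer(label, plan: LayerPlan, clusters: pd.Series, rng) -> set:
    """Draw an annotated gene set realising the requested odds ratios."""
    r0 = plan.background_rate
    if not (0 < r0 < 1):
        raise ValueError(f"layer {label}: background_rate must lie in (0, 1)")
    odds0 = r0 / (1.0 - r0)
    annotated: set = set()
    for cid, group in clusters.groupby(clusters):
        members = group.index.to_numpy()
        orat = plan.odds_ratios.get(int(cid), 1.0)
        if not np.isfinite(orat) or orat <= 0:
            raise ValueError(f"layer {label}: infeasible odds ratio {orat} for cluster {cid}")
        rate = orat * odds0 / (1.0 + orat * odds0)
        n_annot = int(round(rate * len(members)))
        if n_annot > len(members):
            raise ValueError(
                f"layer {label}: odds ratio {orat} infeasible for cluster {cid} "
                f"of size {len(members)}"
            )
        if n_annot:
            annotated.update(rng.choice(members, size=n_annot, replace=False).tolist())
    return annotated


def simulate_proteome(gene_ids, families, identity: float, rng, length_range=(150, 300)) -> dict:
    """Amino-acid sequences with mutated copies of a common ancestor per family.

    ``families`` is an iterable of gene-id lists; every family member is an
    i.i.d. substitution copy of the ancestral sequence (no indels), mutated
    at rate ``(1 - identity) / 2`` so that the *pairwise* identity between
    any two members is ``identity`` in expectation.  Genes outside any
    family get independent random sequences.
    """
    if not (0 < identity <= 1):
        raise ValueError("identity must lie in (0, 1]")
    mut_rate = (1.0 - identity) / 2.0
    lo, hi = length_range
    aa = np.array(list(AMINO_ACIDS))
    proteome: dict = {}
    in_family = set()
    for fam in families:
        length = int(rng.integers(lo, hi + 1))
        ancestor = rng.choice(20, size=length)
        for g in fam:
            seq = ancestor.copy()
            mut = rng.random(length) < mut_rate
            if mut.any():
                # substitute with one of the 19 other residues
                seq[mut] = (seq[mut] + rng.integers(1, 20, size=int(mut.sum()))) % 20
            proteome[g] = "".join(aa[seq])
            in_family.add(g)
    for g in gene_ids:
        if g not in in_family:
            length = int(rng.integers(lo, hi + 1))
            proteome[g] = "".join(aa[rng.integers(0, 20, size=length)])
    return proteome


def generate_annotations(
    config: SimConfig, truth: TruthTable, plan: AnnotationPlan | None = None
) -> AnnotationBundle:
    """Generate the annotation universe (atlas, peaks, terms, proteome).

    Bound-gene sets, paralog families and term annotations are drawn so the
    annotated fraction in each planted cluster matches the requested odds
    ratio (relative to the layer's background rate) in expectation.  Paralog
    family members are mutated copies of a shared ancestral protein; atlas
    rows of planted-cluster genes peak in their designated tissue group.
    """
    plan = default_plan(config) if plan is None else plan
    streams = config.rng_streams()
    rng = streams["annotations"]
    rng_seq = streams["sequences"]
    genes = truth.genes
    clusters = truth.table["cluster"]

    # --- bound-gene layers, with peaks and gene models -----------------
    genes_per_chrom = 500
    gene_models, slot_start = [], {}
    for i, g in enumerate(genes):
        chrom = f"Chr{i // genes_per_chrom + 1}"
        x = 10000 * (i % genes_per_chrom) + 3000
        strand = "+" if i % 2 == 0 else "-"
        gene_models.append(GeneModel(gene_id=g, chrom=chrom, start=x, end=x + 2000, strand=strand))
        slot_start[g] = (chrom, x, strand)

    peaks, bound_sets = [], {}
    for label, layer in plan.bound_layers.items():
        bound = _plant_layer(label, layer, clusters, rng)
        bound_sets[label] = bound
        for g in sorted(bound):
            chrom, x, strand = slot_start[g]
            if strand == "+":
                s, e = x - 2000, x - 1800           # 2 kb upstream of the TSS
            else:
                s, e = x + 2000 + 1800, x + 2000 + 2000
            peaks.append(GenomicInterval(chrom, s, e, name=label))
    # decoy peaks in the dead zone between gene windows
    decoy_rows = rng.choice(len(gene_models), size=min(plan.n_decoy_peaks, len(gene_models)), replace=False)
    for i in decoy_rows:
        gm = gene_models[int(i)]
        peaks.append(GenomicInterval(gm.chrom, gm.start + 5500, gm.start + 5700, name="decoy"))

    # --- paralog families and proteome ---------------------------------
    paralog_genes = sorted(_plant_layer("paralog", plan.paralog, clusters, rng))
    shuffled = np.array(paralog_genes)
    rng.shuffle(shuffled)
    families, i = [], 0
    lo, hi = plan.family_size_range
    while i < len(shuffled):
        size = int(rng.integers(lo, hi + 1))
        fam = shuffled[i : i + size].tolist()
        i += size
        if len(fam) == 1:
            if families:
                families[-1].extend(fam)
            elif len(shuffled) > 1:
                continue
            else:
                families.append(fam)
        else:
            families.append(fam)
    family_map = {f"F{j:04d}": fam for j, fam in enumerate(families, start=1)}
    proteome = simulate_proteome(genes, family_map.values(), plan.paralog_identity, rng_seq)

    # --- term annotations ----------------------------------------------
    term_map = {
        term: _plant_layer(term, layer, clusters, rng)
        for term, layer in plan.term_layers.items()
    }

    # --- tissue atlas ----------------------------------------------------
    tissues = list(plan.tissues)
    atlas = pd.DataFrame(
        rng.normal(5.0, 1.0, size=(len(genes), len(tissues))), index=genes, columns=tissues
    )
    for cid, tissue in plan.tissue_of_cluster.items():
        members = clusters.index[clusters == cid]
        if len(members) == 0:
            continue
        col = tissues.index(tissue)
        vals = atlas.loc[members].to_numpy()
        vals[:, col] = vals.max(axis=1) + 2.0 + np.abs(rng.normal(0.0, 0.5, size=len(members)))
        atlas.loc[members] = vals
    if plan.atlas_coverage < 1.0:
        keep = rng.random(len(genes)) < plan.atlas_coverage
        atlas = atlas.loc[genes[keep]]

    # --- extend the truth table -----------------------------------------
    for label, bound in bound_sets.items():
        truth.table[f"bound_{label}"] = truth.genes.isin(sorted(bound))
    fam_of_gene = {g: fid for fid, fam in family_map.items() for g in fam}
    truth.table["paralog_family"] = [fam_of_gene.get(g, "") for g in truth.genes]
    truth.table["terms"] = [
        ",".join(sorted(t for t, members in term_map.items() if g in members))
        for g in truth.genes
    ]

    return AnnotationBundle(
        atlas=atlas,
        peaks=peaks,
        gene_models=gene_models,
        term_map=term_map,
        proteome=proteome,
        bound_sets=bound_sets,
        paralog_families=family_map,
        tissue_of_cluster=dict(plan.tissue_of_cluster),
    )
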