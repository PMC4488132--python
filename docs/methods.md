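# Methods

This note documents the models implemented in `floratime`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions that matter for reproducibility.

## Study design being modelled

A floral-induction time course: synchronised floral buds collected at 14
time-points from immediately before induction (day 0) to maturity (day 13),
in 3 biologically independent replicate series, profiled on two-channel
arrays against a pooled common reference. The analysed quantity is the
M-value, log2(sample / common reference), per gene and array; the A-value
(mean log2 channel intensity) is carried for intensity-dependent
normalization and background filtering. The default time grid is
{0, 0.5, 1, 1.5, 2, 2.5, 3, 3.5, 4, 5, 7, 9, 11, 13} days — dense 0.5-day
sampling through the morphologically dynamic early phase, widening to 1-
and then 2-day intervals late. The exact day values of such an experiment
are a property of the data, so the grid is configurable everywhere and
never asserted.

## Preprocessing (`floratime.preprocess`)

Order: background subtraction → within-array loess → between-array
Aquantile → probe-to-gene averaging → low-expression filter. Each stage is
a pure function.

- **Subtract method.** Channel value = foreground − background. Non-positive
  corrected intensities become missing rather than being floored: flooring
  would fabricate log-intensities for probes that are indistinguishable
  from background.
- **Loess.** M is regressed on A with a robust locally weighted regression
  (tricube weights; statsmodels `lowess`), default span 0.3 with 4
  robustifying iterations, and the fitted trend subtracted. Control probes
  are excluded from the fit (their M at near-background intensity is
  essentially noise) but receive the interpolated correction. The span is
  exposed; narrower spans track higher-frequency dye bias at the cost of
  variance.
- **Aquantile.** Only the A-values are quantile-normalized across arrays
  (each quantile replaced by the cross-array mean quantile); M is
  untouched. Ties share the mean value of their average rank, which keeps
  the sorted normalized values identical across arrays.
- **Summarization.** Gene value = mean of its finite probes; a gene is
  missing on an array only if all its probes are.
- **Filter.** Per array, the threshold is the median normalized A of the
  negative-control probes; a gene is kept if it beats the threshold on at
  least `min_arrays` arrays (default 1 — a gene must rise above background
  somewhere). The comparison is on the A scale, per array, because that is
  where background level is defined; control probes are carried through
  normalization so thresholds and gene intensities share a scale.

## Differential expression (`floratime.de`)

Per gene, a one-way layout on time-point: coefficients are per-time-point
replicate means; s²_g is the pooled within-group variance on
d_g = n_obs − n_timepoints df. Genes with fewer than two observed
time-points or no residual df are reported untestable, not imputed.

**Variance moderation.** With e_g = log s²_g − ψ(d_g/2) + log(d_g/2),
moment matching gives mean(e) = log s₀² + ψ(d₀/2) − log(d₀/2) and
var(e) = ψ′(d₀/2) + mean ψ′(d_g/2); d₀ follows by Newton inversion of the
trigamma function and s₀² from the mean equation. If the empirical spread
of e does not exceed the sampling component, d₀ = ∞ and every posterior
variance equals s₀² (estimated then as the mean of the s²_g). Posterior:
s̃²_g = (d₀ s₀² + d_g s²_g)/(d₀ + d_g). Genes with s²_g = 0 are excluded
from hyperparameter estimation; an all-zero-variance input is an error.

**Tests.** The global moderated F (df n_tp − 1 and d_g + d₀; the normal /
chi-square limit when d₀ = ∞) with BH adjustment across genes defines
"responsive" genes at adjusted p < 0.01. The DEG scan tests all ordered
time-point pairs within a 2-day window (inclusive, on the real day values
of the design) with moderated t statistics. FDR pooling is one BH pass
over all gene × contrast p-values — the scan is treated as one experiment;
a per-contrast option exists but is not the default. A gene is a DEG iff
some windowed contrast has adjusted p < 0.01 and |fold change| ≥ 1.7
(inclusive), the fold change being measured on the fitted contrast
coefficient, FC = 2^|Δcoef|. Both thresholds, the window and the pooling
are parameters. A zero-day window yields an empty contrast table (there
are no pairs) rather than an error; a negative window is rejected.

## Clustering (`floratime.cluster`)

Profiles are replicate-averaged per time-point and z-scored per gene
across time-points (SD with ddof = 1; constant profiles are dropped and
listed). K-means is Euclidean, k-means++ seeded, best of 25 restarts
(deterministic given a seed); labels are relabelled 1..k by descending
cluster size, so all comparisons against planted truth use label-invariant
scores (adjusted Rand index). The elbow curve reports BSS/TSS over a k
range; the suggestion maximises the perpendicular distance to the chord
joining the curve endpoints and is advisory only — the CLI requires an
explicit k because cluster count is an analyst's choice.

## Atlas mapping (`floratime.atlas`)

For each atlas-covered cluster gene, the arg-max and arg-min tissue group
across atlas columns; per-cluster percentages are over covered, untied
genes. Ties for the extreme are counted separately and excluded from
percentages — attributing them to an arbitrary column would be order
dependent. Atlas values are used as supplied (no re-normalization); the
linear-vs-log scale is the supplier's contract. Sample-to-group collapsing
is a per-group mean.

## Gene-set machinery (`floratime.setscan`)

- **Peak assignment.** Coordinates are 0-based half-open (BED dialect)
  throughout; 1-based inputs must be converted at the reader. A gene is
  bound iff some peak overlaps the window from 3 kb 5′ of its transcribed
  region to 1 kb 3′ of it (strand-aware, clipped at zero).
- **Resampling null.** For each cluster of size n, the observed annotated
  fraction is compared to n-sized draws without replacement (random
  "clusters" mimic real ones) from a stated universe; 100 iterations by
  default; significant beyond 3 standard deviations, with the z-score also
  reported. Degenerate nulls (SD = 0) are flagged and never significant.
  Runs against two universes — the DEG list and the whole gene set — are
  reported side by side by the pipeline.
- **Term enrichment.** One-sided Fisher exact (enrichment) per term after
  intersecting terms with the universe, Benjamini–Yekutieli adjustment
  within a cluster (valid under arbitrary dependence between terms),
  significant at adjusted p < 0.05. Terms with no universe members are
  skipped and reported.
- **List overlap.** Upper-tail hypergeometric p with the independence
  expectation |A||B|/|U|.

## Paralog identification (`floratime.paralogs`)

Optimal affine-gap local alignment (Biopython `PairwiseAligner`), BLOSUM62
with gap open 11 / extend 1 (a gap of length L costs 11 + L); E-values from
the Karlin–Altschul model E = K·m·n·e^(−λS) with the standard published
gapped constants λ = 0.267, K = 0.041 for this scheme (configurable — only
the E-threshold is fixed by the analysis design). Hits are kept at
E ≤ 1e-20 and query coverage ≥ 0.80, where coverage is the contiguous
aligned query span (gaps included) over the query length; self-hits are
removed, reciprocity is *not* required (the listing is directional), and
the top 5 per query by ascending E (ties: higher score, then subject id)
are retained. "Top 5 per query" is one reading of a per-proteome top-5
rule; it is overridable via `top_n`. A k-mer co-occurrence prefilter
(≥ 3 shared 4-mers, words in > 100 sequences ignored) skips pairs that
cannot reach the threshold — a hit at E ≤ 1e-20 requires a raw score of
several hundred and hence a long high-identity stretch; `exhaustive=True`
disables it and is exercised in tests. No low-complexity masking is
applied by default.

## Synthetic-data generator (`floratime.simulate`)

The generator emulates the study design, not the organism: its purpose is
planted ground truth for every downstream stage.

- **Expression.** M_{g,t,r} = archetype_g(t) + ε, ε ~ N(0, σ²_g), with
  σ²_g from a scaled inverse-chi-square (default d₀ = 4, s₀² = 0.05 —
  typical per-gene SDs of ~0.2 with a realistic heavy right tail).
  A fraction `frac_de` (default 0.3) of genes carry one of 15 smooth
  archetypes (transient waves at successive stages, dips, on/off switches,
  bimodal early+late shapes, slow ramps), centred and peak-normalised,
  scaled by `fc_scale` (default 2) with ±25 % per-gene amplitude jitter.
  Rapidly changing shapes head the bank, so small archetype banks consist
  of genes the windowed scan targets; the two slow monotone ramps close it
  (ids 14–15) and are, by design, largely invisible to a 2-day windowed
  fold-change rule.
- **Raw arrays.** Per probe: channel intensities reconstructed from the
  gene's M plus additive background (level 50, 10 % CV, the measured
  background equals the added one, so subtraction is exact), an
  intensity-dependent dye bias `amplitude × sin(2π(A−7)/6)` applied to
  every probe, per-probe noise on M, multiple probes per gene with
  probe-specific affinities, and a block of negative-control probes at
  near-background intensity. Genes can be forced to background level to
  exercise the filter.
- **Annotations.** Bound-gene sets, paralog membership and term
  annotations are planted per cluster at requested odds ratios relative to
  a background rate (counts realised exactly up to rounding; an unplanted
  layer is included by default as a negative control). Gene models are laid
  out 10 kb apart on synthetic chromosomes with alternating strands; each
  bound gene receives a peak 2 kb upstream of its TSS and decoy peaks fall
  in the dead zone between regulatory windows. Paralog families (sizes
  2–5) are i.i.d.-substitution copies of a common ancestral protein at a
  rate targeting the requested *pairwise* identity (default 0.9), no
  indels by default. Atlas rows of planted-cluster genes peak in a
  designated tissue group.
- **Determinism.** One RNG stream per layer (expression, raw, annotations,
  sequences), spawned from the master seed, so layers regenerate
  independently and byte-identically.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: spatial array artefacts, probe sequence effects
and scanner formats; dye-swap designs; background-estimation error
(subtraction is exact here); correlated noise across genes or time;
indels, domain shuffling and low-complexity sequence in proteomes; the
hierarchical structure of real term ontologies; biological coupling
between the annotation layers. Calibration results (FDR, type-I rate of
the 3-SD rule) therefore reflect the idealised independence structure.

## Problem sizes and pipeline defaults

The default `SimConfig` (2 000 genes) is a scaled-down study on which the
full pipeline — including the all-vs-all paralog scan — completes in
seconds to a couple of minutes on one core; calibration checks use 2 000 –
5 000 genes and 10–20 independent seeds, chosen so that empirical rates
(FDR ≤ 5 %, sensitivity ≥ 90 %, 3-SD type-I ≤ 2 %) are measured with
adequate counts. Enrichment-recovery checks use ≥ 200-gene clusters, the
size regime where a 3-SD rule on 100 resamples has essentially full power
at odds ratio 4. All thresholds (α = 0.01, FC ≥ 1.7, 2-day window, k = 15,
100 iterations, 3 SD, E ≤ 1e-20, coverage ≥ 0.80, top 5, term α = 0.05)
live in `RunConfig`, are logged with every run, and are CLI flags.

## Known limitations

- The moderated F reference distribution treats (d₀, s₀²) as known;
  with few genes the estimation uncertainty is not propagated.
- The elbow suggestion is a geometric heuristic; on curves without a
  clear knee it degrades to an endpoint-adjacent pick and should not be
  applied silently (and is not).
- `normalize_between_aquantile` interpolates between empirical quantiles
  when arrays have unequal missing-value counts; exact rank equality
  across arrays then holds only approximately.
- The resampling null conditions on the realised annotation set; for very
  small clusters (tens of genes) the 3-SD rule is conservative relative to
  an exact hypergeometric test.
- Real two-colour data may need dye-swap handling and within-array spatial
  normalization; neither is implemented.
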