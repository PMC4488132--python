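"""Paralog identification by all-vs-all protein local alignment.

Every protein is aligned against every other with an affine-gap
Smith–Waterman (BLOSUM62, gap open 11 / extend 1 by default); hits are
converted to E-values under the Karlin–Altschul extreme-value model
``E = K * m * n * exp(-lambda * S)`` and kept when ``E <= 1e-20`` and the
local alignment covers at least 80 % of the query.  The top 5 hits per
query (self-hits removed, reciprocity not required) are retained as the
query's potential paralogs.

A k-mer co-occurrence prefilter (in the spirit of a seeded search) skips
sequence pairs that share no words and therefore cannot reach the E-value
threshold; ``exhaustive=True`` disables it.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "ScoringScheme",
    "AlignmentHit",
    "ParalogMap",
    "local_align",
    "hit_evalue",
    "find_paralogs",
    "AMINO_ACIDS",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix, affine gap penalties and E-value constants.

    A gap of length L costs ``gap_open + L * gap_extend``.  ``lam`` and
    ``karlin_k`` are the Karlin–Altschul parameters of the gapped scheme;
    the defaults are the standard published values for BLOSUM62 with gap
    open 11 / extend 1.
    """

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    lam: float = 0.267
    karlin_k: float = 0.041

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.lam <= 0 or self.karlin_k <= 0:
            raise ValueError("Karlin-Altschul parameters must be positive")

    def aligner(self) -> Align.PairwiseAligner:
        return _make_aligner(self.matrix, self.gap_open, self.gap_extend)

    def substitution_score(self, a: str, b: str) -> float:
        m = substitution_matrices.load(self.matrix)
        return float(m[a, b])


@lru_cache(maxsize=8)
def _make_aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


@dataclass(frozen=True)
class AlignmentHit:
    """One retained local alignment from query to subject."""

    query: str
    subject: str
    score: float
    query_start: int
    query_end: int           # half-open end of the aligned query span
    coverage: float          # span / query length, gaps included
    evalue: float | None = None


@dataclass
class ParalogMap:
    """Per-gene ordered paralog candidates (ascending E, at most ``top_n``)."""

    hits: dict = field(default_factory=dict)   # gene -> list[AlignmentHit]
    top_n: int = 5

    @property
    def genes_with_paralogs(self) -> frozenset:
        return frozenset(g for g, h in self.hits.items() if h)

    def partners(self, gene: str) -> list:
        return [h.subject for h in self.hits.get(gene, [])]

    def to_records(self) -> list:
        return [
            {
                "gene": g,
                "rank": r,
                "paralog": h.subject,
                "score": h.score,
                "coverage": h.coverage,
                "evalue": h.evalue,
            }
            for g, hs in sorted(self.hits.items())
            for r, h in enumerate(hs, start=1)
        ]


def _validate_sequence(name: str, seq: str) -> None:
    if not seq:
        raise ValueError(f"sequence {name!r} is empty")
    for i, ch in enumerate(seq):
        if ch not in _AA_SET:
            raise ValueError(
                f"invalid residue {ch!r} at position {i + 1} in sequence {name!r}"
            )


def _span_and_score(aligner, query: str, subject: str):
    """Best local score plus the aligned (query, subject) spans."""
    score = aligner.score(query, subject)
    if score <= 0:
        return 0.0, (0, 0), (0, 0)
    aln = next(iter(aligner.align(query, subject)))
    q_seg = aln.aligned[0]
    s_seg = aln.aligned[1]
    return float(score), (int(q_seg[0][0]), int(q_seg[-1][1])), (
        int(s_seg[0][0]), int(s_seg[-1][1]),
    )


def local_align(query: str, subject: str, scheme: ScoringScheme | None = None) -> AlignmentHit:
    """Optimal affine-gap local alignment of ``query`` against ``subject``.

    Returns the raw score, the contiguous aligned query span and the query
    coverage (span / query length).  Dissimilar sequences with no positive
    scoring path get score 0 and coverage 0.
    """
    scheme = scheme or ScoringScheme()
    _validate_sequence("query", query)
    _validate_sequence("subject", subject)
    score, (qs, qe), _ = _span_and_score(scheme.aligner(), query, subject)
    return AlignmentHit(
        query="query", subject="subject", score=score, query_start=qs, query_end=qe,
        coverage=(qe - qs) / len(query),
    )


def hit_evalue(score, query_len: int, db_residues: int, scheme: ScoringScheme | None = None) -> float:
    """Karlin–Altschul E-value: ``E = K * m * n * exp(-lambda * S)``.

    ``m`` is the query length and ``n`` the total number of residues in the
    database searched.  ``score`` may be an :class:`AlignmentHit` or a raw
    score.
    """
    scheme = scheme or ScoringScheme()
    s = score.score if isinstance(score, AlignmentHit) else float(score)
    if s < 0:
        raise ValueError("alignment score must be >= 0")
    return scheme.karlin_k * query_len * db_residues * math.exp(-scheme.lam * s)


def _candidate_pairs(names, seqs, k: int = 4, min_shared: int = 3, max_occurrence: int = 100):
    """Unordered index pairs sharing >= ``min_shared`` distinct k-mers.

    Words occurring in more than ``max_occurrence`` sequences are ignored as
    uninformative.  A hit at E <= 1e-20 needs a raw score of several hundred
    (a long, high-identity stretch) and therefore shares far more than
    ``min_shared`` words; unrelated pairs share ~0.25 on average.
    """
    posting: dict = {}
    for i, s in enumerate(seqs):
        for w in {s[j : j + k] for j in range(len(s) - k + 1)}:
            posting.setdefault(w, []).append(i)
    counts: dict = {}
    for members in posting.values():
        if len(members) < 2 or len(members) > max_occurrence:
            continue
        for a, b in itertools.combinations(members, 2):
            counts[(a, b)] = counts.get((a, b), 0) + 1
    return [pair for pair, c in counts.items() if c >= min_shared]


def find_paralogs(
    proteome: Mapping[str, str],
    scheme: ScoringScheme | None = None,
    e_max: float = 1e-20,
    cov_min: float = 0.80,
    top_n: int = 5,
    exhaustive: bool = False,
) -> ParalogMap:
    """All-vs-all paralog search over a proteome.

    For each query, hits against every other protein are filtered to
    ``E <= e_max`` and query coverage ``>= cov_min``, sorted by ascending
    E-value (ties: higher score, then subject id), and truncated to the top
    ``top_n``.  Self-hits are excluded; the listing is directional (A may
    retain B without B retaining A, e.g. when their lengths differ).
    """
    scheme = scheme or ScoringScheme()
    names = sorted(proteome)
    if len(names) < 2:
        raise ValueError("need at least two sequences to search for paralogs")
    for g in names:
        _validate_sequence(g, proteome[g])
    seqs = [proteome[g] for g in names]
    db_residues = sum(len(s) for s in seqs)
    aligner = scheme.aligner()

    if exhaustive:
        pairs = list(itertools.combinations(range(len(names)), 2))
    else:
        pairs = _candidate_pairs(names, seqs)

    # minimal score that can reach e_max for the shortest query of a pair
    def score_needed(m: int) -> float:
        return (math.log(scheme.karlin_k * m * db_residues) - math.log(e_max)) / scheme.lam

    hits: dict = {g: [] for g in names}
    for a, b in pairs:
        qa, qb = seqs[a], seqs[b]
        score = aligner.score(qa, qb)
        if score < min(score_needed(len(qa)), score_needed(len(qb))):
            continue
        score, (as_, ae), (bs, be) = _span_and_score(aligner, qa, qb)
        for qi, si, span in ((a, b, (as_, ae)), (b, a, (bs, be))):
            qlen = len(seqs[qi])
            ev = hit_evalue(score, qlen, db_residues, scheme)
            cov = (span[1] - span[0]) / qlen
            if ev <= e_max and cov >= cov_min:
                hits[names[qi]].append(
                    AlignmentHit(
                        query=names[qi], subject=names[si], score=score,
                        query_start=span[0], query_end=span[1], coverage=cov, evalue=ev,
                    )
                )
    for g in names:
        hits[g].sort(key=lambda h: (h.evalue, -h.score, h.subject))
        hits[g] = hits[g][:top_n]
    return ParalogMap(hits=hits, top_n=top_n)
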