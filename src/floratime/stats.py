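"""Shared statistical primitives: FDR step-up adjustments and exact set tests.

Benjamini–Hochberg is the default multiplicity correction for the
differential-expression scan; Benjamini–Yekutieli (valid under arbitrary
dependence) is used for term enrichment, matching common practice for
GO-style analyses.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy import stats as sps

__all__ = [
    "adjust_pvalues",
    "fisher_enrichment_p",
    "hypergeom_overlap",
    "OverlapResult",
]


def adjust_pvalues(pvalues, method: str = "bh") -> np.ndarray:
    """Step-up false-discovery-rate adjustment.

    Parameters
    ----------
    pvalues : array-like of float in [0, 1]
    method : "bh" (Benjamini–Hochberg) or "by" (Benjamini–Yekutieli).
        BY multiplies the BH factor by ``c(n) = sum_{i<=n} 1/i``.

    Returns
    -------
    ndarray of adjusted p-values, clipped to 1, monotone in the ranks.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1] and be non-missing")
    method = method.lower()
    if method not in {"bh", "by"}:
        raise ValueError(f"unknown method {method!r}; use 'bh' or 'by'")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    factor = n / np.arange(1, n + 1)
    if method == "by":
        factor = factor * np.sum(1.0 / np.arange(1, n + 1))
    adj = ranked * factor
    # step-up: running minimum from the largest p downwards
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(n, dtype=float)
    out[order] = adj
    return out


def fisher_enrichment_p(a, b, c, d, alternative: str = "greater"):
    """Fisher's exact test p-value for 2x2 table(s) [[a, b], [c, d]].

    ``a`` = annotated in-cluster, ``b`` = unannotated in-cluster,
    ``c`` = annotated outside, ``d`` = unannotated outside.  The one-sided
    "greater" alternative asks for enrichment of the annotation in the
    cluster and is the upper hypergeometric tail ``P(X >= a)`` with
    ``X ~ Hypergeom(N=a+b+c+d, K=a+c, n=a+b)``.  Inputs may be arrays.

    ``alternative="two-sided"`` sums the probabilities of all tables with
    point probability <= that observed (the classic Fisher rule); it is
    only supported for scalar input.
    """
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    c = np.asarray(c, dtype=np.int64)
    d = np.asarray(d, dtype=np.int64)
    if np.any(a < 0) or np.any(b < 0) or np.any(c < 0) or np.any(d < 0):
        raise ValueError("table counts must be non-negative")
    N = a + b + c + d
    K = a + c
    n = a + b
    if alternative == "greater":
        p = sps.hypergeom.sf(a - 1, N, K, n)
        return np.clip(p, 0.0, 1.0)
    if alternative == "two-sided":
        if a.ndim != 0:
            raise ValueError("two-sided test supports scalar tables only")
        return sps.fisher_exact([[int(a), int(b)], [int(c), int(d)]])[1]
    raise ValueError(f"unknown alternative {alternative!r}")


class OverlapResult(NamedTuple):
    overlap: int
    expected: float
    pvalue: float


def hypergeom_overlap(n_overlap: int, n_a: int, n_b: int, n_universe: int) -> OverlapResult:
    """Upper-tail hypergeometric p for the overlap of two gene lists.

    ``P(X >= n_overlap)`` with ``X ~ Hypergeom(N=n_universe, K=n_a, n=n_b)``;
    the expected overlap under independence is ``n_a * n_b / n_universe``.
    """
    if n_universe <= 0:
        raise ValueError("universe must be non-empty")
    if not (0 <= n_a <= n_universe and 0 <= n_b <= n_universe):
        raise ValueError("list sizes must lie within the universe")
    if n_overlap > min(n_a, n_b):
        raise ValueError("overlap cannot exceed either list")
    expected = n_a * n_b / n_universe
    p = float(sps.hypergeom.sf(n_overlap - 1, n_universe, n_a, n_b))
    return OverlapResult(int(n_overlap), expected, min(max(p, 0.0), 1.0))
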