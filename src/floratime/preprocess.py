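"""Two-channel array preprocessing.

Pipeline order: background subtraction (subtract method) -> within-array
loess normalization of M on A -> between-array quantile normalization of
the A-values (Aquantile) -> probe-to-gene averaging -> low-expression
filtering against the median intensity of negative-control probes.  Every
stage is a pure transformation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .containers import ExpressionMatrix

__all__ = [
    "RawArraySet",
    "background_subtract",
    "compute_ma",
    "normalize_within_loess",
    "normalize_between_aquantile",
    "quantile_normalize",
    "summarize_probes_to_genes",
    "filter_low_expression",
    "preprocess_two_channel",
]


@dataclass
class RawArraySet:
    """Raw (or background-corrected) probe intensities for a set of arrays.

    Red is the sample channel, green the common reference.  ``probe_gene``
    maps probes to gene ids (None/NaN for control probes); foreground and
    background frames are probes x arrays.
    """

    probe_gene: pd.Series
    is_control: pd.Series
    red_fg: pd.DataFrame
    red_bg: pd.DataFrame
    green_fg: pd.DataFrame
    green_bg: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.red_fg.index
        for name in ("red_bg", "green_fg", "green_bg"):
            fr = getattr(self, name)
            if fr is not None and not (
                fr.index.equals(idx) and fr.columns.equals(self.red_fg.columns)
            ):
                raise ValueError(f"{name} not aligned with red_fg")
        for name in ("red_fg", "green_fg"):
            if (getattr(self, name).to_numpy() < 0).any():
                raise ValueError(f"negative intensities in {name}")
        unmapped = self.probe_gene[~self.is_control].isna()
        if unmapped.any():
            raise ValueError(
                "non-control probes without a gene: "
                f"{self.probe_gene.index[~self.is_control][unmapped][:5].tolist()}"
            )

    @property
    def arrays(self) -> pd.Index:
        return self.red_fg.columns


def background_subtract(raw: RawArraySet) -> RawArraySet:
    """Subtract the background estimate from each channel.

    Non-positive corrected values are flagged missing (NaN) for that probe
    and array rather than floored, so no log-intensities are fabricated.
    """
    if raw.red_bg is None or raw.green_bg is None:
        raise ValueError("background columns are required for the subtract method")
    red = raw.red_fg - raw.red_bg
    green = raw.green_fg - raw.green_bg
    red = red.where(red > 0)
    green = green.where(green > 0)
    zeros = raw.red_bg * 0.0
    return replace(raw, red_fg=red, red_bg=zeros, green_fg=green, green_bg=zeros)


def compute_ma(raw: RawArraySet) -> tuple:
    """Probe-level (M, A) from corrected channels.

    M = log2(red/green), A = mean of the channel log2 intensities; missing
    wherever either channel is missing.
    """
    r = raw.red_fg - raw.red_bg
    g = raw.green_fg - raw.green_bg
    with np.errstate(divide="ignore", invalid="ignore"):
        lr = np.log2(r.where(r > 0))
        lg = np.log2(g.where(g > 0))
    return lr - lg, (lr + lg) / 2.0


def normalize_within_loess(
    M, A, span: float = 0.3, iterations: int = 4, fit_mask=None
) -> np.ndarray:
    """Within-array intensity-dependent normalization: M' = M - g(A).

    ``g`` is a robust locally weighted regression (tricube weights,
    ``iterations`` robustifying passes) of M on A.  ``fit_mask`` restricts
    the probes used to fit the trend (e.g. excluding control probes); the
    correction is applied to every finite probe by interpolation.
    """
    M = np.asarray(M, dtype=float)
    A = np.asarray(A, dtype=float)
    if M.shape != A.shape:
        raise ValueError("M and A must have the same length")
    finite = np.isfinite(M) & np.isfinite(A)
    fit = finite if fit_mask is None else (finite & np.asarray(fit_mask, dtype=bool))
    if fit.sum() < 50:
        raise ValueError(f"need >= 50 finite (M, A) pairs to fit loess, got {int(fit.sum())}")
    a_fit = A[fit]
    delta = 0.01 * (a_fit.max() - a_fit.min())
    smoothed = lowess(
        M[fit], a_fit, frac=span, it=iterations, delta=delta, return_sorted=True
    )
    out = M.copy()
    trend = np.interp(A[finite], smoothed[:, 0], smoothed[:, 1])
    out[finite] = M[finite] - trend
    return out


def quantile_normalize(df: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns; ties share the mean value of their ranks.

    Each column's empirical quantile function is replaced by the cross-array
    mean quantile function; missing values stay missing.  With equal finite
    counts per column the sorted output is identical across columns.
    """
    cols = {}
    counts = [int(np.isfinite(df[c].to_numpy()).sum()) for c in df.columns]
    if min(counts) < 2:
        raise ValueError("each array needs >= 2 finite values to quantile-normalize")
    m = max(counts)
    grid = np.linspace(0.0, 1.0, m)
    q_funcs = []
    for c in df.columns:
        v = df[c].to_numpy(dtype=float)
        sv = np.sort(v[np.isfinite(v)])
        p = np.linspace(0.0, 1.0, len(sv))
        q_funcs.append(np.interp(grid, p, sv))
    ref = np.mean(q_funcs, axis=0)
    for c in df.columns:
        v = df[c].astype(float)
        finite = np.isfinite(v.to_numpy())
        n = int(finite.sum())
        ranks = v[finite].rank(method="average").to_numpy()  # ties -> average rank
        p = (ranks - 1.0) / (n - 1.0)
        out = v.to_numpy().copy()
        out[finite] = np.interp(p, grid, ref)
        cols[c] = out
    return pd.DataFrame(cols, index=df.index)


def normalize_between_aquantile(arrays):
    """Between-array normalization of A-values (M untouched).

    ``arrays`` is a list of ``(M, A)`` pairs with identical probe sets;
    returns the list with A quantile-normalized across arrays.
    """
    if len(arrays) < 2:
        raise ValueError("need >= 2 arrays for between-array normalization")
    lengths = {len(np.asarray(a)) for _, a in arrays}
    if len(lengths) != 1:
        raise ValueError("arrays must share one probe set")
    n_probes = lengths.pop()
    if any(len(np.asarray(m)) != n_probes for m, _ in arrays):
        raise ValueError("arrays must share one probe set")
    A_df = pd.DataFrame({i: np.asarray(a, dtype=float) for i, (_, a) in enumerate(arrays)})
    A_norm = quantile_normalize(A_df)
    return [(np.asarray(m, dtype=float), A_norm[i].to_numpy()) for i, (m, _) in enumerate(arrays)]


def summarize_probes_to_genes(M: pd.DataFrame, A: pd.DataFrame | None, probe_gene: pd.Series):
    """Average probe-level values to gene level (finite probes only).

    A gene is missing on an array iff all its probes are missing there.
    """
    pg = probe_gene.reindex(M.index)
    orphans = pg.index[pg.isna()]
    if len(orphans):
        raise ValueError(f"probes mapped to zero genes: {orphans[:5].tolist()}")
    gene_M = M.groupby(pg).mean()
    gene_M.index.name = "gene"
    gene_A = None
    if A is not None:
        gene_A = A.groupby(pg).mean()
        gene_A.index.name = "gene"
    return gene_M, gene_A


def filter_low_expression(
    matrix: ExpressionMatrix, negctl_A: pd.DataFrame, min_arrays: int = 1
):
    """Drop genes that never rise above the negative-control background.

    Per array the threshold is the median A of the negative-control probes;
    a gene is retained iff its A exceeds that threshold on at least
    ``min_arrays`` arrays.  Returns ``(filtered matrix, removed gene list)``.
    """
    if negctl_A is None or len(negctl_A) == 0:
        raise ValueError("negative-control intensities are required for filtering")
    if matrix.A is None:
        raise ValueError("expression matrix lacks A-values; cannot filter on intensity")
    thresholds = negctl_A.median(axis=0).reindex(matrix.arrays)
    if thresholds.isna().any():
        raise ValueError("negative-control values missing for some arrays")
    above = (matrix.A > thresholds).sum(axis=1)
    keep = above >= min_arrays
    removed = matrix.genes[~keep].tolist()
    filtered = ExpressionMatrix(
        M=matrix.M.loc[keep], design=matrix.design, A=matrix.A.loc[keep]
    )
    return filtered, removed


def preprocess_two_channel(
    raw: RawArraySet, span: float = 0.3, iterations: int = 4, min_arrays: int = 1
):
    """Full preprocessing: subtract -> loess -> Aquantile -> summarize -> filter.

    Control probes are excluded from the loess fit and from gene
    summarization but are carried through normalization so the filtering
    thresholds live on the same scale as the gene intensities.  Returns
    ``(ExpressionMatrix, report dict)``.
    """
    corrected = background_subtract(raw)
    M, A = compute_ma(corrected)
    not_ctl = ~raw.is_control.to_numpy()
    M_norm = pd.DataFrame(
        {
            arr: normalize_within_loess(
                M[arr].to_numpy(), A[arr].to_numpy(), span=span,
                iterations=iterations, fit_mask=not_ctl,
            )
            for arr in M.columns
        },
        index=M.index,
    )
    A_norm = quantile_normalize(A)
    ctl_A = A_norm.loc[raw.is_control.to_numpy()]
    gene_M, gene_A = summarize_probes_to_genes(
        M_norm.loc[not_ctl], A_norm.loc[not_ctl], raw.probe_gene
    )
    em = ExpressionMatrix(M=gene_M, design=raw.design, A=gene_A)
    filtered, removed = filter_low_expression(em, ctl_A, min_arrays=min_arrays)
    report = {
        "n_probes": int(not_ctl.sum()),
        "n_controls": int((~not_ctl).sum()),
        "n_genes_in": int(len(em.genes)),
        "n_genes_removed": len(removed),
        "removed_genes": removed,
        "loess_span": span,
        "min_arrays": min_arrays,
    }
    return filtered, report
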