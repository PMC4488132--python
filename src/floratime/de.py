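"""Moderated differential expression over a time course.

The model is a one-way layout on time-point per gene: the coefficients are
the per-time-point replicate means of M, and the residual variance is the
pooled within-time-point variance.  Per-gene variances are then shrunk by
empirical Bayes towards a prior scale ``s0^2`` with prior degrees of
freedom ``d0``, both estimated by moment matching on the log residual
variances (trigamma inversion).  Two scans are offered:

* a global moderated F-test for any change across the course (a permissive
  "responsive gene" scan), and
* *windowed contrasts*: moderated t-tests of all time-point pairs lying
  within a window (default 2 days), which target rapid changes; a gene is
  called differentially expressed when some windowed contrast passes both
  an FDR-adjusted p threshold and a fold-change threshold.

`TimecourseDE` / `TimecourseDEResults` present this as a model/results
pair; the functional surface (`fit_linear_model`, `moderate_variances`,
`global_f_test`, `windowed_contrasts`, `call_degs`) exposes each step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats as sps
from statsmodels.iolib.table import SimpleTable

from .containers import ExpressionMatrix
from .stats import adjust_pvalues

__all__ = [
    "ModelFit",
    "ModeratedFit",
    "fit_linear_model",
    "moderate_variances",
    "trigamma_inverse",
    "global_f_test",
    "windowed_contrasts",
    "window_pairs",
    "call_degs",
    "TimecourseDE",
    "TimecourseDEResults",
]


# ----------------------------------------------------------------------
# per-gene linear model
# ----------------------------------------------------------------------
@dataclass
class ModelFit:
    """Per-gene one-way fit: time-point means, residual variance and df."""

    coef: pd.DataFrame          # genes x time-points, replicate means of M
    n_per_group: pd.DataFrame   # genes x time-points, finite replicate counts
    s2: pd.Series               # residual variance
    df: pd.Series               # residual degrees of freedom
    untestable: list            # genes with df < 1 or < 2 time-points

    @property
    def time_points(self) -> np.ndarray:
        return self.coef.columns.to_numpy(dtype=float)


@dataclass
class ModeratedFit(ModelFit):
    """ModelFit plus empirical-Bayes shrinkage hyperparameters.

    ``s2_post = (d0 * s0_sq + df * s2) / (d0 + df)``; with ``d0 = inf``
    every posterior variance equals ``s0_sq``.
    """

    d0: float = np.nan
    s0_sq: float = np.nan
    s2_post: pd.Series = None

    @property
    def total_df(self) -> pd.Series:
        return self.df + (self.d0 if math.isfinite(self.d0) else np.inf)


def fit_linear_model(matrix: ExpressionMatrix) -> ModelFit:
    """Fit the one-way time-point layout to every gene.

    Coefficients are per-time-point means over replicates; ``s2`` is the
    usual unbiased pooled residual variance with ``df = n_obs - n_groups``.
    Genes with fewer than two observed time-points or no residual df are
    flagged untestable (NaN statistics) and listed.
    """
    times = matrix.array_times().to_numpy()
    tp = np.sort(np.unique(times))
    X = matrix.M.to_numpy(dtype=float)
    n_genes = X.shape[0]
    coef = np.full((n_genes, len(tp)), np.nan)
    counts = np.zeros((n_genes, len(tp)), dtype=int)
    rss = np.zeros(n_genes)
    for j, t in enumerate(tp):
        cols = times == t
        block = X[:, cols]
        finite = np.isfinite(block)
        n = finite.sum(axis=1)
        counts[:, j] = n
        with np.errstate(invalid="ignore"):
            mean = np.nansum(np.where(finite, block, 0.0), axis=1) / np.where(n > 0, n, 1)
        coef[:, j] = np.where(n > 0, mean, np.nan)
        resid = np.where(finite, block - mean[:, None], 0.0)
        rss += (resid**2).sum(axis=1)
    k = (counts > 0).sum(axis=1)
    df = counts.sum(axis=1) - k
    testable = (k >= 2) & (df >= 1)
    s2 = np.where(df > 0, rss / np.where(df > 0, df, 1), np.nan)
    s2 = np.where(testable, s2, np.nan)
    genes = matrix.genes
    return ModelFit(
        coef=pd.DataFrame(coef, index=genes, columns=tp),
        n_per_group=pd.DataFrame(counts, index=genes, columns=tp),
        s2=pd.Series(s2, index=genes, name="s2"),
        df=pd.Series(np.where(testable, df, 0), index=genes, name="df").astype(float),
        untestable=genes[~testable].tolist(),
    )


# ----------------------------------------------------------------------
# empirical-Bayes variance moderation
# ----------------------------------------------------------------------
def trigamma_inverse(y: float) -> float:
    """Solve ``trigamma(x) = y`` for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma_inverse requires y > 0")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x = x + dif
        if -dif / x < 1e-10:
            break
    return x


def moderate_variances(fit: ModelFit) -> ModeratedFit:
    """Estimate ``(d0, s0_sq)`` and squeeze the per-gene variances.

    Moment matching on ``e = log s2 - psi(df/2) + log(df/2)``:
    ``mean(e) = log s0_sq + psi(d0/2) - log(d0/2)`` and
    ``var(e) = psi'(d0/2) + mean psi'(df/2)``, solved by trigamma
    inversion.  If the empirical spread of ``e`` is no larger than expected
    from the per-gene sampling variability alone, ``d0`` is infinite and
    every posterior variance equals ``s0_sq``.
    """
    ok = (fit.df >= 1) & fit.s2.notna()
    s2 = fit.s2[ok]
    d = fit.df[ok]
    if len(s2) == 0 or (s2 <= 0).all():
        raise ValueError("all residual variances are zero or missing; cannot moderate")
    pos = s2 > 0
    s2p = s2[pos].to_numpy()
    dp = d[pos].to_numpy()
    if len(s2p) < 2:
        raise ValueError("need >= 2 positive residual variances to estimate the prior")
    e = np.log(s2p) - special.digamma(dp / 2.0) + np.log(dp / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, dp / 2.0).mean())
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(s2p.mean())
    if math.isfinite(d0):
        s2_post = (d0 * s0_sq + fit.df * fit.s2) / (d0 + fit.df)
    else:
        s2_post = pd.Series(
            np.where(fit.s2.notna(), s0_sq, np.nan), index=fit.s2.index
        )
    return ModeratedFit(
        coef=fit.coef,
        n_per_group=fit.n_per_group,
        s2=fit.s2,
        df=fit.df,
        untestable=fit.untestable,
        d0=d0,
        s0_sq=s0_sq,
        s2_post=pd.Series(s2_post, index=fit.s2.index, name="s2_post"),
    )


# ----------------------------------------------------------------------
# tests
# ----------------------------------------------------------------------
def _df2(mfit: ModeratedFit) -> np.ndarray:
    d0 = mfit.d0 if math.isfinite(mfit.d0) else np.inf
    return mfit.df.to_numpy() + d0


def global_f_test(mfit: ModeratedFit, alpha: float = 0.01) -> pd.DataFrame:
    """Moderated F for equality of all time-point coefficients, per gene.

    BH adjustment across genes; ``responsive`` = adjusted p < ``alpha``.
    Untestable genes are excluded from the returned table.
    """
    coef = mfit.coef.to_numpy()
    n = mfit.n_per_group.to_numpy(dtype=float)
    present = n > 0
    k = present.sum(axis=1)
    ntot = n.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        grand = np.nansum(np.where(present, coef * n, 0.0), axis=1) / ntot
        msb = (
            np.nansum(np.where(present, n * (coef - grand[:, None]) ** 2, 0.0), axis=1)
            / np.maximum(k - 1, 1)
        )
        F = msb / mfit.s2_post.to_numpy()
    testable = mfit.s2_post.notna().to_numpy() & (k >= 2) & (mfit.df.to_numpy() >= 1)
    df1 = k - 1.0
    df2 = _df2(mfit)
    p = np.full(len(F), np.nan)
    finite_df2 = np.isfinite(df2)
    sel = testable & finite_df2
    p[sel] = sps.f.sf(F[sel], df1[sel], df2[sel])
    sel_inf = testable & ~finite_df2
    p[sel_inf] = sps.chi2.sf(F[sel_inf] * df1[sel_inf], df1[sel_inf])
    out = pd.DataFrame(
        {"F": F, "df1": df1, "df2": df2, "pvalue": p}, index=mfit.coef.index
    )[testable]
    out["padj"] = adjust_pvalues(out["pvalue"].to_numpy(), method="bh")
    out["responsive"] = out["padj"] < alpha
    return out


def window_pairs(time_points, window: float = 2.0) -> list:
    """Ordered time-point pairs (t_i < t_j) with t_j - t_i <= window (inclusive)."""
    if window < 0:
        raise ValueError("window must be >= 0")
    tp = np.asarray(time_points, dtype=float)
    return [
        (tp[i], tp[j])
        for i in range(len(tp))
        for j in range(i + 1, len(tp))
        if tp[j] - tp[i] <= window + 1e-9
    ]


def windowed_contrasts(
    mfit: ModeratedFit, window: float = 2.0, pooling: str = "global"
) -> pd.DataFrame:
    """Moderated t for every time-point pair within the window, per gene.

    ``t = (coef_j - coef_i) / (s_post * sqrt(1/n_i + 1/n_j))`` on
    ``df + d0`` degrees of freedom.  One FDR adjustment pools all
    gene x contrast p-values (``pooling="global"``, the default, i.e.
    "across the experiment"); ``pooling="per_contrast"`` adjusts within
    each time-point pair instead.
    """
    if pooling not in {"global", "per_contrast"}:
        raise ValueError("pooling must be 'global' or 'per_contrast'")
    pairs = window_pairs(mfit.time_points, window)
    genes = mfit.coef.index
    s_post = np.sqrt(mfit.s2_post.to_numpy())
    df2 = _df2(mfit)
    blocks = []
    tp = mfit.time_points
    col = {t: i for i, t in enumerate(tp)}
    coef = mfit.coef.to_numpy()
    n = mfit.n_per_group.to_numpy(dtype=float)
    for ti, tj in pairs:
        i, j = col[ti], col[tj]
        with np.errstate(invalid="ignore", divide="ignore"):
            fc = coef[:, j] - coef[:, i]
            se = s_post * np.sqrt(1.0 / n[:, i] + 1.0 / n[:, j])
            tstat = fc / se
        finite_df = np.isfinite(df2)
        p = np.full(len(genes), np.nan)
        with np.errstate(invalid="ignore"):
            p[finite_df] = 2.0 * sps.t.sf(np.abs(tstat[finite_df]), df2[finite_df])
            p[~finite_df] = 2.0 * sps.norm.sf(np.abs(tstat[~finite_df]))
        blocks.append(
            pd.DataFrame(
                {
                    "gene": genes,
                    "time_i": ti,
                    "time_j": tj,
                    "log2fc": fc,
                    "t": tstat,
                    "pvalue": p,
                }
            )
        )
    if not blocks:
        return pd.DataFrame(
            columns=["gene", "time_i", "time_j", "log2fc", "t", "pvalue", "padj"]
        )
    table = pd.concat(blocks, ignore_index=True)
    table = table[np.isfinite(table["pvalue"])].reset_index(drop=True)
    if pooling == "global":
        table["padj"] = adjust_pvalues(table["pvalue"].to_numpy(), method="bh")
    else:
        table["padj"] = table.groupby(["time_i", "time_j"])["pvalue"].transform(
            lambda p: adjust_pvalues(p.to_numpy(), method="bh")
        )
    return table


def call_degs(
    contrasts: pd.DataFrame, alpha: float = 0.01, fc_min: float = 1.7
) -> pd.DataFrame:
    """Call differentially expressed genes from the windowed-contrast table.

    A gene is a DEG iff some contrast has adjusted p < ``alpha`` and
    |fold change| >= ``fc_min`` (inclusive, on the fitted contrast
    coefficient: FC = 2^|log2fc|).  The best contrast is the passing one
    with the smallest adjusted p (ties broken by larger |log2fc|); for
    non-DEGs it is the overall smallest-p contrast.
    """
    lfc_min = np.log2(fc_min)
    ct = contrasts.copy()
    ct["abs_lfc"] = ct["log2fc"].abs()
    ct["passes"] = (ct["padj"] < alpha) & (ct["abs_lfc"] >= lfc_min - 1e-12)
    ct = ct.sort_values(
        ["gene", "passes", "padj", "abs_lfc"], ascending=[True, False, True, False]
    )
    best = ct.groupby("gene", sort=True).first()
    agg = ct.groupby("gene", sort=True).agg(
        max_abs_log2fc=("abs_lfc", "max"), min_padj=("padj", "min"), is_deg=("passes", "any")
    )
    out = pd.DataFrame(
        {
            "best_time_i": best["time_i"],
            "best_time_j": best["time_j"],
            "direction": np.where(best["log2fc"] >= 0, "up", "down"),
            "max_abs_log2fc": agg["max_abs_log2fc"],
            "min_padj": agg["min_padj"],
            "is_deg": agg["is_deg"],
        }
    )
    out.index.name = "gene"
    return out


# ----------------------------------------------------------------------
# model / results presentation
# ----------------------------------------------------------------------
class TimecourseDE:
    """Per-gene time-course differential-expression model.

    Parameters
    ----------
    data : ExpressionMatrix
        Gene-level M-values with a (time-point, replicate) design.

    Examples
    --------
    >>> model = TimecourseDE(matrix)          # doctest: +SKIP
    >>> res = model.fit()                     # doctest: +SKIP
    >>> degs = res.call_degs(alpha=0.01, fc_min=1.7)  # doctest: +SKIP
    """

    def __init__(self, data: ExpressionMatrix):
        self.data = data

    @classmethod
    def from_dataframe(cls, M: pd.DataFrame, design: pd.DataFrame) -> "TimecourseDE":
        return cls(ExpressionMatrix(M=M, design=design))

    def fit(self, moderate: bool = True) -> "TimecourseDEResults":
        fit = fit_linear_model(self.data)
        if moderate:
            fit = moderate_variances(fit)
        else:
            fit = ModeratedFit(
                coef=fit.coef, n_per_group=fit.n_per_group, s2=fit.s2, df=fit.df,
                untestable=fit.untestable, d0=0.0, s0_sq=np.nan, s2_post=fit.s2.copy(),
            )
        return TimecourseDEResults(self, fit)


class TimecourseDEResults:
    """Fitted per-gene time-course model with moderated variances."""

    def __init__(self, model: TimecourseDE, fit: ModeratedFit):
        self.model = model
        self.fit_ = fit
        self._contrasts: pd.DataFrame | None = None
        self._contrast_key = None

    # convenient views -------------------------------------------------
    coef = property(lambda self: self.fit_.coef)
    s2 = property(lambda self: self.fit_.s2)
    df_resid = property(lambda self: self.fit_.df)
    d0 = property(lambda self: self.fit_.d0)
    s0_sq = property(lambda self: self.fit_.s0_sq)
    s2_post = property(lambda self: self.fit_.s2_post)
    untestable = property(lambda self: self.fit_.untestable)

    def f_test(self, alpha: float = 0.01) -> pd.DataFrame:
        return global_f_test(self.fit_, alpha=alpha)

    def windowed_contrasts(self, window: float = 2.0, pooling: str = "global") -> pd.DataFrame:
        key = (window, pooling)
        if self._contrast_key != key:
            self._contrasts = windowed_contrasts(self.fit_, window=window, pooling=pooling)
            self._contrast_key = key
        return self._contrasts

    def call_degs(
        self,
        alpha: float = 0.01,
        fc_min: float = 1.7,
        window: float = 2.0,
        pooling: str = "global",
    ) -> pd.DataFrame:
        return call_degs(self.windowed_contrasts(window, pooling), alpha=alpha, fc_min=fc_min)

    def summary(self, alpha: float = 0.01, fc_min: float = 1.7, window: float = 2.0) -> str:
        """Text summary: design, shrinkage hyperparameters and DEG counts."""
        ftab = self.f_test(alpha=alpha)
        degs = self.call_degs(alpha=alpha, fc_min=fc_min, window=window)
        rows = [
            ("genes tested", f"{len(self.fit_.s2.dropna())}"),
            ("genes untestable", f"{len(self.untestable)}"),
            ("time-points", f"{len(self.fit_.time_points)}"),
            ("prior df (d0)", f"{self.d0:.4g}"),
            ("prior scale (s0^2)", f"{self.s0_sq:.4g}"),
            ("responsive genes (F, padj < %.3g)" % alpha, f"{int(ftab['responsive'].sum())}"),
            ("windowed contrasts per gene", f"{len(window_pairs(self.fit_.time_points, window))}"),
            (
                "DEGs (padj < %.3g, FC >= %.3g)" % (alpha, fc_min),
                f"{int(degs['is_deg'].sum())}",
            ),
        ]
        table = SimpleTable(
            [[v] for _, v in rows],
            headers=["value"],
            stubs=[k for k, _ in rows],
            title="Time-course differential expression (moderated one-way layout)",
        )
        return table.as_text()
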