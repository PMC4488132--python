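"""Core in-memory containers shared across the pipeline.

The central object is :class:`ExpressionMatrix`: genes x arrays of M-values
(log2 of sample over common reference) from a common-reference two-channel
design, together with the design metadata (which array was hybridised at
which time-point, in which replicate).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "make_design"]


def make_design(time_points, n_replicates: int) -> pd.DataFrame:
    """Build a tidy design table for a complete time-course layout.

    Array ids are ``t{time}_r{rep}``; one array per (time-point, replicate).
    """
    rows = [
        {"array": f"t{t:g}_r{r}", "time_point": float(t), "replicate": r}
        for r in range(1, n_replicates + 1)
        for t in time_points
    ]
    return pd.DataFrame(rows).set_index("array")


@dataclass
class ExpressionMatrix:
    """Gene-level M-values (and optional A-values) with their design.

    Parameters
    ----------
    M : DataFrame, genes x arrays
        log2(sample / common reference) per gene and array.
    design : DataFrame indexed by array id
        Columns ``time_point`` (days, float) and ``replicate``.
    A : DataFrame or None
        Average log2 intensity per gene and array, aligned with ``M``.
    """

    M: pd.DataFrame
    design: pd.DataFrame
    A: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.M.index.has_duplicates:
            dups = self.M.index[self.M.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        missing = [a for a in self.M.columns if a not in self.design.index]
        if missing:
            raise ValueError(f"arrays absent from design: {missing[:5]}")
        for col in ("time_point", "replicate"):
            if col not in self.design.columns:
                raise ValueError(f"design lacks required column {col!r}")
        if self.A is not None:
            if not (
                self.A.index.equals(self.M.index)
                and self.A.columns.equals(self.M.columns)
            ):
                raise ValueError("A must be aligned with M (same genes/arrays)")

    # ------------------------------------------------------------------
    @property
    def genes(self) -> pd.Index:
        return self.M.index

    @property
    def arrays(self) -> pd.Index:
        return self.M.columns

    @property
    def time_points(self) -> np.ndarray:
        """Sorted unique time-points (days) present in the design."""
        return np.sort(self.design["time_point"].unique())

    @property
    def n_replicates(self) -> int:
        return int(self.design["replicate"].nunique())

    # ------------------------------------------------------------------
    def array_times(self) -> pd.Series:
        """Time-point (days) per array, in M column order."""
        return self.design.loc[self.arrays, "time_point"]

    def replicate_matrix(self, replicate) -> pd.DataFrame:
        """Genes x time-points M matrix of a single replicate."""
        sub = self.design[self.design["replicate"] == replicate]
        cols = [a for a in self.arrays if a in sub.index]
        mat = self.M[cols].copy()
        mat.columns = self.design.loc[cols, "time_point"].to_numpy()
        return mat.sort_index(axis=1)

    def replicate_average(self) -> pd.DataFrame:
        """Genes x time-points matrix of per-time-point means across replicates."""
        times = self.array_times()
        avg = self.M.T.groupby(times.to_numpy()).mean().T
        return avg.reindex(columns=np.sort(avg.columns.to_numpy()))

    def subset_genes(self, genes) -> "ExpressionMatrix":
        genes = pd.Index(genes)
        absent = genes.difference(self.M.index)
        if len(absent):
            raise KeyError(f"genes not in matrix: {list(absent[:5])}")
        return ExpressionMatrix(
            M=self.M.loc[genes],
            design=self.design,
            A=None if self.A is None else self.A.loc[genes],
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ExpressionMatrix({self.M.shape[0]} genes x {self.M.shape[1]} arrays, "
            f"{len(self.time_points)} time-points, {self.n_replicates} replicates)"
        )
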