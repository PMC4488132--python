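"""File formats: headered TSV tables, BED6 intervals, GMT gene sets, FASTA.

All text, all UTF-8.  Readers validate strictly and report the offending
file, line and rule; genomic coordinates are 0-based half-open (BED
dialect) throughout the package.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import ExpressionMatrix
from .setscan import GeneModel, GenomicInterval

__all__ = [
    "write_expression", "read_expression",
    "write_table", "read_table",
    "write_bed6", "read_bed6",
    "write_gene_models", "read_gene_models",
    "write_gmt", "read_gmt",
    "write_fasta", "read_fasta",
    "write_yaml", "read_yaml",
    "write_json", "read_json",
]


# ----------------------------------------------------------------------
# tabular
# ----------------------------------------------------------------------
def write_table(df: pd.DataFrame, path, index_label=None) -> None:
    df.to_csv(path, sep="\t", index_label=index_label or df.index.name or "id")


def read_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_expression(em: ExpressionMatrix, m_path, design_path, a_path=None) -> None:
    """Write an ExpressionMatrix as gene x array M TSV plus a design TSV."""
    write_table(em.M, m_path, index_label="gene")
    write_table(em.design, design_path, index_label="array")
    if a_path is not None and em.A is not None:
        write_table(em.A, a_path, index_label="gene")


def read_expression(m_path, design_path, a_path=None) -> ExpressionMatrix:
    M = read_table(m_path)
    M.columns.name = "array"
    design = read_table(design_path)
    if "time_point" not in design.columns or "replicate" not in design.columns:
        raise ValueError(f"{design_path}: design needs 'time_point' and 'replicate' columns")
    A = read_table(a_path) if a_path is not None else None
    return ExpressionMatrix(M=M, design=design, A=A)


# ----------------------------------------------------------------------
# BED-like intervals and gene models
# ----------------------------------------------------------------------
def write_bed6(intervals, path) -> None:
    """Write GenomicIntervals as 6-column BED (0-based half-open)."""
    with open(path, "w", encoding="utf-8") as fh:
        for iv in intervals:
            score = "." if iv.score is None else f"{iv.score:g}"
            name = iv.name or "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t.\n")


def _parse_bed_line(path, lineno: int, line: str, n_min: int):
    fields = line.rstrip("\n").split("\t")
    if len(fields) < n_min:
        raise ValueError(f"{path}:{lineno}: expected >= {n_min} tab-separated fields")
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: start/end must be integers") from exc
    if not (0 <= start < end):
        raise ValueError(f"{path}:{lineno}: need 0 <= start < end, got {start}..{end}")
    return fields, start, end


def read_bed6(path) -> list:
    """Read peaks from BED (3+ columns); name/score kept when present."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields, start, end = _parse_bed_line(path, lineno, line, 3)
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] != ".":
                score = float(fields[4])
            out.append(GenomicInterval(fields[0], start, end, name=name, score=score))
    return out


def write_gene_models(models, path) -> None:
    """Write gene models as BED6 with the gene id in the name column."""
    with open(path, "w", encoding="utf-8") as fh:
        for gm in models:
            fh.write(f"{gm.chrom}\t{gm.start}\t{gm.end}\t{gm.gene_id}\t.\t{gm.strand}\n")


def read_gene_models(path) -> list:
    out, seen = [], set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields, start, end = _parse_bed_line(path, lineno, line, 6)
            gene_id, strand = fields[3], fields[5]
            if strand not in {"+", "-"}:
                raise ValueError(f"{path}:{lineno}: strand must be '+' or '-', got {strand!r}")
            if gene_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene id {gene_id!r}")
            seen.add(gene_id)
            out.append(GeneModel(gene_id=gene_id, chrom=fields[0], start=start, end=end, strand=strand))
    return out


# ----------------------------------------------------------------------
# GMT gene sets
# ----------------------------------------------------------------------
def write_gmt(term_map, path, descriptions=None) -> None:
    descriptions = descriptions or {}
    with open(path, "w", encoding="utf-8") as fh:
        for term in sorted(term_map):
            desc = descriptions.get(term, "na")
            genes = "\t".join(sorted(term_map[term]))
            fh.write(f"{term}\t{desc}\t{genes}\n")


def read_gmt(path) -> dict:
    term_map = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT needs term, description, >= 1 gene")
            term = fields[0]
            if term in term_map:
                raise ValueError(f"{path}:{lineno}: duplicate term {term!r}")
            term_map[term] = set(g for g in fields[2:] if g)
    return term_map


# ----------------------------------------------------------------------
# FASTA proteome
# ----------------------------------------------------------------------
def write_fasta(proteome, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=gene, description="") for gene, seq in sorted(proteome.items())
    ]
    SeqIO.write(records, path, "fasta")


def read_fasta(path) -> dict:
    proteome = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in proteome:
            raise ValueError(f"{path}: duplicate sequence id {record.id!r}")
        proteome[record.id] = str(record.seq)
    if not proteome:
        raise ValueError(f"{path}: no FASTA records found")
    return proteome


# ----------------------------------------------------------------------
# config and summaries
# ----------------------------------------------------------------------
def write_yaml(obj, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def read_yaml(path):
    with open(path, encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, (set, frozenset, tuple)):
        return sorted(obj) if isinstance(obj, (set, frozenset)) else list(obj)
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def write_json(obj, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)


def read_json(path):
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
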