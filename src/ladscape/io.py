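"""Plain-text genomics I/O: BED3/BED6, bedGraph, chrom-sizes and gene tables.

Readers convert everything to 0-based half-open coordinates (BED and
bedGraph already are; any 1-based dialect must be converted by the caller
before it reaches these functions). Writers emit tab-separated text that
round-trips bit-exactly through the matching reader.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Mapping, Union

import pandas as pd

from .intervals import GenomicInterval, IntervalSet

PathLike = Union[str, Path]

GENE_COLUMNS = ["gene_id", "chrom", "tss", "strand", "expression"]


def read_genome(path: PathLike) -> Dict[str, int]:
    """Read a two-column chrom-size TSV (``chrom<TAB>length``)."""
    genome: Dict[str, int] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected 'chrom<TAB>length'")
        genome[parts[0]] = int(parts[1])
    return genome


def write_genome(genome: Mapping[str, int], path: PathLike) -> None:
    Path(path).write_text(
        "".join(f"{c}\t{l}\n" for c, l in genome.items())
    )


def read_bed(path: PathLike, genome: Mapping[str, int]) -> IntervalSet:
    """Read BED3/BED6 into a normalized :class:`IntervalSet`."""
    ivs: List[GenomicInterval] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
        name = parts[3] if len(parts) > 3 else None
        strand = parts[5] if len(parts) > 5 else "."
        try:
            ivs.append(
                GenomicInterval(parts[0], int(parts[1]), int(parts[2]), strand, name)
            )
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return IntervalSet(ivs, genome)


def write_bed(iset: IntervalSet, path: PathLike) -> None:
    """Write an interval set as BED3 (normalized intervals, sorted)."""
    with open(path, "w") as fh:
        for iv in iset:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_bedgraph(path: PathLike) -> pd.DataFrame:
    """Read a 4-column bedGraph into a DataFrame (chrom, start, end, value)."""
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise ValueError(f"{path}:{lineno}: bedGraph needs 4 columns")
        rows.append((parts[0], int(parts[1]), int(parts[2]), float(parts[3])))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def write_bedgraph(df: pd.DataFrame, path: PathLike) -> None:
    df = df[["chrom", "start", "end", "value"]]
    with open(path, "w") as fh:
        for chrom, start, end, value in df.itertuples(index=False):
            fh.write(f"{chrom}\t{start}\t{end}\t{value:.6g}\n")


def read_gene_table(path: PathLike) -> pd.DataFrame:
    """Read the gene-model TSV (gene_id, chrom, tss, strand, expression)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in GENE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: gene table missing columns {missing}")
    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        raise ValueError(f"{path}: gene strand must be '+' or '-'")
    return df


def write_gene_table(df: pd.DataFrame, path: PathLike) -> None:
    df[GENE_COLUMNS].to_csv(path, sep="\t", index=False)
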