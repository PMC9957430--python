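"""Coverage-track arithmetic and expression utilities.

Implements the signal layer of the pipeline: fixed-bin coverage tracks,
log2(ChIP/input) ratio tracks, meta-profiles around transcription start
sites, the expressed-gene filter (normalized read count >= 15), and
2^-ddCt relative expression for qPCR readouts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .intervals import IntervalSet

__all__ = [
    "CoverageTrack",
    "GeneModel",
    "TSSProfile",
    "log2_ratio_track",
    "tss_metaprofile",
    "filter_expressed",
    "relative_expression",
]


@dataclass(frozen=True)
class GeneModel:
    """A gene reduced to its TSS, strand and normalized expression level."""

    gene_id: str
    chrom: str
    tss: int
    strand: str
    expression: float

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if self.expression < 0:
            raise ValueError(f"gene {self.gene_id}: negative expression")


class CoverageTrack:
    """Per-bin real-valued signal over a genome on a fixed bin grid.

    ``values[chrom]`` is a float array of length ``ceil(length / bin_size)``;
    missing data is NaN (never silently zero).
    """

    def __init__(
        self,
        genome: Mapping[str, int],
        bin_size: int,
        values: Optional[Mapping[str, np.ndarray]] = None,
    ) -> None:
        if bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        self.genome = dict(genome)
        self.bin_size = int(bin_size)
        self.values: Dict[str, np.ndarray] = {}
        for chrom, length in self.genome.items():
            n = -(-length // bin_size)  # ceil
            if values is not None and chrom in values:
                arr = np.asarray(values[chrom], dtype=float)
                if arr.shape != (n,):
                    raise ValueError(
                        f"{chrom}: expected {n} bins of size {bin_size}, got {arr.shape}"
                    )
                self.values[chrom] = arr.copy()
            else:
                self.values[chrom] = np.full(n, np.nan)

    # -- construction -------------------------------------------------------

    @classmethod
    def from_bedgraph(
        cls, df: pd.DataFrame, genome: Mapping[str, int], bin_size: int
    ) -> "CoverageTrack":
        """Rasterize a bedGraph onto the bin grid (length-weighted per bin)."""
        track = cls(genome, bin_size)
        sums: Dict[str, np.ndarray] = {
            c: np.zeros_like(v) for c, v in track.values.items()
        }
        weights: Dict[str, np.ndarray] = {
            c: np.zeros_like(v) for c, v in track.values.items()
        }
        for chrom, start, end, value in df[
            ["chrom", "start", "end", "value"]
        ].itertuples(index=False):
            if chrom not in track.values:
                raise ValueError(f"bedGraph chromosome {chrom!r} not in genome")
            first, last = start // bin_size, (end - 1) // bin_size
            for b in range(first, last + 1):
                lo, hi = max(start, b * bin_size), min(end, (b + 1) * bin_size)
                sums[chrom][b] += value * (hi - lo)
                weights[chrom][b] += hi - lo
        for chrom in track.values:
            with np.errstate(invalid="ignore"):
                track.values[chrom] = np.where(
                    weights[chrom] > 0, sums[chrom] / np.maximum(weights[chrom], 1), np.nan
                )
        return track

    def to_bedgraph(self) -> pd.DataFrame:
        rows = []
        for chrom, arr in sorted(self.values.items()):
            length = self.genome[chrom]
            for b, v in enumerate(arr):
                if np.isfinite(v):
                    rows.append(
                        (chrom, b * self.bin_size, min((b + 1) * self.bin_size, length), v)
                    )
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])

    # -- access -------------------------------------------------------------

    def value_at(self, chrom: str, pos: int) -> float:
        """Signal of the bin containing base *pos* (NaN outside the genome)."""
        if chrom not in self.values or pos < 0 or pos >= self.genome[chrom]:
            return float("nan")
        return float(self.values[chrom][pos // self.bin_size])

    def same_grid(self, other: "CoverageTrack") -> bool:
        return self.genome == other.genome and self.bin_size == other.bin_size


@dataclass
class TSSProfile:
    """Mean signal as a function of offset from the TSS (strand-oriented)."""

    flank: int
    bin: int
    positions: np.ndarray  # offsets, -flank .. +flank inclusive
    mean_signal: np.ndarray
    n: np.ndarray  # genes contributing per position
    n_genes: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"offset": self.positions, "mean": self.mean_signal, "n": self.n}
        )


def log2_ratio_track(
    chip: CoverageTrack, input_: CoverageTrack, pseudocount: float = 1.0
) -> CoverageTrack:
    """Per-bin log2((chip + c) / (input + c)).

    Bins where both signals are zero (no evidence at all) are reported as
    missing rather than 0, so downstream means are not diluted by
    unmappable regions.
    """
    if not chip.same_grid(input_):
        raise ValueError("chip and input tracks are on different bin grids")
    out = CoverageTrack(chip.genome, chip.bin_size)
    for chrom in chip.values:
        a, b = chip.values[chrom], input_.values[chrom]
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.log2((a + pseudocount) / (b + pseudocount))
        both_zero = (a == 0) & (b == 0)
        ratio[both_zero] = np.nan
        out.values[chrom] = ratio
    return out


def tss_metaprofile(
    track: CoverageTrack,
    genes: Sequence[GeneModel],
    flank: int = 4000,
    bin: int = 50,
) -> TSSProfile:
    """Mean signal around TSSs, oriented so +offset is downstream.

    Minus-strand genes are mirrored (offset ``+o`` samples ``tss - o``);
    genes whose window runs off the chromosome contribute only the covered
    positions. Positions are offsets ``-flank, -flank+bin, ..., +flank``.
    """
    if not genes:
        raise ValueError("tss_metaprofile needs at least one gene")
    if flank % bin != 0:
        raise ValueError("flank must be a multiple of bin")
    offsets = np.arange(-flank, flank + bin, bin)
    total = np.zeros(offsets.shape, dtype=float)
    count = np.zeros(offsets.shape, dtype=int)
    for g in genes:
        sign = 1 if g.strand == "+" else -1
        for k, off in enumerate(offsets):
            v = track.value_at(g.chrom, g.tss + sign * int(off))
            if np.isfinite(v):
                total[k] += v
                count[k] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return TSSProfile(
        flank=flank,
        bin=bin,
        positions=offsets,
        mean_signal=mean,
        n=count,
        n_genes=len(genes),
    )


def filter_expressed(
    genes: Sequence[GeneModel], threshold: float = 15.0
) -> Tuple[List[GeneModel], List[GeneModel]]:
    """Partition genes into (expressed, non-expressed) at ``expression >= threshold``.

    The default threshold of 15 normalized read counts is inclusive: a gene
    at exactly 15 counts is expressed.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    expressed = [g for g in genes if g.expression >= threshold]
    silent = [g for g in genes if g.expression < threshold]
    return expressed, silent


def relative_expression(
    ct_target: float, ct_ref: float, ct_target_cal: float, ct_ref_cal: float
) -> float:
    """qPCR fold change by the 2^-ddCt method.

    ``ct_*_cal`` are the calibrator-condition cycle thresholds; the
    reference gene (here typically SF3A1) normalizes input amounts.
    """
    for ct in (ct_target, ct_ref, ct_target_cal, ct_ref_cal):
        if ct <= 0:
            raise ValueError("Ct values must be positive")
    ddct = (ct_target - ct_ref) - (ct_target_cal - ct_ref_cal)
    return float(2.0 ** (-ddct))


def genes_from_frame(df: pd.DataFrame) -> List[GeneModel]:
    """Build gene models from a table with the gene-TSV columns."""
    return [
        GeneModel(str(r.gene_id), str(r.chrom), int(r.tss), str(r.strand), float(r.expression))
        for r in df.itertuples(index=False)
    ]
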