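"""LAD catalog: constitutive/variable/inter-LAD partition and active-region
annotation.

A LAD timecourse holds one lamina-associated-domain interval set per
differentiation timepoint (e.g. D0, D1, D3). Constitutive LADs (cLADs) are
the per-base intersection across all timepoints, variable LADs (vLADs) the
union minus that intersection, and inter-LADs (iLADs) everything else; the
three classes partition the genome exactly.

Within cLADs, euchromatic "active" regions are delimited by clustering
H3K4me1 peaks (peaks closer than a merge gap coalesce) and clipping the
clusters to cLAD bounds; the remaining cLAD bases form the non-K4
background against which lamin enrichment is contrasted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from .intervals import (
    GenomicInterval,
    IntervalSet,
    base_coverage,
    complement,
    intersect,
    union,
)
from .signal import CoverageTrack
from .stats import WelchTestResult, welch_test

__all__ = [
    "LADTimecourse",
    "LADPartition",
    "CladRegionAnnotation",
    "derive_lad_partition",
    "annotate_clad_regions",
    "region_mean_signal",
    "welch_test",
    "WelchTestResult",
]


@dataclass(frozen=True)
class LADTimecourse:
    timepoints: Sequence[str]
    lad_sets: Sequence[IntervalSet]

    def __post_init__(self) -> None:
        if len(self.timepoints) != len(self.lad_sets):
            raise ValueError("one LAD set per timepoint required")
        if len(self.timepoints) < 2:
            raise ValueError("a LAD timecourse needs >= 2 timepoints")
        g0 = self.lad_sets[0].genome
        for s in self.lad_sets[1:]:
            if s.genome != g0:
                raise ValueError("all timepoints must share one genome")


@dataclass(frozen=True)
class LADPartition:
    """Pairwise-disjoint cLAD / vLAD / iLAD sets covering the genome."""

    clads: IntervalSet
    vlads: IntervalSet
    ilads: IntervalSet

    def __post_init__(self) -> None:
        g = self.clads.genome
        total = base_coverage(self.clads) + base_coverage(self.vlads) + base_coverage(
            self.ilads
        )
        if total != sum(g.values()):
            raise ValueError("partition does not cover the genome exactly")


@dataclass(frozen=True)
class CladRegionAnnotation:
    """cLAD bases split into H3K4me1-owning regions and the remainder."""

    k4_regions: IntervalSet
    nonk4_regions: IntervalSet


def derive_lad_partition(tc: LADTimecourse) -> LADPartition:
    """Split the genome into cLADs (all timepoints), vLADs (some) and iLADs."""
    core = tc.lad_sets[0]
    any_lad = tc.lad_sets[0]
    for s in tc.lad_sets[1:]:
        core = intersect(core, s)
        any_lad = union(any_lad, s)
    vlads = intersect(any_lad, complement(core))
    ilads = complement(any_lad)
    return LADPartition(clads=core, vlads=vlads, ilads=ilads)


def partition_from_sets(
    clads: IntervalSet, vlads: IntervalSet
) -> LADPartition:
    """Build a partition from externally supplied cLAD and vLAD calls.

    Supports importing published cLAD/vLAD coordinates instead of deriving
    them from a timecourse; iLADs are the uncovered remainder. vLAD bases
    overlapping cLADs are trimmed so the partition invariant holds.
    """
    vlads = intersect(vlads, complement(clads))
    ilads = complement(union(clads, vlads))
    return LADPartition(clads=clads, vlads=vlads, ilads=ilads)


def annotate_clad_regions(
    clads: IntervalSet, k4_peaks: IntervalSet, merge_gap: int = 10_000
) -> CladRegionAnnotation:
    """Delimit H3K4me1 regions inside cLADs.

    Peaks closer than *merge_gap* bases are merged into one region; regions
    are then clipped to cLAD bounds. A cLAD region "owns" >= 1 peak iff it
    retains >= 1 bp of (extended) peak footprint after clipping.
    """
    if merge_gap < 0:
        raise ValueError("merge_gap must be >= 0")
    half = merge_gap // 2
    extended: List[GenomicInterval] = []
    genome = clads.genome
    for iv in k4_peaks:
        start = max(0, iv.start - half)
        end = min(genome[iv.chrom], iv.end + (merge_gap - half))
        extended.append(GenomicInterval(iv.chrom, start, end))
    clusters = IntervalSet(extended, genome)
    # clip the padding back so regions never extend beyond outermost peaks
    clipped: List[GenomicInterval] = []
    for iv in clusters:
        inner_start, inner_end = None, None
        for p in k4_peaks:
            if p.chrom == iv.chrom and p.start >= iv.start and p.end <= iv.end:
                inner_start = p.start if inner_start is None else min(inner_start, p.start)
                inner_end = p.end if inner_end is None else max(inner_end, p.end)
        if inner_start is not None:
            clipped.append(GenomicInterval(iv.chrom, inner_start, inner_end))
    k4_regions = intersect(IntervalSet(clipped, genome), clads)
    nonk4 = intersect(clads, complement(k4_regions))
    return CladRegionAnnotation(k4_regions=k4_regions, nonk4_regions=nonk4)


def region_mean_signal(
    track: CoverageTrack, regions: IntervalSet
) -> List[float]:
    """Length-weighted mean track value per region.

    Bins with missing data are excluded from the weighting; a region with
    no data at all yields NaN (flagged missing, never zero).
    """
    means: List[float] = []
    bs = track.bin_size
    for iv in regions:
        arr = track.values.get(iv.chrom)
        if arr is None:
            means.append(float("nan"))
            continue
        total = 0.0
        weight = 0
        first, last = iv.start // bs, (iv.end - 1) // bs
        for b in range(first, last + 1):
            v = arr[b]
            if not np.isfinite(v):
                continue
            lo, hi = max(iv.start, b * bs), min(iv.end, (b + 1) * bs)
            total += v * (hi - lo)
            weight += hi - lo
        means.append(total / weight if weight > 0 else float("nan"))
    return means


def region_contrast(
    track: CoverageTrack, annotation: CladRegionAnnotation
) -> Dict[str, object]:
    """Lamin enrichment contrast between K4 and non-K4 cLAD regions.

    Returns per-region means for both classes plus the Welch test on them.
    """
    k4_means = [m for m in region_mean_signal(track, annotation.k4_regions) if np.isfinite(m)]
    nonk4_means = [
        m for m in region_mean_signal(track, annotation.nonk4_regions) if np.isfinite(m)
    ]
    result = welch_test(k4_means, nonk4_means)
    return {"k4_means": k4_means, "nonk4_means": nonk4_means, "test": result}


def partition_to_frame(partition: LADPartition) -> pd.DataFrame:
    rows = []
    for label, iset in (
        ("cLAD", partition.clads),
        ("vLAD", partition.vlads),
        ("iLAD", partition.ilads),
    ):
        for iv in iset:
            rows.append((iv.chrom, iv.start, iv.end, label))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "lad_class"])
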