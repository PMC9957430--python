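"""Genomic interval model and overlap engine.

All coordinates are BED-convention 0-based half-open ``[start, end)``.
An overlap exists iff the shared length is at least 1 bp; book-ended
intervals (``[a,b)`` and ``[b,c)``) share zero bases and do not overlap,
but they do merge during normalization.

Strand is carried on :class:`GenomicInterval` but ignored by all overlap
operations: the analyses these primitives serve (LAD partitioning, bait
and target intersection) are strand-blind.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Tuple

import numpy as np

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "normalize",
    "intersect",
    "complement",
    "base_coverage",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic range.

    Parameters
    ----------
    chrom : str
        Sequence name; matched exactly (no ``chr`` aliasing).
    start, end : int
        Base offsets with ``0 <= start < end``.
    strand : str
        One of ``+``, ``-`` or ``.`` (unstranded). Carried but ignored by
        overlap tests.
    name : str, optional
        Free-form label (peak id, bait id, ...).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.chrom}:{self.start}-{self.end}")
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval: {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be '+', '-' or '.', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 bp (strand-blind)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class IntervalSet:
    """A collection of :class:`GenomicInterval` on a common genome.

    A set is *normalized* when, per chromosome, its intervals are sorted and
    non-overlapping (book-ended runs merged). All set algebra
    (:func:`intersect`, :func:`complement`, :func:`base_coverage`) requires
    normalized operands; constructors normalize eagerly unless told not to.

    Parameters
    ----------
    intervals : iterable of GenomicInterval
    genome : mapping chrom -> chromosome length in bases
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval],
        genome: Mapping[str, int],
        *,
        _presorted: bool = False,
    ) -> None:
        self.genome: Dict[str, int] = dict(genome)
        ivs = list(intervals)
        for iv in ivs:
            if iv.chrom not in self.genome:
                raise ValueError(
                    f"interval on unknown chromosome {iv.chrom!r} "
                    f"(genome has {sorted(self.genome)})"
                )
            if iv.end > self.genome[iv.chrom]:
                raise ValueError(
                    f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
                    f"length {self.genome[iv.chrom]}"
                )
        if _presorted:
            self._by_chrom = self._group(ivs)
        else:
            self._by_chrom = self._merge(self._group(ivs))

    @staticmethod
    def _group(ivs: List[GenomicInterval]) -> Dict[str, np.ndarray]:
        by: Dict[str, List[Tuple[int, int]]] = {}
        for iv in ivs:
            by.setdefault(iv.chrom, []).append((iv.start, iv.end))
        return {
            c: np.asarray(sorted(pairs), dtype=np.int64).reshape(-1, 2)
            for c, pairs in by.items()
        }

    @staticmethod
    def _merge(by: Dict[str, np.ndarray]) -> Dict[str, np.ndarray]:
        out: Dict[str, np.ndarray] = {}
        for c, arr in by.items():
            merged: List[List[int]] = []
            for s, e in arr:
                if merged and s <= merged[-1][1]:  # overlap or book-ended
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            out[c] = np.asarray(merged, dtype=np.int64).reshape(-1, 2)
        return out

    # -- container protocol -------------------------------------------------

    def __iter__(self) -> Iterator[GenomicInterval]:
        for c in sorted(self._by_chrom):
            for s, e in self._by_chrom[c]:
                yield GenomicInterval(c, int(s), int(e))

    def __len__(self) -> int:
        return sum(arr.shape[0] for arr in self._by_chrom.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        if self.genome != other.genome:
            return False
        keys = set(self._by_chrom) | set(other._by_chrom)
        for c in keys:
            a = self._by_chrom.get(c, np.empty((0, 2), dtype=np.int64))
            b = other._by_chrom.get(c, np.empty((0, 2), dtype=np.int64))
            if a.shape != b.shape or not np.array_equal(a, b):
                return False
        return True

    def __repr__(self) -> str:
        n = len(self)
        return f"IntervalSet({n} intervals, {base_coverage(self)} bp, {len(self.genome)} chroms)"

    def arrays(self, chrom: str) -> np.ndarray:
        """(n, 2) int64 array of [start, end) rows for one chromosome."""
        return self._by_chrom.get(chrom, np.empty((0, 2), dtype=np.int64))

    @property
    def chroms(self) -> List[str]:
        return sorted(self._by_chrom)

    def to_intervals(self) -> List[GenomicInterval]:
        return list(self)


def normalize(iset: IntervalSet) -> IntervalSet:
    """Return a sorted, merged copy of *iset* (book-ended runs coalesced)."""
    out = IntervalSet([], iset.genome, _presorted=True)
    out._by_chrom = IntervalSet._merge({c: a.copy() for c, a in iset._by_chrom.items()})
    return out


def intersect(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Bases present in both sets; overlap requires >= 1 shared bp."""
    if a.genome != b.genome:
        raise ValueError("genome mismatch between interval sets")
    out = IntervalSet([], a.genome, _presorted=True)
    result: Dict[str, np.ndarray] = {}
    for c in set(a._by_chrom) & set(b._by_chrom):
        xs, ys = a.arrays(c), b.arrays(c)
        pieces: List[Tuple[int, int]] = []
        i = j = 0
        while i < len(xs) and j < len(ys):
            s = max(xs[i, 0], ys[j, 0])
            e = min(xs[i, 1], ys[j, 1])
            if s < e:
                pieces.append((int(s), int(e)))
            if xs[i, 1] < ys[j, 1]:
                i += 1
            else:
                j += 1
        if pieces:
            result[c] = np.asarray(pieces, dtype=np.int64)
    out._by_chrom = result
    return out


def complement(iset: IntervalSet) -> IntervalSet:
    """Bases of the genome not covered by *iset*."""
    if not iset.genome:
        raise ValueError("complement requires a genome (chrom -> length) map")
    out = IntervalSet([], iset.genome, _presorted=True)
    result: Dict[str, np.ndarray] = {}
    for c, length in iset.genome.items():
        arr = iset.arrays(c)
        gaps: List[Tuple[int, int]] = []
        prev = 0
        for s, e in arr:
            if s > prev:
                gaps.append((prev, int(s)))
            prev = int(e)
        if prev < length:
            gaps.append((prev, length))
        if gaps:
            result[c] = np.asarray(gaps, dtype=np.int64)
    out._by_chrom = result
    return out


def base_coverage(iset: IntervalSet) -> int:
    """Total covered bases (sum of interval lengths on a normalized set)."""
    return int(
        sum((arr[:, 1] - arr[:, 0]).sum() for arr in iset._by_chrom.values())
    )


def union(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Bases present in either set."""
    if a.genome != b.genome:
        raise ValueError("genome mismatch between interval sets")
    out = IntervalSet([], a.genome, _presorted=True)
    combined: Dict[str, np.ndarray] = {}
    for c in set(a._by_chrom) | set(b._by_chrom):
        rows = np.vstack([a.arrays(c), b.arrays(c)])
        combined[c] = rows[np.lexsort((rows[:, 1], rows[:, 0]))]
    out._by_chrom = IntervalSet._merge(combined)
    return out


def validate_chrom_names(a: IntervalSet, b: IntervalSet) -> Dict[str, set]:
    """Report chromosome-name mismatches between two sets' genomes.

    No aliasing is attempted (``chr1`` != ``1``); callers are expected to fix
    inputs upstream.
    """
    ga, gb = set(a.genome), set(b.genome)
    return {"only_in_first": ga - gb, "only_in_second": gb - ga}
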