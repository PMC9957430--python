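"""Enhancer-capture Hi-C connectivity: bait classification, per-bait
connection density, and target annotation by LAD class and H3K4me1 status.

A *bait* is a captured enhancer fragment; a *connection* links a bait to a
*target* locus with an interaction p-value. Connections from all
differentiation timepoints are pooled, keeping only significant ones
(p <= 0.01, boundary inclusive). Baits falling in constitutive LADs are
split into "K4 baits" (>= 1 bp overlap with an H3K4me1 peak inside cLADs)
and "nonK4 baits" (no such overlap); K4 baits in real data show roughly
twice the connection density of nonK4 baits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, IntervalSet, intersect
from .lads import LADPartition
from .stats import WelchTestResult, welch_test

__all__ = [
    "Bait",
    "Connection",
    "BaitClassification",
    "TargetAnnotation",
    "ConnectivitySummary",
    "load_connections",
    "baits_in_clads",
    "classify_baits",
    "connection_density",
    "annotate_targets",
    "summarize_proportions",
]

CONNECTION_COLUMNS = [
    "bait_chrom",
    "bait_start",
    "bait_end",
    "target_chrom",
    "target_start",
    "target_end",
    "p_value",
    "timepoint",
]

LAD_CLASSES = ("cLAD", "vLAD", "iLAD")
K4_STATUSES = ("in_K4_peak", "outside_K4_peak")


@dataclass(frozen=True)
class Bait:
    interval: GenomicInterval
    bait_id: str


@dataclass(frozen=True)
class Connection:
    bait_id: str
    target: GenomicInterval
    p_value: float
    timepoint: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass
class BaitClassification:
    """K4 / nonK4 labels for the cLAD bait subset."""

    class_of: Dict[str, str]  # bait_id -> "K4" | "nonK4"
    clad_baits: List[Bait]

    @property
    def n_k4(self) -> int:
        return sum(1 for v in self.class_of.values() if v == "K4")

    @property
    def n_nonk4(self) -> int:
        return sum(1 for v in self.class_of.values() if v == "nonK4")


@dataclass
class TargetAnnotation:
    """Per-connection LAD class and H3K4me1 status of the target."""

    lad_class: List[str]
    k4_status: List[str]
    connections: List[Connection]


@dataclass
class ConnectivitySummary:
    targets_per_bait: Dict[str, int]
    class_means: Dict[str, float]
    class_medians: Dict[str, float] = field(default_factory=dict)
    unique_target_means: Dict[str, float] = field(default_factory=dict)
    class_totals: Dict[str, int] = field(default_factory=dict)
    welch: Optional[WelchTestResult] = None
    category_proportions: Optional[pd.DataFrame] = None


def load_connections(
    records: Iterable[Mapping[str, object]] | pd.DataFrame,
    p_threshold: float = 0.01,
) -> Tuple[List[Bait], List[Connection]]:
    """Pool connection records across timepoints, keeping p <= threshold.

    Baits are deduplicated on exact coordinates (the same fragment captured
    at several timepoints is one bait); connection multiplicity across
    timepoints is retained. Malformed rows are rejected with their line
    number.
    """
    if isinstance(records, pd.DataFrame):
        records = records.to_dict("records")
    baits: Dict[Tuple[str, int, int], Bait] = {}
    connections: List[Connection] = []
    for lineno, rec in enumerate(records, 1):
        try:
            bc = str(rec["bait_chrom"])
            bs, be = int(rec["bait_start"]), int(rec["bait_end"])
            tc = str(rec["target_chrom"])
            ts, te = int(rec["target_start"]), int(rec["target_end"])
            p = float(rec["p_value"])
            tp = str(rec.get("timepoint", "pooled"))
            bait_iv = GenomicInterval(bc, bs, be)
            target_iv = GenomicInterval(tc, ts, te)
        except (KeyError, ValueError, TypeError) as exc:
            raise ValueError(f"connection record {lineno}: {exc}") from exc
        if p > p_threshold:
            continue
        key = (bc, bs, be)
        if key not in baits:
            baits[key] = Bait(bait_iv, bait_id=f"bait_{bc}_{bs}_{be}")
        connections.append(Connection(baits[key].bait_id, target_iv, p, tp))
    return list(baits.values()), connections


def read_connections_tsv(
    path, p_threshold: float = 0.01
) -> Tuple[List[Bait], List[Connection]]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CONNECTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: connections table missing columns {missing}")
    return load_connections(df, p_threshold=p_threshold)


def _overlaps_set(iv: GenomicInterval, iset: IntervalSet) -> bool:
    arr = iset.arrays(iv.chrom)
    if arr.size == 0:
        return False
    # sorted non-overlapping rows: the candidate with the largest end among
    # those starting before iv.end is the last one
    i = int(np.searchsorted(arr[:, 0], iv.end, side="left"))
    return i > 0 and int(arr[i - 1, 1]) > iv.start


def _overlap_bases(iv: GenomicInterval, iset: IntervalSet) -> int:
    arr = iset.arrays(iv.chrom)
    if arr.size == 0:
        return 0
    lo = np.maximum(arr[:, 0], iv.start)
    hi = np.minimum(arr[:, 1], iv.end)
    return int(np.clip(hi - lo, 0, None).sum())


def baits_in_clads(baits: Sequence[Bait], partition: LADPartition) -> List[Bait]:
    """Baits overlapping constitutive LADs by >= 1 bp."""
    return [b for b in baits if _overlaps_set(b.interval, partition.clads)]


def classify_baits(
    clad_baits: Sequence[Bait], k4_peaks_in_clads: IntervalSet
) -> BaitClassification:
    """K4 iff >= 1 bp overlap with an H3K4me1 peak footprint inside cLADs."""
    class_of = {
        b.bait_id: ("K4" if _overlaps_set(b.interval, k4_peaks_in_clads) else "nonK4")
        for b in clad_baits
    }
    return BaitClassification(class_of=class_of, clad_baits=list(clad_baits))


def connection_density(
    connections: Sequence[Connection], classification: BaitClassification
) -> ConnectivitySummary:
    """Per-bait connection counts and K4 vs nonK4 density comparison.

    Baits with zero connections count as zero (they are not dropped). Means
    are reported both over connections (with timepoint multiplicity) and
    over unique target coordinates per bait, since the two differ whenever
    the same bait-target pair recurs across timepoints.
    """
    counts: Dict[str, int] = {b.bait_id: 0 for b in classification.clad_baits}
    uniq: Dict[str, set] = {b.bait_id: set() for b in classification.clad_baits}
    for c in connections:
        if c.bait_id in counts:
            counts[c.bait_id] += 1
            uniq[c.bait_id].add((c.target.chrom, c.target.start, c.target.end))
    per_class: Dict[str, List[int]] = {"K4": [], "nonK4": []}
    per_class_uniq: Dict[str, List[int]] = {"K4": [], "nonK4": []}
    for b in classification.clad_baits:
        cls = classification.class_of[b.bait_id]
        per_class[cls].append(counts[b.bait_id])
        per_class_uniq[cls].append(len(uniq[b.bait_id]))
    means = {k: float(np.mean(v)) if v else float("nan") for k, v in per_class.items()}
    medians = {
        k: float(np.median(v)) if v else float("nan") for k, v in per_class.items()
    }
    uniq_means = {
        k: float(np.mean(v)) if v else float("nan") for k, v in per_class_uniq.items()
    }
    totals = {k: int(np.sum(v)) for k, v in per_class.items()}
    welch = None
    if len(per_class["K4"]) >= 2 and len(per_class["nonK4"]) >= 2:
        try:
            welch = welch_test(per_class["K4"], per_class["nonK4"])
        except ValueError:
            welch = None
    return ConnectivitySummary(
        targets_per_bait=counts,
        class_means=means,
        class_medians=medians,
        unique_target_means=uniq_means,
        class_totals=totals,
        welch=welch,
    )


def annotate_targets(
    connections: Sequence[Connection],
    partition: LADPartition,
    k4_peaks: IntervalSet,
    strategy: str = "largest_overlap",
) -> TargetAnnotation:
    """Assign each connection target one LAD class and one K4 status.

    ``largest_overlap`` assigns the class covering most target bases, ties
    broken cLAD > vLAD > iLAD; ``any_overlap_priority`` assigns the first
    class in that precedence order with >= 1 bp overlap. K4 status is
    >= 1 bp overlap with any H3K4me1 peak.
    """
    if strategy not in ("largest_overlap", "any_overlap_priority"):
        raise ValueError(f"unknown strategy {strategy!r}")
    sets = {
        "cLAD": partition.clads,
        "vLAD": partition.vlads,
        "iLAD": partition.ilads,
    }
    lad_class: List[str] = []
    k4_status: List[str] = []
    for c in connections:
        if strategy == "largest_overlap":
            best, best_bases = "iLAD", -1
            for cls in LAD_CLASSES:  # precedence order resolves ties
                bases = _overlap_bases(c.target, sets[cls])
                if bases > best_bases:
                    best, best_bases = cls, bases
            lad_class.append(best)
        else:
            chosen = "iLAD"
            for cls in LAD_CLASSES:
                if _overlaps_set(c.target, sets[cls]):
                    chosen = cls
                    break
            lad_class.append(chosen)
        k4_status.append(
            "in_K4_peak" if _overlaps_set(c.target, k4_peaks) else "outside_K4_peak"
        )
    return TargetAnnotation(
        lad_class=lad_class, k4_status=k4_status, connections=list(connections)
    )


def summarize_proportions(
    annotation: TargetAnnotation, classification: BaitClassification
) -> pd.DataFrame:
    """Per bait class, the fraction of targets in each (LAD class, K4 status)
    cell; fractions within a bait class sum to 1."""
    rows = []
    for cls in ("K4", "nonK4"):
        idx = [
            i
            for i, c in enumerate(annotation.connections)
            if classification.class_of.get(c.bait_id) == cls
        ]
        n = len(idx)
        for lad in LAD_CLASSES:
            for k4 in K4_STATUSES:
                count = sum(
                    1
                    for i in idx
                    if annotation.lad_class[i] == lad and annotation.k4_status[i] == k4
                )
                rows.append(
                    {
                        "bait_class": cls,
                        "lad_class": lad,
                        "k4_status": k4,
                        "count": count,
                        "fraction": count / n if n else float("nan"),
                        "empty_class": n == 0,
                    }
                )
    df = pd.DataFrame(rows)
    for cls in ("K4", "nonK4"):
        sub = df[df.bait_class == cls]
        if not sub.empty_class.all():
            assert abs(sub.fraction.sum() - 1.0) < 1e-9
    return df


def annotation_to_frame(annotation: TargetAnnotation) -> pd.DataFrame:
    rows = []
    for c, lad, k4 in zip(
        annotation.connections, annotation.lad_class, annotation.k4_status
    ):
        rows.append(
            {
                "bait_id": c.bait_id,
                "target_chrom": c.target.chrom,
                "target_start": c.target.start,
                "target_end": c.target.end,
                "p_value": c.p_value,
                "timepoint": c.timepoint,
                "lad_class": lad,
                "k4_status": k4,
            }
        )
    return pd.DataFrame(rows)
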