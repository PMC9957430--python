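"""FISH distance analysis: probe pairing, 3D distances, distance to the
nuclear periphery, and between-condition comparisons.

Input is a table of dual-color probe signals per nucleus (two red/gene and
two green/enhancer spots per analyzable nucleus, i.e. two alleles), with
positions in micrometres. The nuclear boundary is modeled as an ellipsoid
fit from DAPI; pre-measured distance tables can also be consumed directly,
bypassing geometry entirely.

Peripheral localization uses the <= 2 um rule: a probe is "at the nuclear
periphery" iff its distance to the boundary is at most 2 um (inclusive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .stats import WelchTestResult, welch_test

__all__ = [
    "ProbeSignal",
    "NucleusGeometry",
    "DistanceRecord",
    "pair_alleles",
    "probe_distance",
    "periphery_distance",
    "peripheral_fraction",
    "compare_conditions",
    "measure_nuclei",
]

log = logging.getLogger(__name__)

CHANNELS = ("red", "green")  # red = gene probe, green = enhancer probe


@dataclass(frozen=True)
class ProbeSignal:
    nucleus_id: str
    channel: str  # "red" (gene) or "green" (enhancer)
    position: Tuple[float, float, float]  # um

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}")


@dataclass(frozen=True)
class NucleusGeometry:
    """Ellipsoidal nuclear boundary: center plus semi-axes, in um."""

    nucleus_id: str
    center: Tuple[float, float, float]
    semi_axes: Tuple[float, float, float]

    def __post_init__(self) -> None:
        if min(self.semi_axes) <= 0:
            raise ValueError("semi-axes must be positive")


@dataclass(frozen=True)
class DistanceRecord:
    nucleus_id: str
    allele: int
    probe_probe_um: float
    periphery_red_um: float
    periphery_green_um: float
    condition: str


def probe_distance(
    a: Sequence[float] | ProbeSignal, b: Sequence[float] | ProbeSignal
) -> float:
    """Euclidean 3D distance between two probe positions, in um."""
    pa = np.asarray(a.position if isinstance(a, ProbeSignal) else a, dtype=float)
    pb = np.asarray(b.position if isinstance(b, ProbeSignal) else b, dtype=float)
    return float(np.linalg.norm(pa - pb))


def pair_alleles(
    signals: Sequence[ProbeSignal],
) -> List[Tuple[ProbeSignal, ProbeSignal]]:
    """Match the two red to the two green signals of one nucleus.

    Uses the minimum-total-distance one-to-one matching (only two pairings
    exist for 2x2); exact ties keep input order. Nuclei without exactly two
    signals per channel are rejected.
    """
    reds = [s for s in signals if s.channel == "red"]
    greens = [s for s in signals if s.channel == "green"]
    if len(reds) != 2 or len(greens) != 2:
        raise ValueError(
            f"nucleus needs exactly 2 signals per channel, got "
            f"{len(reds)} red / {len(greens)} green"
        )
    straight = probe_distance(reds[0], greens[0]) + probe_distance(reds[1], greens[1])
    crossed = probe_distance(reds[0], greens[1]) + probe_distance(reds[1], greens[0])
    if crossed < straight:
        return [(reds[0], greens[1]), (reds[1], greens[0])]
    return [(reds[0], greens[0]), (reds[1], greens[1])]


def periphery_distance(
    probe: Sequence[float] | ProbeSignal, geom: NucleusGeometry, tol: float = 1e-6
) -> float:
    """Distance from a probe to the ellipsoid surface, in um.

    For a sphere this is radius - |p - center|. The general case solves the
    Lagrange condition x_i = a_i^2 p_i / (a_i^2 + t), sum (x_i/a_i)^2 = 1
    for the interior root by bracketed root-finding; exactly-zero probe
    components are perturbed by an infinitesimal so symmetric degenerate
    cases converge to the correct off-axis foot point. A probe outside the
    boundary yields 0 with a warning.
    """
    p = np.asarray(
        probe.position if isinstance(probe, ProbeSignal) else probe, dtype=float
    ) - np.asarray(geom.center, dtype=float)
    a = np.asarray(geom.semi_axes, dtype=float)
    if float(np.sum((p / a) ** 2)) > 1.0 + 1e-12:
        log.warning("probe outside nucleus %s; periphery distance set to 0", geom.nucleus_id)
        return 0.0
    if np.allclose(a, a[0]):
        return float(a[0] - np.linalg.norm(p))
    if np.allclose(p, 0.0):
        return float(a.min())
    # break exact-zero degeneracies; the limit is the true foot point
    q = np.where(p == 0.0, 1e-9 * a, np.abs(p))

    def f(t: float) -> float:
        return float(np.sum((a * a * q * q) / (a * a + t) ** 2) - 1.0)

    lo = -float((a.min()) ** 2)
    lo_eps = lo + 1e-14 * max(1.0, abs(lo))
    while f(lo_eps) < 0:  # widen toward the pole if still negative
        lo_eps = lo + (lo_eps - lo) * 0.1
        if lo_eps - lo < 1e-300:
            return float(a.min() - np.linalg.norm(p))
    hi = 0.0
    if f(hi) > 0:  # numerically on the surface
        return 0.0
    t_star = brentq(f, lo_eps, hi, xtol=1e-13, rtol=8.9e-16, maxiter=200)
    foot = (a * a * q) / (a * a + t_star)
    d = float(np.linalg.norm(foot - q))
    return max(d, 0.0) if d > tol else d


def peripheral_fraction(
    periphery_um: Sequence[float], cutoff: float = 2.0
) -> float:
    """Fraction of probes within *cutoff* um of the boundary (inclusive)."""
    vals = np.asarray(list(periphery_um), dtype=float)
    if vals.size == 0:
        raise ValueError("no periphery distances supplied")
    return float(np.mean(vals <= cutoff))


def compare_conditions(
    records_a: Sequence[DistanceRecord],
    records_b: Sequence[DistanceRecord],
    quantity: str = "probe_probe_um",
    channel: str = "green",
) -> WelchTestResult:
    """Unpaired two-tailed Welch t-test between two conditions.

    *quantity* selects probe-probe distance or periphery distance; for
    periphery distance, *channel* picks which probe's distance enters the
    test (both channels are stored on every record).
    """
    def extract(records: Sequence[DistanceRecord]) -> List[float]:
        if quantity == "probe_probe_um":
            return [r.probe_probe_um for r in records]
        if quantity == "periphery_um":
            attr = "periphery_green_um" if channel == "green" else "periphery_red_um"
            return [getattr(r, attr) for r in records]
        raise ValueError(f"unknown quantity {quantity!r}")

    return welch_test(extract(records_a), extract(records_b))


# ---------------------------------------------------------------------------
# table-level drivers


def measure_nuclei(
    signals: pd.DataFrame,
    geometries: Optional[Mapping[str, NucleusGeometry]] = None,
) -> List[DistanceRecord]:
    """Turn a signal table into per-allele distance records.

    Expects columns nucleus_id, condition, channel, x, y, z and, unless
    *geometries* is given, the ellipsoid columns cx, cy, cz, ax, ay, az.
    Nuclei with the wrong signal multiplicity are excluded with a log entry.
    """
    records: List[DistanceRecord] = []
    for (nucleus_id, condition), grp in signals.groupby(
        ["nucleus_id", "condition"], sort=True
    ):
        sigs = [
            ProbeSignal(str(nucleus_id), str(r.channel), (float(r.x), float(r.y), float(r.z)))
            for r in grp.itertuples(index=False)
        ]
        try:
            pairs = pair_alleles(sigs)
        except ValueError as exc:
            log.warning("nucleus %s excluded: %s", nucleus_id, exc)
            continue
        if geometries is not None:
            geom = geometries[str(nucleus_id)]
        else:
            r0 = grp.iloc[0]
            geom = NucleusGeometry(
                str(nucleus_id),
                (float(r0.cx), float(r0.cy), float(r0.cz)),
                (float(r0.ax), float(r0.ay), float(r0.az)),
            )
        for allele, (red, green) in enumerate(pairs):
            records.append(
                DistanceRecord(
                    nucleus_id=str(nucleus_id),
                    allele=allele,
                    probe_probe_um=probe_distance(red, green),
                    periphery_red_um=periphery_distance(red, geom),
                    periphery_green_um=periphery_distance(green, geom),
                    condition=str(condition),
                )
            )
    return records


def records_to_frame(records: Sequence[DistanceRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "nucleus_id": r.nucleus_id,
                "allele": r.allele,
                "condition": r.condition,
                "probe_probe_um": r.probe_probe_um,
                "periphery_red_um": r.periphery_red_um,
                "periphery_green_um": r.periphery_green_um,
            }
            for r in records
        ]
    )
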