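"""Bait classification, connection density, and target annotation."""

import collections

import numpy as np
import pandas as pd
import pytest

import ladscape as L
from ladscape.connectivity import (
    Bait,
    Connection,
    annotate_targets,
    baits_in_clads,
    classify_baits,
    connection_density,
    load_connections,
    summarize_proportions,
)
from ladscape.lads import partition_from_sets

G = {"chrT": 100_000}


def iset(pairs, genome=G):
    return L.IntervalSet([L.GenomicInterval("chrT", s, e) for s, e in pairs], genome)


def make_partition(clad_pairs, vlad_pairs=(), genome=G):
    return partition_from_sets(iset(clad_pairs, genome), iset(list(vlad_pairs), genome))


def record(bs, be, ts, te, p, tp="D0", chrom="chrT"):
    return {
        "bait_chrom": chrom,
        "bait_start": bs,
        "bait_end": be,
        "target_chrom": chrom,
        "target_start": ts,
        "target_end": te,
        "p_value": p,
        "timepoint": tp,
    }


class TestLoadConnections:
    def test_p_threshold_boundary_inclusive(self):
        recs = [record(0, 100, 200, 300, p) for p in (0.005, 0.01, 0.02)]
        baits, conns = load_connections(recs)
        assert len(conns) == 2  # p = 0.01 retained, 0.02 dropped

    def test_bait_deduplicated_across_timepoints(self):
        recs = [
            record(0, 100, 200, 300, 0.001, "D0"),
            record(0, 100, 400, 500, 0.001, "D3"),
        ]
        baits, conns = load_connections(recs)
        assert len(baits) == 1
        assert len(conns) == 2

    def test_malformed_row_rejected_with_line_number(self):
        recs = [record(0, 100, 200, 300, 0.001), record(50, 10, 200, 300, 0.001)]
        with pytest.raises(ValueError, match="record 2"):
            load_connections(recs)


class TestBaitsInClads:
    def test_one_bp_overlap_retained_abutting_excluded(self):
        part = make_partition([(1000, 2000)])
        inside = Bait(L.GenomicInterval("chrT", 1500, 1600), "in")
        touching = Bait(L.GenomicInterval("chrT", 1999, 2100), "touch")  # 1 bp in
        abutting = Bait(L.GenomicInterval("chrT", 2000, 2100), "out")  # 0 bp shared
        kept = baits_in_clads([inside, touching, abutting], part)
        assert [b.bait_id for b in kept] == ["in", "touch"]


class TestClassifyBaits:
    def test_single_bp_peak_overlap_is_k4(self):
        peaks = iset([(100, 200)])
        bait = Bait(L.GenomicInterval("chrT", 199, 300), "b1")  # exactly 1 bp
        cls = classify_baits([bait], peaks)
        assert cls.class_of["b1"] == "K4"

    def test_no_peaks_all_nonk4(self):
        baits = [Bait(L.GenomicInterval("chrT", i * 1000, i * 1000 + 100), f"b{i}") for i in range(3)]
        cls = classify_baits(baits, L.IntervalSet([], G))
        assert set(cls.class_of.values()) == {"nonK4"}

    def test_partition_invariant_on_synthetic_census(self, dataset, partition, loaded_connections):
        baits, _ = loaded_connections
        clad_baits = baits_in_clads(baits, partition)
        cls = classify_baits(clad_baits, L.intersect(dataset.k4_peaks, partition.clads))
        assert cls.n_k4 + cls.n_nonk4 == len(clad_baits)
        # generator study conditions: the real study's cLAD bait census
        assert len(clad_baits) == 768
        assert cls.n_k4 == 225
        assert cls.n_nonk4 == 543


class TestConnectionDensity:
    def _classification(self, counts_by_bait):
        baits = [
            Bait(L.GenomicInterval("chrT", i * 1000, i * 1000 + 100), bid)
            for i, bid in enumerate(counts_by_bait)
        ]
        class_of = {bid: cls for bid, (cls, _) in counts_by_bait.items()}
        conns = []
        for i, (bid, (_, n)) in enumerate(counts_by_bait.items()):
            for j in range(n):
                conns.append(
                    Connection(bid, L.GenomicInterval("chrT", 50_000 + j * 10, 50_005 + j * 10), 0.001, "D0")
                )
        from ladscape.connectivity import BaitClassification

        return BaitClassification(class_of=class_of, clad_baits=baits), conns

    def test_class_mean(self):
        cls, conns = self._classification({"a": ("K4", 3), "b": ("K4", 1)})
        summary = connection_density(conns, cls)
        assert summary.class_means["K4"] == 2.0

    def test_zero_connection_bait_counted(self):
        cls, conns = self._classification({"a": ("K4", 4), "b": ("K4", 0)})
        summary = connection_density(conns, cls)
        assert summary.targets_per_bait["b"] == 0
        assert summary.class_means["K4"] == 2.0

    def test_equal_counts_give_t_zero(self):
        cls, conns = self._classification(
            {"a": ("K4", 2), "b": ("K4", 4), "c": ("nonK4", 2), "d": ("nonK4", 4)}
        )
        summary = connection_density(conns, cls)
        assert summary.welch.t_statistic == pytest.approx(0.0)

    def test_totals_equal_connection_counts(self, dataset, partition, loaded_connections):
        baits, conns = loaded_connections
        clad_baits = baits_in_clads(baits, partition)
        cls = classify_baits(clad_baits, L.intersect(dataset.k4_peaks, partition.clads))
        summary = connection_density(conns, cls)
        clad_ids = set(cls.class_of)
        n_clad_conns = sum(1 for c in conns if c.bait_id in clad_ids)
        assert sum(summary.targets_per_bait.values()) == n_clad_conns
        assert summary.class_totals["K4"] + summary.class_totals["nonK4"] == n_clad_conns

    def test_density_ordering_recovered_with_power(self, dataset, partition, loaded_connections):
        """λ_K4 > λ_nonK4 in the generator must surface as a higher K4 mean
        with Welch p < 1e-4 at the study's bait census."""
        baits, conns = loaded_connections
        clad_baits = baits_in_clads(baits, partition)
        cls = classify_baits(clad_baits, L.intersect(dataset.k4_peaks, partition.clads))
        summary = connection_density(conns, cls)
        assert summary.class_means["K4"] > summary.class_means["nonK4"]
        assert summary.welch.p_value < 1e-4


class TestAnnotateTargets:
    def test_wholly_interior_target(self):
        part = make_partition([(10_000, 20_000)])
        conns = [Connection("b", L.GenomicInterval("chrT", 50_000, 50_100), 0.001, "D0")]
        ann = annotate_targets(conns, part, L.IntervalSet([], G))
        assert ann.lad_class == ["iLAD"]
        assert ann.k4_status == ["outside_K4_peak"]

    def test_majority_rule_for_straddling_target(self):
        part = make_partition([(10_000, 20_000)])
        # 60 of 100 bases in the cLAD
        conns = [Connection("b", L.GenomicInterval("chrT", 19_940, 20_040), 0.001, "D0")]
        ann = annotate_targets(conns, part, L.IntervalSet([], G))
        assert ann.lad_class == ["cLAD"]

    def test_any_overlap_priority_strategy(self):
        part = make_partition([(10_000, 20_000)])
        # only 10 of 100 bases in the cLAD: majority iLAD, priority cLAD
        conns = [Connection("b", L.GenomicInterval("chrT", 19_990, 20_090), 0.001, "D0")]
        majority = annotate_targets(conns, part, L.IntervalSet([], G))
        priority = annotate_targets(
            conns, part, L.IntervalSet([], G), strategy="any_overlap_priority"
        )
        assert majority.lad_class == ["iLAD"]
        assert priority.lad_class == ["cLAD"]

    def test_placement_fractions_recovered(self, dataset, partition, loaded_connections):
        """Targets were placed 0.7/0.2/0.1 over cLAD/vLAD/iLAD; recovered
        proportions must lie within 3 binomial SDs."""
        _, conns = loaded_connections
        ann = annotate_targets(conns, partition, dataset.k4_peaks)
        n = len(conns)
        found = collections.Counter(ann.lad_class)
        for cls, f in zip(("cLAD", "vLAD", "iLAD"), dataset.truth.config.placement_fractions):
            sd = np.sqrt(f * (1 - f) / n)
            assert abs(found[cls] / n - f) < 3 * sd


class TestSummarizeProportions:
    def test_single_cell_gets_all_mass(self):
        part = make_partition([(10_000, 20_000)])
        bait = Bait(L.GenomicInterval("chrT", 12_000, 12_100), "b")
        from ladscape.connectivity import BaitClassification

        cls = BaitClassification({"b": "K4"}, [bait])
        conns = [
            Connection("b", L.GenomicInterval("chrT", 15_000, 15_100), 0.001, "D0")
            for _ in range(5)
        ]
        ann = annotate_targets(conns, part, L.IntervalSet([], G))
        props = summarize_proportions(ann, cls)
        cell = props[
            (props.bait_class == "K4")
            & (props.lad_class == "cLAD")
            & (props.k4_status == "outside_K4_peak")
        ]
        assert cell.fraction.iloc[0] == 1.0
        assert props[props.bait_class == "K4"].fraction.sum() == pytest.approx(1.0)

    def test_empty_class_flagged(self):
        part = make_partition([(10_000, 20_000)])
        from ladscape.connectivity import BaitClassification

        bait = Bait(L.GenomicInterval("chrT", 12_000, 12_100), "b")
        cls = BaitClassification({"b": "K4"}, [bait])
        ann = annotate_targets([], part, L.IntervalSet([], G))
        props = summarize_proportions(ann, cls)
        assert props[props.bait_class == "nonK4"].empty_class.all()

    def test_fractions_sum_to_one_per_class(self, dataset, partition, loaded_connections):
        baits, conns = loaded_connections
        clad_baits = baits_in_clads(baits, partition)
        cls = classify_baits(clad_baits, L.intersect(dataset.k4_peaks, partition.clads))
        ann = annotate_targets(conns, partition, dataset.k4_peaks)
        props = summarize_proportions(ann, cls)
        for bait_class in ("K4", "nonK4"):
            assert props[props.bait_class == bait_class].fraction.sum() == pytest.approx(
                1.0, abs=1e-9
            )
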