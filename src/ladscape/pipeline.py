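"""Stage orchestration with provenance records.

Each stage reads its inputs from the run directory (or the paths named in
the config), writes fixed-name outputs there, and drops a provenance JSON
carrying input checksums, the effective config, the package version and
the seed. Deterministic stages are byte-identical across re-runs with
identical inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, List, Mapping, Optional

import numpy as np
import pandas as pd

from . import __version__
from . import io as lio
from .chromstates import attribute_targets, baum_welch, binarize, decode, fold_enrichment
from .connectivity import (
    annotate_targets,
    annotation_to_frame,
    baits_in_clads,
    classify_baits,
    connection_density,
    read_connections_tsv,
    summarize_proportions,
)
from .fish import compare_conditions, measure_nuclei, peripheral_fraction, records_to_frame
from .intervals import GenomicInterval, IntervalSet, intersect
from .lads import (
    LADTimecourse,
    annotate_clad_regions,
    derive_lad_partition,
    partition_from_sets,
    region_contrast,
)
from .signal import CoverageTrack, filter_expressed, genes_from_frame, tss_metaprofile
from .synth import SyntheticConfig, generate

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Bad or missing configuration (CLI exit code 2)."""


class DataError(ValueError):
    """Missing or malformed input data (CLI exit code 3)."""


@dataclass
class PipelineConfig:
    """Paths and thresholds for a pipeline run.

    Thresholds default to the study's printed values: connection
    significance p <= 0.01, expressed-gene count >= 15, peripheral cutoff
    2 um, and H3K4me1-region merge gap 10 kb.
    """

    outdir: str = "run"
    seed: int = 0
    p_threshold: float = 0.01
    expression_threshold: float = 15.0
    peripheral_cutoff_um: float = 2.0
    merge_gap: int = 10_000
    n_states: int = 3
    hmm_bin_size: int = 200
    hmm_max_iter: int = 100
    tss_flank: int = 4000
    tss_bin: int = 50
    timepoints: List[str] = field(default_factory=lambda: ["D0", "D1", "D3"])
    target_strategy: str = "largest_overlap"
    synthetic: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("p_threshold", "expression_threshold", "peripheral_cutoff_um"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.merge_gap < 0 or self.n_states < 2:
            raise ConfigError("merge_gap must be >= 0 and n_states >= 2")

    @classmethod
    def from_dict(cls, d: Mapping[str, object]) -> "PipelineConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**dict(d))
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    @property
    def rundir(self) -> Path:
        return Path(self.outdir)

    @property
    def inputs_dir(self) -> Path:
        return self.rundir / "inputs"


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _provenance(config: PipelineConfig, stage: str, inputs: List[Path]) -> None:
    rec = {
        "stage": stage,
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "inputs": {str(p): _checksum(p) for p in inputs if p.exists()},
    }
    out = config.rundir / f"provenance_{stage}.json"
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(json.dumps(rec, indent=1, sort_keys=True))


def _require(path: Path, produced_by: str) -> Path:
    if not path.exists():
        raise DataError(
            f"missing input {path}; run the `{produced_by}` subcommand first"
        )
    return path


# ---------------------------------------------------------------------------
# stages


def stage_generate(config: PipelineConfig) -> Dict[str, object]:
    ds = generate(config.synthetic or None, seed=config.seed, outdir=config.inputs_dir)
    _provenance(config, "generate", sorted(config.inputs_dir.glob("*")))
    return {"outdir": str(config.inputs_dir), "n_connections": len(ds.connections)}


def _load_partition(config: PipelineConfig):
    rundir = config.rundir
    genome = lio.read_genome(_require(rundir / "inputs" / "genome.tsv", "generate"))
    beds = {
        label: lio.read_bed(rundir / f"partition_{label}.bed", genome)
        for label in ("clad", "vlad", "ilad")
        if (rundir / f"partition_{label}.bed").exists()
    }
    if len(beds) != 3:
        raise DataError("partition BEDs missing; run the `partition` subcommand first")
    return partition_from_sets(beds["clad"], beds["vlad"]), genome


def stage_partition(config: PipelineConfig) -> Dict[str, object]:
    indir = config.inputs_dir
    genome = lio.read_genome(_require(indir / "genome.tsv", "generate"))
    lad_sets = []
    inputs = [indir / "genome.tsv"]
    for tp in config.timepoints:
        path = _require(indir / f"lads_{tp}.bed", "generate")
        inputs.append(path)
        lad_sets.append(lio.read_bed(path, genome))
    partition = derive_lad_partition(LADTimecourse(config.timepoints, lad_sets))
    lio.write_bed(partition.clads, config.rundir / "partition_clad.bed")
    lio.write_bed(partition.vlads, config.rundir / "partition_vlad.bed")
    lio.write_bed(partition.ilads, config.rundir / "partition_ilad.bed")
    _provenance(config, "partition", inputs)
    from .intervals import base_coverage

    return {
        "clad_bp": base_coverage(partition.clads),
        "vlad_bp": base_coverage(partition.vlads),
        "ilad_bp": base_coverage(partition.ilads),
    }


def stage_profiles(config: PipelineConfig) -> Dict[str, object]:
    indir = config.inputs_dir
    partition, genome = _load_partition(config)
    k4_peaks = lio.read_bed(_require(indir / "h3k4me1_peaks.bed", "generate"), genome)
    lamin_df = lio.read_bedgraph(_require(indir / "lamin_log2ratio.bedgraph", "generate"))
    bin_size = int((lamin_df.end - lamin_df.start).mode().iloc[0])
    lamin = CoverageTrack.from_bedgraph(lamin_df, genome, bin_size)
    annotation = annotate_clad_regions(partition.clads, k4_peaks, config.merge_gap)
    contrast = region_contrast(lamin, annotation)

    genes = genes_from_frame(lio.read_gene_table(_require(indir / "genes.tsv", "generate")))
    expressed, silent = filter_expressed(genes, config.expression_threshold)
    tss_df = lio.read_bedgraph(_require(indir / "tss_signal.bedgraph", "generate"))
    tss_bin = int((tss_df.end - tss_df.start).mode().iloc[0])
    tss_track = CoverageTrack.from_bedgraph(tss_df, genome, tss_bin)
    prof_expr = tss_metaprofile(tss_track, expressed, config.tss_flank, config.tss_bin)
    prof_expr.to_frame().to_csv(config.rundir / "tss_profile_expressed.tsv", sep="\t", index=False)
    if silent:
        prof_sil = tss_metaprofile(tss_track, silent, config.tss_flank, config.tss_bin)
        prof_sil.to_frame().to_csv(
            config.rundir / "tss_profile_nonexpressed.tsv", sep="\t", index=False
        )
    test = contrast["test"]
    means_df = pd.DataFrame(
        {
            "region_class": ["K4"] * len(contrast["k4_means"])
            + ["nonK4"] * len(contrast["nonk4_means"]),
            "mean_log2ratio": contrast["k4_means"] + contrast["nonk4_means"],
        }
    )
    means_df.to_csv(config.rundir / "clad_region_means.tsv", sep="\t", index=False)
    result = {
        "n_expressed": len(expressed),
        "n_non_expressed": len(silent),
        "k4_region_mean": float(np.mean(contrast["k4_means"])),
        "nonk4_region_mean": float(np.mean(contrast["nonk4_means"])),
        "welch_t": test.t_statistic,
        "welch_p": test.p_value,
    }
    (config.rundir / "profiles_summary.json").write_text(json.dumps(result, indent=1))
    _provenance(
        config,
        "profiles",
        [indir / "lamin_log2ratio.bedgraph", indir / "genes.tsv", indir / "tss_signal.bedgraph"],
    )
    return result


def stage_connectivity(config: PipelineConfig) -> Dict[str, object]:
    indir = config.inputs_dir
    partition, genome = _load_partition(config)
    k4_peaks = lio.read_bed(_require(indir / "h3k4me1_peaks.bed", "generate"), genome)
    conn_path = _require(indir / "connections.tsv", "generate")
    baits, connections = read_connections_tsv(conn_path, config.p_threshold)
    clad_baits = baits_in_clads(baits, partition)
    classification = classify_baits(clad_baits, intersect(k4_peaks, partition.clads))
    density = connection_density(connections, classification)
    annotation = annotate_targets(
        connections, partition, k4_peaks, strategy=config.target_strategy
    )
    proportions = summarize_proportions(annotation, classification)
    proportions.to_csv(config.rundir / "target_proportions.tsv", sep="\t", index=False)
    annotation_to_frame(annotation).to_csv(
        config.rundir / "annotated_connections.tsv", sep="\t", index=False
    )
    result = {
        "n_baits": len(baits),
        "n_clad_baits": len(clad_baits),
        "n_k4_baits": classification.n_k4,
        "n_nonk4_baits": classification.n_nonk4,
        "mean_targets_per_k4_bait": density.class_means["K4"],
        "mean_targets_per_nonk4_bait": density.class_means["nonK4"],
        "mean_unique_targets_per_k4_bait": density.unique_target_means["K4"],
        "mean_unique_targets_per_nonk4_bait": density.unique_target_means["nonK4"],
        "total_k4_targets": density.class_totals["K4"],
        "total_nonk4_targets": density.class_totals["nonK4"],
        "welch_p": density.welch.p_value if density.welch else None,
    }
    (config.rundir / "connectivity_summary.json").write_text(json.dumps(result, indent=1))
    _provenance(config, "connectivity", [conn_path, indir / "h3k4me1_peaks.bed"])
    return result


def stage_chromstates(config: PipelineConfig) -> Dict[str, object]:
    indir = config.inputs_dir
    genome = lio.read_genome(_require(indir / "genome.tsv", "generate"))
    count_paths = sorted(indir.glob("counts_*.bedgraph"))
    if not count_paths:
        raise DataError("no counts_*.bedgraph inputs; run the `generate` subcommand first")
    tracks = {}
    for path in count_paths:
        mark = path.stem.replace("counts_", "")
        df = lio.read_bedgraph(path)
        bs = int((df.end - df.start).mode().iloc[0])
        tracks[mark] = CoverageTrack.from_bedgraph(df, genome, bs)
    binarized = binarize(tracks, bin_size=config.hmm_bin_size)
    model, history = baum_welch(
        binarized, config.n_states, seed=config.seed, max_iter=config.hmm_max_iter
    )
    seg = decode(model, binarized)
    seg.to_bed_frame().to_csv(
        config.rundir / "segmentation.bed", sep="\t", index=False, header=False
    )
    (config.rundir / "hmm_model.json").write_text(json.dumps(model.to_dict(), indent=1))
    result: Dict[str, object] = {
        "n_states": config.n_states,
        "n_iterations": len(history),
        "final_loglik": history[-1],
    }
    ann_path = config.rundir / "annotated_connections.tsv"
    if ann_path.exists():
        ann = pd.read_csv(ann_path, sep="\t")
        targets = [
            GenomicInterval(r.target_chrom, r.target_start, r.target_end)
            for r in ann.itertuples(index=False)
            if r.target_chrom in genome
        ]
        enrich = fold_enrichment(
            seg,
            IntervalSet(
                [GenomicInterval(t.chrom, t.start, t.end) for t in targets], genome
            ),
        )
        enrich.frame.to_csv(config.rundir / "state_enrichment.tsv", sep="\t", index=False)
        attribution = attribute_targets(targets, seg, min_fraction=0.003)
        attribution.to_csv(config.rundir / "target_states.tsv", sep="\t", index=False)
        result["states_with_targets"] = int((attribution.attributions > 0).sum())
    _provenance(config, "chromstates", count_paths)
    return result


def stage_fish(config: PipelineConfig) -> Dict[str, object]:
    indir = config.inputs_dir
    fish_paths = sorted(indir.glob("fish_*.tsv"))
    if not fish_paths:
        raise DataError("no fish_*.tsv inputs; run the `generate` subcommand first")
    rows = []
    for path in fish_paths:
        locus = path.stem.replace("fish_", "")
        records = measure_nuclei(pd.read_csv(path, sep="\t"))
        conditions = sorted({r.condition for r in records})
        frame = records_to_frame(records)
        frame.insert(0, "locus", locus)
        rows.append(frame)
        if len(conditions) == 2:
            a = [r for r in records if r.condition == conditions[0]]
            b = [r for r in records if r.condition == conditions[1]]
            test = compare_conditions(a, b)
            rows[-1].attrs[locus] = test
    all_records = pd.concat(rows, ignore_index=True)
    all_records.to_csv(config.rundir / "fish_distances.tsv", sep="\t", index=False)
    stats_rows = []
    for path in fish_paths:
        locus = path.stem.replace("fish_", "")
        sub = all_records[all_records.locus == locus]
        conds = sorted(sub.condition.unique())
        if len(conds) != 2:
            continue
        a = sub[sub.condition == conds[0]]
        b = sub[sub.condition == conds[1]]
        from .stats import welch_test

        test = welch_test(a.probe_probe_um, b.probe_probe_um)
        stats_rows.append(
            {
                "locus": locus,
                "cond_a": conds[0],
                "cond_b": conds[1],
                "mean_a_um": float(a.probe_probe_um.mean()),
                "mean_b_um": float(b.probe_probe_um.mean()),
                "shift_um": float(b.probe_probe_um.mean() - a.probe_probe_um.mean()),
                "welch_p": test.p_value,
                "peripheral_fraction_green": peripheral_fraction(
                    sub.periphery_green_um, config.peripheral_cutoff_um
                ),
            }
        )
    stats_df = pd.DataFrame(stats_rows)
    stats_df.to_csv(config.rundir / "fish_stats.tsv", sep="\t", index=False)
    _provenance(config, "fish", fish_paths)
    return {"loci": stats_df.locus.tolist(), "stats": stats_rows}


def stage_report(config: PipelineConfig) -> Dict[str, object]:
    report: Dict[str, object] = {"version": __version__, "seed": config.seed}
    for name in ("profiles_summary", "connectivity_summary"):
        path = config.rundir / f"{name}.json"
        if path.exists():
            report[name] = json.loads(path.read_text())
    fish_path = config.rundir / "fish_stats.tsv"
    if fish_path.exists():
        report["fish"] = pd.read_csv(fish_path, sep="\t").to_dict("records")
    out = config.rundir / "report.json"
    out.write_text(json.dumps(report, indent=1, sort_keys=True))
    _provenance(config, "report", [])
    return report


STAGES: Dict[str, Callable[[PipelineConfig], Dict[str, object]]] = {
    "generate": stage_generate,
    "partition": stage_partition,
    "profiles": stage_profiles,
    "connectivity": stage_connectivity,
    "chromstates": stage_chromstates,
    "fish": stage_fish,
    "report": stage_report,
}


def run_stage(name: str, config: PipelineConfig) -> Dict[str, object]:
    """Run one named stage; see ``STAGES`` for the available names."""
    if name not in STAGES:
        raise ConfigError(f"unknown stage {name!r}; choose from {sorted(STAGES)}")
    config.rundir.mkdir(parents=True, exist_ok=True)
    log.info("running stage %s into %s", name, config.rundir)
    return STAGES[name](config)


def run_all(config: PipelineConfig) -> Dict[str, Dict[str, object]]:
    """generate -> partition -> profiles -> connectivity -> chromstates ->
    fish -> report, in order."""
    return {name: run_stage(name, config) for name in STAGES}
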