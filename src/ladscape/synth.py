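"""Seeded synthetic-data generator with known ground truth.

Emulates the statistical structure of an early-adipogenesis LAD study so
every pipeline stage can be exercised without downloads:

* multi-timepoint LAD architectures — constitutive cores shared by all
  timepoints plus per-timepoint variable edges;
* euchromatic H3K4me1 regions punched into half the constitutive LADs,
  carrying clustered H3K4me1 peaks (with H3K27ac nearby) while the rest of
  the LAD is tiled by H3K9me3;
* a lamin log2(ChIP/input) track whose mean is lower inside K4 regions
  than in the non-K4 LAD remainder by a configurable effect size;
* gene models with a two-component expression distribution around the
  15-count threshold, and a coverage track with Gaussian TSS enrichment
  for the expressed genes only;
* a bait-target connection table with 225 K4 and 543 nonK4 baits in
  constitutive LADs (the real study's cLAD bait census), per-class Poisson
  connection counts (defaults 27.5 and 14.7 per bait, the study's printed
  means) and class-dependent target placement over cLAD/vLAD/iLAD;
* binarized chromatin-mark tracks sampled from a known Bernoulli HMM, plus
  matching Poisson count tracks for the binarization step;
* two-condition FISH coordinate tables with a controlled probe-probe
  distance shift per locus.

One RNG stream per file type, each derived from the master seed, so
adding a generator does not perturb the others; regeneration from
(config, seed) is bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as lio
from .chromstates import BinarizedTracks, HMMModel
from .intervals import GenomicInterval, IntervalSet, complement, intersect, union
from .signal import CoverageTrack, GeneModel

__all__ = ["SyntheticConfig", "SyntheticTruth", "SyntheticDataset", "generate", "truth_report"]

# fixed stream indices per file type (stable across versions)
_STREAMS = {
    "lads": 0,
    "peaks": 1,
    "lamin": 2,
    "genes": 3,
    "tss_track": 4,
    "hmm": 5,
    "counts": 6,
    "connections": 7,
    "fish": 8,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), _STREAMS[stream]])


@dataclass
class SyntheticConfig:
    """Study conditions for the generator (defaults mirror the real design)."""

    genome: Dict[str, int] = field(
        default_factory=lambda: {"chr1": 2_000_000, "chr2": 2_000_000, "chr3": 2_000_000}
    )
    timepoints: Tuple[str, ...] = ("D0", "D1", "D3")
    # LAD architecture
    lads_per_chrom: int = 4
    lad_core_bp: int = 250_000
    lad_spacing_bp: int = 450_000
    lad_first_start_bp: int = 100_000
    max_edge_extension_bp: int = 50_000
    # K4 regions and peaks
    k4_region_bp: int = 30_000
    k4_peaks_per_region: int = 6
    k4_peak_bp: int = 1_500
    # lamin track
    lamin_bin_bp: int = 1_000
    lamin_lad_mean: float = 0.5
    lamin_k4_effect: float = 1.0  # K4-region mean = lad_mean - effect
    lamin_ilad_mean: float = -0.5
    lamin_sd: float = 0.3
    # genes + TSS track
    n_expressed_genes: int = 40
    n_silent_clad_genes: int = 60
    n_ilad_genes: int = 20
    expression_threshold: float = 15.0
    tss_track_bin_bp: int = 50
    tss_peak_amplitude: float = 4.0
    tss_peak_sd_bp: float = 500.0
    # connectivity
    n_k4_baits: int = 225
    n_nonk4_baits: int = 543
    n_decoy_baits: int = 200  # outside cLADs; must be filtered out
    bait_bp: int = 2_000
    target_bp: int = 4_000
    lambda_k4: float = 27.5
    lambda_nonk4: float = 14.7
    placement_fractions: Tuple[float, float, float] = (0.7, 0.2, 0.1)  # cLAD/vLAD/iLAD
    p_target_in_k4: Dict[str, float] = field(
        default_factory=lambda: {"K4": 0.33, "nonK4": 0.08}
    )
    noise_fraction: float = 0.10  # extra rows with p > 0.01 to be filtered
    # chromatin-state HMM
    hmm_bin_bp: int = 200
    hmm_marks: Tuple[str, ...] = ("H3K4me1", "H3K9me3")
    hmm_emission: Tuple[Tuple[float, ...], ...] = (
        (0.90, 0.10),
        (0.10, 0.80),
        (0.05, 0.05),
    )
    hmm_self_transition: float = 0.95
    count_rate_low: float = 0.5
    count_rate_high: float = 15.0
    # FISH
    fish_loci: Dict[str, float] = field(
        default_factory=lambda: {"locusA": 0.5, "locusB": -0.5}
    )
    fish_conditions: Tuple[str, ...] = ("D0", "D3")
    fish_nuclei_per_condition: int = 50
    fish_base_distance_um: float = 1.5
    fish_distance_sd_um: float = 0.8
    fish_semi_axes_um: Tuple[float, float, float] = (9.0, 7.0, 5.0)

    def validate(self) -> None:
        if abs(sum(self.placement_fractions) - 1.0) > 1e-9:
            raise ValueError("placement_fractions must sum to 1")
        if self.lambda_k4 <= 0 or self.lambda_nonk4 <= 0:
            raise ValueError("connection rates must be positive")
        if len(self.timepoints) < 2:
            raise ValueError("need >= 2 timepoints")
        em = np.asarray(self.hmm_emission)
        if em.shape[1] != len(self.hmm_marks):
            raise ValueError("hmm_emission columns must match hmm_marks")

    @classmethod
    def from_dict(cls, d: Mapping[str, object]) -> "SyntheticConfig":
        cfg = cls(**{k: v for k, v in d.items() if k in {f.name for f in dataclasses.fields(cls)}})
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg.validate()
        return cfg


@dataclass
class SyntheticTruth:
    """Machine-readable ground truth for recovery tests."""

    seed: int
    config: SyntheticConfig
    core_lads: List[Tuple[str, int, int]]
    k4_regions: List[Tuple[str, int, int]]
    hmm_model: HMMModel
    state_paths_checksum: int
    n_expressed: int
    n_silent: int

    def to_dict(self) -> Dict[str, object]:
        cfg = dataclasses.asdict(self.config)
        return {
            "seed": self.seed,
            "config": cfg,
            "core_lads": [list(t) for t in self.core_lads],
            "k4_regions": [list(t) for t in self.k4_regions],
            "hmm_model": self.hmm_model.to_dict(),
            "state_paths_checksum": self.state_paths_checksum,
            "n_expressed": self.n_expressed,
            "n_silent": self.n_silent,
            "lambda_k4": self.config.lambda_k4,
            "lambda_nonk4": self.config.lambda_nonk4,
            "placement_fractions": list(self.config.placement_fractions),
            "fish_shifts_um": dict(self.config.fish_loci),
            "lamin_k4_effect": self.config.lamin_k4_effect,
        }


@dataclass
class SyntheticDataset:
    """All generated inputs, in memory, plus the truth that produced them."""

    truth: SyntheticTruth
    genome: Dict[str, int]
    lad_sets: Dict[str, IntervalSet]
    k4_peaks: IntervalSet
    k27ac_peaks: IntervalSet
    k9me3_peaks: IntervalSet
    lamin_track: CoverageTrack
    genes: List[GeneModel]
    tss_track: CoverageTrack
    binarized: BinarizedTracks
    count_tracks: Dict[str, CoverageTrack]
    connections: pd.DataFrame
    fish_tables: Dict[str, pd.DataFrame]

    def write(self, outdir) -> Dict[str, Path]:
        """Write every input as plain-text files plus truth.json."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: Dict[str, Path] = {}

        def p(name: str) -> Path:
            paths[name] = outdir / name
            return paths[name]

        lio.write_genome(self.genome, p("genome.tsv"))
        for tp, iset in self.lad_sets.items():
            lio.write_bed(iset, p(f"lads_{tp}.bed"))
        lio.write_bed(self.k4_peaks, p("h3k4me1_peaks.bed"))
        lio.write_bed(self.k27ac_peaks, p("h3k27ac_peaks.bed"))
        lio.write_bed(self.k9me3_peaks, p("h3k9me3_peaks.bed"))
        lio.write_bedgraph(self.lamin_track.to_bedgraph(), p("lamin_log2ratio.bedgraph"))
        genes_df = pd.DataFrame(
            [
                {
                    "gene_id": g.gene_id,
                    "chrom": g.chrom,
                    "tss": g.tss,
                    "strand": g.strand,
                    "expression": g.expression,
                }
                for g in self.genes
            ]
        )
        lio.write_gene_table(genes_df, p("genes.tsv"))
        lio.write_bedgraph(self.tss_track.to_bedgraph(), p("tss_signal.bedgraph"))
        for mark, tr in self.count_tracks.items():
            lio.write_bedgraph(tr.to_bedgraph(), p(f"counts_{mark}.bedgraph"))
        self.connections.to_csv(p("connections.tsv"), sep="\t", index=False)
        for locus, df in self.fish_tables.items():
            df.to_csv(p(f"fish_{locus}.tsv"), sep="\t", index=False)
        with open(p("truth.json"), "w") as fh:
            json.dump(self.truth.to_dict(), fh, indent=1, sort_keys=True)
        return paths


# ---------------------------------------------------------------------------


def _make_lads(cfg: SyntheticConfig, rng: np.random.Generator):
    cores: List[Tuple[str, int, int]] = []
    for chrom in cfg.genome:
        for i in range(cfg.lads_per_chrom):
            s = cfg.lad_first_start_bp + i * cfg.lad_spacing_bp
            cores.append((chrom, s, s + cfg.lad_core_bp))
    lad_sets: Dict[str, IntervalSet] = {}
    for t, tp in enumerate(cfg.timepoints):
        ivs = []
        for chrom, s, e in cores:
            if t == 0:
                left = right = 0  # anchor timepoint: cores exactly
            else:
                left = int(rng.integers(0, cfg.max_edge_extension_bp + 1))
                right = int(rng.integers(0, cfg.max_edge_extension_bp + 1))
            ivs.append(
                GenomicInterval(
                    chrom,
                    max(0, s - left),
                    min(cfg.genome[chrom], e + right),
                )
            )
        lad_sets[tp] = IntervalSet(ivs, cfg.genome)
    return cores, lad_sets


def _make_peaks(cfg: SyntheticConfig, cores, rng: np.random.Generator):
    k4_regions: List[Tuple[str, int, int]] = []
    k4_peaks: List[GenomicInterval] = []
    k27ac: List[GenomicInterval] = []
    k9me3: List[GenomicInterval] = []
    for idx, (chrom, s, e) in enumerate(cores):
        if idx % 2 == 0:  # every other constitutive LAD gets an active region
            mid = (s + e) // 2
            rs, re = mid - cfg.k4_region_bp // 2, mid + cfg.k4_region_bp // 2
            k4_regions.append((chrom, rs, re))
            span = re - rs
            step = span // cfg.k4_peaks_per_region
            for j in range(cfg.k4_peaks_per_region):
                ps = rs + j * step + int(rng.integers(0, max(step - cfg.k4_peak_bp, 1)))
                k4_peaks.append(GenomicInterval(chrom, ps, ps + cfg.k4_peak_bp))
                if j % 2 == 0:
                    k27ac.append(GenomicInterval(chrom, ps, ps + cfg.k4_peak_bp))
            # heterochromatin tiles the LAD outside the active region
            k9me3.append(GenomicInterval(chrom, s, rs))
            k9me3.append(GenomicInterval(chrom, re, e))
        else:
            k9me3.append(GenomicInterval(chrom, s, e))
    # enhancer-like K4 peaks between LADs too
    for chrom in cfg.genome:
        for _ in range(4):
            gap_pos = int(rng.integers(0, cfg.lad_first_start_bp - cfg.k4_peak_bp))
            k4_peaks.append(GenomicInterval(chrom, gap_pos, gap_pos + cfg.k4_peak_bp))
    return (
        k4_regions,
        IntervalSet(k4_peaks, cfg.genome),
        IntervalSet(k27ac, cfg.genome),
        IntervalSet(k9me3, cfg.genome),
    )


def _make_lamin_track(cfg, cores, k4_regions, rng) -> CoverageTrack:
    track = CoverageTrack(cfg.genome, cfg.lamin_bin_bp)
    for chrom, length in cfg.genome.items():
        n = -(-length // cfg.lamin_bin_bp)
        vals = rng.normal(cfg.lamin_ilad_mean, cfg.lamin_sd, size=n)
        starts = np.arange(n) * cfg.lamin_bin_bp
        for c, s, e in cores:
            if c == chrom:
                sel = (starts >= s) & (starts < e)
                vals[sel] = rng.normal(cfg.lamin_lad_mean, cfg.lamin_sd, size=sel.sum())
        for c, s, e in k4_regions:
            if c == chrom:
                sel = (starts >= s) & (starts < e)
                vals[sel] = rng.normal(
                    cfg.lamin_lad_mean - cfg.lamin_k4_effect, cfg.lamin_sd, size=sel.sum()
                )
        track.values[chrom] = vals
    return track


def _make_genes(cfg, cores, k4_regions, rng) -> List[GeneModel]:
    genes: List[GeneModel] = []
    chroms = list(cfg.genome)
    for i in range(cfg.n_expressed_genes):
        chrom, rs, re = k4_regions[int(rng.integers(len(k4_regions)))]
        tss = int(rng.integers(rs + 1000, re - 1000))
        expr = cfg.expression_threshold + float(rng.gamma(2.0, 30.0))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"geneE{i:03d}", chrom, tss, strand, expr))
    silent_cores = [c for idx, c in enumerate(cores) if idx % 2 == 1]
    for i in range(cfg.n_silent_clad_genes):
        chrom, s, e = silent_cores[int(rng.integers(len(silent_cores)))]
        tss = int(rng.integers(s + 1000, e - 1000))
        expr = float(rng.uniform(0.0, 14.5))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"geneS{i:03d}", chrom, tss, strand, expr))
    for i in range(cfg.n_ilad_genes):
        chrom = chroms[int(rng.integers(len(chroms)))]
        tss = int(rng.integers(5_000, cfg.lad_first_start_bp - 5_000))
        expr = (
            cfg.expression_threshold + float(rng.gamma(2.0, 30.0))
            if rng.random() < 0.5
            else float(rng.uniform(0.0, 14.5))
        )
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"geneI{i:03d}", chrom, tss, strand, expr))
    return genes


def _make_tss_track(cfg, genes, rng) -> CoverageTrack:
    track = CoverageTrack(cfg.genome, cfg.tss_track_bin_bp)
    for chrom, length in cfg.genome.items():
        n = -(-length // cfg.tss_track_bin_bp)
        track.values[chrom] = rng.normal(1.0, 0.1, size=n)
    for g in genes:
        if g.expression < cfg.expression_threshold:
            continue
        centers = (
            np.arange(len(track.values[g.chrom])) * cfg.tss_track_bin_bp
            + cfg.tss_track_bin_bp / 2
        )
        bump = cfg.tss_peak_amplitude * np.exp(
            -0.5 * ((centers - g.tss) / cfg.tss_peak_sd_bp) ** 2
        )
        track.values[g.chrom] += bump
    return track


def _make_hmm_data(cfg, rng):
    em = np.asarray(cfg.hmm_emission, dtype=float)
    S = em.shape[0]
    off = (1.0 - cfg.hmm_self_transition) / (S - 1)
    trans = np.full((S, S), off)
    np.fill_diagonal(trans, cfg.hmm_self_transition)
    model = HMMModel(
        emission=em,
        transition=trans,
        initial=np.full(S, 1.0 / S),
        marks=list(cfg.hmm_marks),
    )
    calls: Dict[str, np.ndarray] = {}
    paths: Dict[str, np.ndarray] = {}
    for chrom, length in cfg.genome.items():
        n = -(-length // cfg.hmm_bin_bp)
        path = np.zeros(n, dtype=int)
        path[0] = int(rng.choice(S, p=model.initial))
        for t in range(1, n):
            path[t] = int(rng.choice(S, p=model.transition[path[t - 1]]))
        obs = (rng.random((n, len(cfg.hmm_marks))) < em[path]).astype(np.uint8)
        calls[chrom] = obs
        paths[chrom] = path
    tracks = BinarizedTracks(
        genome=dict(cfg.genome),
        bin_size=cfg.hmm_bin_bp,
        marks=list(cfg.hmm_marks),
        calls=calls,
    )
    return model, tracks, paths


def _make_count_tracks(cfg, binarized: BinarizedTracks, rng) -> Dict[str, CoverageTrack]:
    out: Dict[str, CoverageTrack] = {}
    for m, mark in enumerate(binarized.marks):
        tr = CoverageTrack(cfg.genome, cfg.hmm_bin_bp)
        for chrom, arr in binarized.calls.items():
            lam = np.where(arr[:, m] == 1, cfg.count_rate_high, cfg.count_rate_low)
            tr.values[chrom] = rng.poisson(lam).astype(float)
        out[mark] = tr
    return out


def _sample_interval_in(
    footprint: List[Tuple[str, int, int]], size: int, rng
) -> Tuple[str, int, int]:
    """Uniform-by-length choice of a sub-interval fully inside a footprint."""
    lengths = np.asarray([e - s for _, s, e in footprint], dtype=float)
    ok = lengths > size
    idx = rng.choice(np.flatnonzero(ok), p=lengths[ok] / lengths[ok].sum())
    chrom, s, e = footprint[int(idx)]
    start = int(rng.integers(s, e - size))
    return chrom, start, start + size


def _make_connections(cfg, cores, k4_regions, k4_peaks: IntervalSet, lad_sets, rng):
    # class footprints known by construction: D0 anchors cores exactly
    genome = cfg.genome
    clad_fp = [(c, s, e) for c, s, e in cores]
    union_set = None
    for iset in lad_sets.values():
        union_set = iset if union_set is None else union(union_set, iset)
    core_set = IntervalSet(
        [GenomicInterval(c, s, e) for c, s, e in cores], genome
    )
    vlad_set = intersect(union_set, complement(core_set))
    ilad_set = complement(union_set)
    vlad_fp = [(iv.chrom, iv.start, iv.end) for iv in vlad_set]
    ilad_fp = [(iv.chrom, iv.start, iv.end) for iv in ilad_set]
    k4_region_span = {
        c: [(s, e) for cc, s, e in k4_regions if cc == c] for c in genome
    }
    peaks_in_clads = intersect(k4_peaks, core_set)
    peak_list = list(peaks_in_clads)

    baits: List[Dict[str, object]] = []
    used_coords: set = set()

    def add_bait(chrom: str, start: int, cls: str) -> bool:
        # baits are deduplicated on exact coordinates downstream, so every
        # synthetic bait must be coordinate-unique
        key = (chrom, start)
        if key in used_coords:
            return False
        used_coords.add(key)
        baits.append(
            {"chrom": chrom, "start": start, "end": start + cfg.bait_bp, "class": cls}
        )
        return True

    # K4 baits: overlap a cLAD H3K4me1 peak by construction
    n_placed = 0
    while n_placed < cfg.n_k4_baits:
        pk = peak_list[int(rng.integers(len(peak_list)))]
        shift = int(rng.integers(-(cfg.bait_bp - 1), len(pk)))
        start = max(0, pk.start + shift)
        if add_bait(pk.chrom, start, "K4"):
            n_placed += 1
    # nonK4 baits: inside a core, >= 5 kb away from any K4 region
    margin = 5_000
    nonk4_zones: List[Tuple[str, int, int]] = []
    for chrom, s, e in clad_fp:
        zones = [(s, e)]
        for rs, re in k4_region_span[chrom]:
            nz = []
            for zs, ze in zones:
                if re + margin <= zs or rs - margin >= ze:
                    nz.append((zs, ze))
                else:
                    if rs - margin > zs:
                        nz.append((zs, rs - margin))
                    if re + margin < ze:
                        nz.append((re + margin, ze))
            zones = nz
        nonk4_zones.extend((chrom, zs, ze) for zs, ze in zones if ze - zs > cfg.bait_bp)
    n_placed = 0
    while n_placed < cfg.n_nonk4_baits:
        chrom, s, e = _sample_interval_in(nonk4_zones, cfg.bait_bp, rng)
        if add_bait(chrom, s, "nonK4"):
            n_placed += 1
    # decoy baits outside cLADs (middle of inter-core gaps)
    n_placed = 0
    while n_placed < cfg.n_decoy_baits:
        chrom, s, e = _sample_interval_in(ilad_fp, cfg.bait_bp, rng)
        if add_bait(chrom, s, "decoy"):
            n_placed += 1

    fractions = np.asarray(cfg.placement_fractions)
    footprints = {"cLAD": clad_fp, "vLAD": vlad_fp, "iLAD": ilad_fp}
    rows = []
    for b in baits:
        lam = {
            "K4": cfg.lambda_k4,
            "nonK4": cfg.lambda_nonk4,
            "decoy": cfg.lambda_nonk4,
        }[b["class"]]
        n_conn = int(rng.poisson(lam))
        for _ in range(n_conn):
            lad_cls = ("cLAD", "vLAD", "iLAD")[int(rng.choice(3, p=fractions))]
            in_k4 = (
                lad_cls == "cLAD"
                and rng.random() < cfg.p_target_in_k4.get(b["class"], 0.0)
            )
            if in_k4:
                pk = peak_list[int(rng.integers(len(peak_list)))]
                mid = (pk.start + pk.end) // 2
                ts = max(0, mid - cfg.target_bp // 2)
                chrom, te = pk.chrom, ts + cfg.target_bp
            else:
                fp = footprints[lad_cls]
                if lad_cls == "cLAD":
                    fp = nonk4_zones  # avoid accidental K4 overlap
                chrom, ts, te = _sample_interval_in(fp, cfg.target_bp, rng)
            rows.append(
                {
                    "bait_chrom": b["chrom"],
                    "bait_start": b["start"],
                    "bait_end": b["end"],
                    "target_chrom": chrom,
                    "target_start": ts,
                    "target_end": te,
                    "p_value": float(rng.uniform(0.0, 0.01)),
                    "timepoint": str(rng.choice(list(cfg.timepoints))),
                }
            )
    # non-significant noise rows that p <= 0.01 filtering must drop
    n_noise = int(len(rows) * cfg.noise_fraction)
    for _ in range(n_noise):
        b = baits[int(rng.integers(len(baits)))]
        chrom, ts, te = _sample_interval_in(ilad_fp, cfg.target_bp, rng)
        rows.append(
            {
                "bait_chrom": b["chrom"],
                "bait_start": b["start"],
                "bait_end": b["end"],
                "target_chrom": chrom,
                "target_start": ts,
                "target_end": te,
                "p_value": float(rng.uniform(0.02, 1.0)),
                "timepoint": str(rng.choice(list(cfg.timepoints))),
            }
        )
    return pd.DataFrame(rows)


def _make_fish(cfg, rng) -> Dict[str, pd.DataFrame]:
    tables: Dict[str, pd.DataFrame] = {}
    axes = np.asarray(cfg.fish_semi_axes_um)
    for locus, shift in cfg.fish_loci.items():
        rows = []
        for ci, cond in enumerate(cfg.fish_conditions):
            mu = cfg.fish_base_distance_um + (shift if ci > 0 else 0.0)
            for n in range(cfg.fish_nuclei_per_condition):
                nid = f"{locus}_{cond}_n{n:03d}"
                for allele in range(2):
                    # gene (red) probe near the periphery
                    for _ in range(100):
                        u = rng.normal(size=3)
                        u /= np.linalg.norm(u)
                        s = rng.uniform(0.70, 0.95)
                        red = axes * u * s
                        if np.sum((red / axes) ** 2) < 1.0:
                            break
                    # enhancer (green) probe at a controlled distance
                    for _ in range(200):
                        d = rng.normal(mu, cfg.fish_distance_sd_um)
                        if d < 0.05:
                            continue
                        v = rng.normal(size=3)
                        v /= np.linalg.norm(v)
                        green = red + v * d
                        if np.sum((green / axes) ** 2) < 1.0:
                            break
                    else:
                        green = red * 0.9
                    for channel, pos in (("red", red), ("green", green)):
                        rows.append(
                            {
                                "nucleus_id": nid,
                                "condition": cond,
                                "channel": channel,
                                "x": round(float(pos[0]), 4),
                                "y": round(float(pos[1]), 4),
                                "z": round(float(pos[2]), 4),
                                "cx": 0.0,
                                "cy": 0.0,
                                "cz": 0.0,
                                "ax": float(axes[0]),
                                "ay": float(axes[1]),
                                "az": float(axes[2]),
                            }
                        )
        tables[locus] = pd.DataFrame(rows)
    return tables


def generate(
    config: Optional[SyntheticConfig | Mapping[str, object]] = None,
    seed: int = 0,
    outdir=None,
) -> SyntheticDataset:
    """Generate the full synthetic input suite with ground truth.

    Deterministic given (config, seed); if *outdir* is set, all inputs are
    also written as plain-text files plus ``truth.json``.
    """
    if config is None:
        cfg = SyntheticConfig()
    elif isinstance(config, SyntheticConfig):
        cfg = config
    else:
        cfg = SyntheticConfig.from_dict(config)
    cfg.validate()

    cores, lad_sets = _make_lads(cfg, _rng(seed, "lads"))
    k4_regions, k4_peaks, k27ac, k9me3 = _make_peaks(cfg, cores, _rng(seed, "peaks"))
    lamin = _make_lamin_track(cfg, cores, k4_regions, _rng(seed, "lamin"))
    genes = _make_genes(cfg, cores, k4_regions, _rng(seed, "genes"))
    tss_track = _make_tss_track(cfg, genes, _rng(seed, "tss_track"))
    hmm_model, binarized, paths = _make_hmm_data(cfg, _rng(seed, "hmm"))
    count_tracks = _make_count_tracks(cfg, binarized, _rng(seed, "counts"))
    connections = _make_connections(
        cfg, cores, k4_regions, k4_peaks, lad_sets, _rng(seed, "connections")
    )
    fish_tables = _make_fish(cfg, _rng(seed, "fish"))

    checksum = int(
        sum(int(arr.sum()) * (i + 1) for i, (c, arr) in enumerate(sorted(paths.items())))
    )
    truth = SyntheticTruth(
        seed=seed,
        config=cfg,
        core_lads=cores,
        k4_regions=k4_regions,
        hmm_model=hmm_model,
        state_paths_checksum=checksum,
        n_expressed=sum(1 for g in genes if g.expression >= cfg.expression_threshold),
        n_silent=sum(1 for g in genes if g.expression < cfg.expression_threshold),
    )
    ds = SyntheticDataset(
        truth=truth,
        genome=dict(cfg.genome),
        lad_sets=lad_sets,
        k4_peaks=k4_peaks,
        k27ac_peaks=k27ac,
        k9me3_peaks=k9me3,
        lamin_track=lamin,
        genes=genes,
        tss_track=tss_track,
        binarized=binarized,
        count_tracks=count_tracks,
        connections=connections,
        fish_tables=fish_tables,
    )
    if outdir is not None:
        ds.write(outdir)
    return ds


def truth_report(truth: SyntheticTruth, path=None) -> Dict[str, object]:
    """Ground-truth parameters as a JSON-ready dict (optionally written)."""
    d = truth.to_dict()
    if path is not None:
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1, sort_keys=True)
    return d
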