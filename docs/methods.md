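# Methods

## Coordinate model

All genomic coordinates are 0-based half-open `[start, end)`, the BED
convention; any 1-based dialect must be converted at the reader boundary.
An overlap exists iff two features share at least 1 bp, so book-ended
intervals (`[a,b)`, `[b,c)`) do not overlap but do merge during
normalization. Strand is carried on intervals but ignored by every overlap
test: the analyses served here (LAD membership, bait/target intersection)
are strand-blind. Chromosome names are matched exactly — no `chr` aliasing —
and a validation helper reports name-set mismatches instead of guessing.

The interval engine (sorted per-chromosome start/end arrays with merge,
intersect, complement, union and base-coverage) is implemented directly
rather than delegated, because the ≥ 1 bp overlap rule and base-level
set algebra are the semantic core of the pipeline; the test suite checks it
against a per-base boolean-mask oracle on toy genomes and against bedtools.

## LAD partition

Given one LAD interval set per timepoint, constitutive LADs are the
per-base intersection across all timepoints, variable LADs the union minus
the intersection, and inter-LADs the complement of the union. The per-base
definition (rather than a reciprocal-overlap rule) was chosen because the
quantity of interest downstream is the cLAD base footprint that baits and
targets intersect. An import path (`partition_from_sets`) accepts
externally published cLAD/vLAD coordinates instead; vLAD bases overlapping
the imported cLADs are trimmed so the partition invariant (pairwise
disjoint, tiling the genome) always holds.

H3K4me1 regions inside cLADs are built by extending each peak by half the
merge gap on each side, merging, then trimming the padding back to the
outermost peak boundaries and clipping to cLADs. The merge gap defaults to
10 kb; how finely peaks should be clustered into "regions" is genuinely
open, so the gap is exposed as a parameter. Per-region track means are
length-weighted over bins; missing bins are excluded from the weighting,
never imputed as zero, and a region with no data is reported as NaN.

## Signal tracks and profiles

Coverage tracks are fixed-bin arrays per chromosome with NaN for missing
data. log2 ratio tracks use `log2((chip + c)/(input + c))` with pseudocount
c = 1.0 by default (configurable); bins where both signals are zero are
missing, not 0, so unmappable regions do not dilute region means.

TSS meta-profiles sample the track at offsets −flank … +flank (default
±4 kb in 50-bp steps, 161 positions) around each TSS, mirror minus-strand
genes so that positive offsets are always downstream of transcription, and
average per offset over the genes whose window covers that position
(windows running off a chromosome contribute only covered positions).
Expressed genes are those with normalized read count ≥ 15 (inclusive).
qPCR fold changes use 2^−ΔΔCt against a reference gene and calibrator
condition.

## ECHi-C connectivity

Connections are pooled over timepoints and filtered at p ≤ 0.01
(inclusive). Baits are deduplicated on exact coordinates across timepoints,
while connection multiplicity is retained; per-bait means are therefore
reported both over connections (with multiplicity) and over unique target
coordinates, since archival tables do not always distinguish the two.
Baits with zero retained connections count as zero, not dropped.

A target touching two LAD classes is assigned by largest base overlap with
ties broken cLAD > vLAD > iLAD; an alternative any-overlap-priority
strategy (first class in that precedence with ≥ 1 bp) is available as a
flag because a pure ≥ 1 bp rule is ambiguous for straddling targets.
H3K4me1 status of a target is a plain ≥ 1 bp overlap test against the peak
set. Class proportions are computed over the six
(LAD class × K4 status) cells per bait class and must sum to 1.

## Chromatin-state model

Binarization follows the ChromHMM default scheme: counts are summed into
200-bp bins and a bin is called present iff the upper-tail Poisson
probability of its count under the genome-wide mean rate is below 1e-4.

The state model is a hidden Markov chain with independent Bernoulli
emissions per mark (no mark covariance), trained with Baum–Welch over all
chromosome sequences jointly. Initialization is seeded and non-degenerate:
emissions are the empirical mark frequencies plus uniform jitter in
±0.2 (clipped to [0.02, 0.98]), transitions near-uniform with a sticky 0.9
diagonal, initial distribution uniform. Forward/backward variables are
rescaled per bin; the scaling factors yield the log-likelihood exactly
(checked to 1e-8 against exhaustive path enumeration on 6-bin chains). The
log-likelihood is asserted non-decreasing at every EM iteration; training
stops at an absolute improvement below `tol` (1e-4 by default) or
`max_iter`. Emissions are clipped away from {0, 1} by 1e-6 and a 1e-10
floor keeps transition rows stochastic in degenerate corners. Decoding is
per-bin max posterior by default (Viterbi available by flag) because the
downstream statistics are per-bin footprints, not paths.

`n_states` defaults to 15 to match common practice for rich mark panels,
but the synthetic study conditions use 3 states over 2 marks, which is the
scale at which parameter recovery is meaningfully testable on a desk-sized
genome; state labels are user-supplied annotations, not inferred.

Fold enrichment of an annotation in a state is
`((overlap bases)/(state bases)) / ((annotation bases)/(genome bases))`,
reported as missing for states with zero footprint. Target-to-state
attribution assigns a target to every state it overlaps by ≥ 1 bp
(multi-counting by design); proportions can exclude named states (e.g.
Quiescent) and flag cells below a reporting threshold (0.3%).

## FISH distances

Each analyzable nucleus carries exactly two gene (red) and two enhancer
(green) signals; the two alleles are paired by the minimum-total-distance
matching over the two possible 2×2 assignments, with exact ties keeping
input order. Distances are Euclidean in µm. The nuclear boundary is
modeled as an axis-aligned ellipsoid (center + semi-axes); this is a
deliberate simplification of a DAPI-segmented boundary, and pre-measured
distance tables are accepted directly to bypass geometry entirely.

Point-to-ellipsoid distance solves the Lagrange stationarity condition
`x_i = a_i² p_i/(a_i² + t)` with `Σ (x_i/a_i)² = 1` for the interior root
by bracketed root-finding to 1e-13; exactly-zero probe components are
perturbed by an infinitesimal (1e-9 · a_i) so symmetric degenerate cases
converge to the correct off-axis foot point (verified against a surface-
minimization oracle to 1e-6 µm). Probes numerically outside the boundary
get distance 0 with a warning. A probe is peripheral iff its boundary
distance is ≤ 2 µm (inclusive). Between-condition comparisons are unpaired
two-tailed Welch t-tests at the allele level (no nucleus averaging);
periphery distances are computed for both channels and the caller chooses
which to test, since conventions differ.

## Synthetic study conditions

The generator's defaults are the study conditions all recovery tests and
the acceptance script run under; they were fixed once, from the real
study's design:

* genome: 3 chromosomes × 2 Mb; 4 constitutive LAD cores of 250 kb per
  chromosome; timepoints D0/D1/D3, with D0 anchoring the cores exactly and
  later timepoints extending each edge by 0–50 kb (so the true cLAD set is
  the cores by construction, and vLADs are the variable edges);
* every other core carries a 30-kb euchromatic H3K4me1 region with six
  1.5-kb peaks (H3K27ac on alternate peaks) while the rest of the LAD is
  tiled by H3K9me3; additional H3K4me1 peaks fall between LADs;
* lamin log2 ratio: N(+0.5, 0.3) in LAD bases, N(−0.5, 0.3) outside, and an
  effect size of 1.0 subtracted inside K4 regions;
* genes: 40 expressed (15 + Gamma(2, 30) counts) at K4-region TSSs, 60
  silent (U(0, 14.5)) in non-K4 cLADs, 20 mixed between LADs; expressed
  TSSs add a Gaussian bump (amplitude 4, σ 500 bp) to the TSS track;
* connectivity: 225 K4 baits placed on cLAD H3K4me1 peaks, 543 nonK4 baits
  in cLADs ≥ 5 kb from any K4 region, 200 decoy baits outside cLADs (the
  real census of 768 cLAD baits); per-bait connection counts are
  Poisson(27.5) for K4 and Poisson(14.7) for nonK4 (the published class
  means); targets are placed 0.7/0.2/0.1 over cLAD/vLAD/iLAD, fully inside
  one class so the majority rule is unambiguous, with 33% (K4) / 8% (nonK4)
  of cLAD targets centred on an H3K4me1 peak; 10% extra rows carry
  p > 0.01 and must be filtered out;
* chromatin states: a known 3-state, 2-mark Bernoulli HMM (emissions
  0.9/0.1, 0.1/0.8, 0.05/0.05; self-transition 0.95) sampled over 200-bp
  bins, plus Poisson count tracks (rates 0.5/15 for absent/present calls)
  for the binarization step;
* FISH: two loci with probe-probe distance shifts of +0.5 and −0.5 µm
  between two conditions, base distance 1.5 µm, σ 0.8 µm, 50 nuclei × 2
  alleles per condition (100 alleles), ellipsoid semi-axes (9, 7, 5) µm,
  gene probes placed near the periphery.

Each file type draws from its own RNG stream derived from the master seed,
so adding one generator leaves the others bit-identical.

What the generator does **not** emulate: read-level noise and mappability,
copy-number and GC biases, distance decay in contact frequency, bait
capture efficiency, chromosome territories, or image segmentation error in
FISH coordinates. Passing recovery tests therefore demonstrates that the
statistics recover the designed effects under clean sampling noise, not
that the pipeline is robust to raw-data artifacts; real inputs should be
quality-controlled upstream.

Distance draws for the FISH tables are truncated at the nuclear boundary
(the enhancer probe must stay inside the ellipsoid), which attenuates the
realized mean shift relative to the configured one; the recovery tests
therefore check sign and significance rather than the literal shift value.

## Problem sizes

The default synthetic scale — 6 Mb genome, 968 baits, ≈ 17,000 significant
connections, 2 marks × 30,000 bins, 3 HMM states, 200 nuclei — was chosen
so a full generate → analyze cycle completes in seconds on one CPU while
keeping every statistical contrast well-powered (binomial SDs on placement
fractions < 0.4%, Welch tests at p ≪ 10⁻⁴). HMM parameter-recovery tests
run at 2 states × 10,000 bins, where ±0.05 emission recovery is attainable
and exhaustive-enumeration oracles stay tractable.

## Known limitations

* The ellipsoidal nuclear boundary cannot represent lobulated or tilted
  nuclei; use pre-measured distance tables for real microscopy data.
* The per-base cLAD definition differs from reciprocal-overlap LAD
  harmonization schemes; imported partitions bypass the difference.
* Bernoulli emissions assume conditional independence of marks given the
  state, as in ChromHMM; correlated marks inflate state counts.
* EM finds local optima; seeded jittered initialization makes runs
  reproducible and the label-permutation test checks stability on
  well-separated data, but poorly separated states may still differ across
  seeds.
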