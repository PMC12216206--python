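# Methods

## Scope and data model

`nucleodyn` analyses targeted (hybridization-capture) paired-end
MNase-seq over a panel of loci and summary statistics of coarse-grained
chromatin trajectories. The in-memory unit is the `FragmentSet`: the
MNase-protected fragments of one locus in one library, stored as 0-based
half-open intervals. A fragment is reconstituted from each proper read
pair as `[POS, POS + |TLEN|)` — the sequenced insert, not the read
union. 1-based coordinates appear only at I/O boundaries (SAM POS,
printed target tables, FASTA headers).

All analysis happens in a transcription-oriented frame: for a
minus-strand locus, genomic coordinates are reflected about the TSS on
ingest (base `p → 2·tss − p`, an involution), so the +1 nucleosome is
always at positive TSS offsets and window definitions are
strand-agnostic. Capture regions typically extend beyond the gene, so
the TSS can be placed anywhere inside the region (`tss_override`); by
default it sits at the strand-appropriate region edge.

## Fragment filters and maps

- **Quality.** Pairs are dropped when unpaired/not-proper, secondary or
  supplementary, TLEN 0, mate missing, or MAPQ < 10 on either mate. The
  original per-locus splitting step filtered on a quality threshold of
  10 whose exact meaning (mapping vs. base quality) is ambiguous; this
  package applies it as MAPQ, the natural per-record filter at that
  step, and exposes `mapq_min`. Drop counts are always reported.
- **Length bands.** Nucleosomal analyses keep 100–150 bp inclusive;
  di-nucleosome analyses 230–300 bp inclusive.
- **V-map.** Frequency of a `(start, end)` species = its count divided
  by the library's total fragment count over the locus *after* the
  caller's filters (a switch for pre-filter denominators is deliberate
  future work; the per-replicate frequencies always sum to 1 by
  construction). Replicate averaging is an unweighted mean, with absent
  species contributing zero.
- **Centers.** `center = start + ⌊length/2⌋` (left-of-middle for even
  lengths; fixed and documented). Center profiles draw 20,000 fragments
  without replacement (all, with a warning, if fewer are available)
  and histogram centers on a 1-bp grid over TSS ± 250 bp.
- **Modal length.** Most frequent integer length among fragments
  centered in a window; ties break to the smaller length so hexasome
  calls are conservative.

## Position calling and linkers

Dyads are called on a Gaussian-kernel density of fragment centers
(1-bp grid, kernels truncated at ±4σ, renormalized to sum to 1).
Default bandwidth is 10 bp — below the nucleosome scale, above
digestion noise — and peaks are the `k` highest local maxima subject to
a pairwise separation of ≥ 120 bp, greedily by height with ties to the
leftmost position. "Spacing" between nucleosomes is reported as the
edge-to-edge linker assuming canonical 147-bp footprints,
`ℓ = Δdyad − 147` (so 1 bp means near-adjacent particles); dyad-to-dyad
distances are available via `footprint=0`. Positional variability
across replicates is the per-dyad sample SD.

## Repositioning statistic

Two disjoint TSS-relative windows bracket the alternative +1 positions;
membership is by fragment center (unambiguous single assignment;
overlap counting is available). Defaults are proximal `[+10, +120)` and
distal `[+130, +240)`, chosen to bracket the cold (+1 dyad ≈ +94) and
warm (+1 dyad ≈ +145) configurations; the published windows exist only
graphically, so these are an explicit interpretation, recorded in every
output manifest and fully configurable. Per replicate the statistic is
proximal/distal; cold replicates are normalized by the warm mean ratio;
groups are compared with a two-tailed pooled-variance Student's t
(df = n₁ + n₂ − 2). Both-groups-constant input yields NaN t/p with a
warning rather than a failure. No multiple-testing correction is
applied. Occupancy values divide window counts by the summed ACT7 +
GAPDH fragment totals of the same library.

## Synthetic digestion generator

The generator defines the ground truth the analysis is validated
against. Conditions place canonical 147-bp footprints with a fixed −1
anchor at TSS−145 (so condition differences isolate +1/+2/+3 movement):

| condition | linkers (bp) | particulars |
|---|---|---|
| `warm` | 143, 1, 21 | +1 octasome modal 140 bp, +2 hexasome modal 110 bp |
| `cold` | 92, 34, 39 | all octasomes, modal 147 bp |
| `vrn1_cold` | 92, 34, 39 | +1/+2 fuzziness ×3 (H2A.Z-like variability) |
| `warm_3nuc` | 260, 52 | three particles (alternative single-+1 reading) |

Each fragment picks a particle ∝ weight, displaces its dyad by
`Normal(0, fuzziness_sd)`, draws a protected length
`Normal(modal, footprint_sd)` rounded to integer bp and truncated to
[50, 400], and jitters both ends independently by
`Normal(0, edge_jitter_sd)`. Background fragments are uniform over the
region with lengths uniform in [50, 250] bp. Defaults — fuzziness 5 bp,
footprint SD 4 bp, edge jitter 5 bp, background rate 0.05 — are
realistic MNase-library magnitudes chosen once; the source study states
no digestion depth or jitter, so these are free parameters of the
emulation, not calibrated claims. The `vrn1_cold` tripling is likewise a
choice: the biology states only "more variable".

What the generator does *not* emulate: sequence-dependent MNase cutting
bias, GC/capture efficiency differences between baits, PCR duplicates,
partial digestion ladders, or mappability. Passing tests therefore
demonstrate correctness of the analysis chain on its own statistical
assumptions, not robustness to those real-data artefacts.

With these defaults the warm proximal window contains essentially only
background, so normalized cold/warm repositioning values on synthetic
data are in the 10³–10⁴ range — far larger than on real chromatin,
where the +1 occupies both positions with finite frequency. The
statistic's sign and calibration, not its magnitude, are the portable
quantities.

## Trajectory statistics

Rg is computed per frame over the supplied beads, unweighted by default
(mass weighting optional) — whether published ensemble figures used all
beads or nucleosome centroids is not stated, so the bead selection is
the caller's. The median over post-burn-in frames is reported with a
95% percentile-bootstrap CI: frames are resampled with replacement
(10,000 resamples by default), the median recomputed per resample, and
the 2.5th/97.5th percentiles taken. Frames are resampled independently;
for autocorrelated trajectories this narrows the CI relative to a block
bootstrap — a documented caveat, not corrected here. Inter-nucleosome
distances are Euclidean distances between group centroids per frame,
for every unordered pair. Positional drift of a scalar series is the
RMS and maximum absolute deviation from its initial (or supplied)
reference.

## Bait tiling

Probes of 80 nt start every 40 nt from the region start while they fit;
if the last regular probe stops short of the region end one extra probe
is appended anchored at `end − 80`, keeping all probes full-length and
coverage exact. The vendor's remainder rule is unknown, so edge-probe
counts may differ from the ordered set by one. Probes are emitted on
the plus strand (capture is strand-agnostic). For the 9,568-bp *FLC*
region this yields 238 regular + 1 right-anchored = 239 probes. No
Tm/GC/repeat filtering is applied (vendor-side in practice).

## Numerical and validation choices

- All stochastic stages take explicit integer seeds
  (`numpy.random.default_rng`); identical seeds give bit-identical
  outputs, and the pipeline manifest records every parameter and
  interpretation in force.
- Validation study sizes follow the package's standard conditions:
  20,000-fragment libraries for recovery and power studies (200
  cold-vs-warm and 1,000 null experiments for power/calibration),
  n = 5,000 per particle for modal-length recovery, 500 datasets of
  n = 200 for bootstrap coverage. The modal length of a rounded Normal
  with SD 4 bp has ±1–2 bp sampling noise at n = 5,000 (neighboring
  1-bp bins differ by less than the counting error), so single-draw
  modes are validated within ±2 bp and the median over 11 independent
  draws — which is stable — is required to hit 140/110 exactly.
- Degenerate inputs fail loudly and specifically: empty densities,
  infeasible peak separation (reports how many peaks were found),
  zero-distal replicates (excluded, counted, warned), zero control
  totals, empty trajectory groups.

## Known limitations

- No genome-wide calling, HMM/template nucleosome callers, MNase-bias
  correction, or duplicate marking (the upstream protocol applies
  none).
- The coarse-grained force field and replica-exchange machinery that
  produce trajectories are out of scope; this package only consumes
  coordinates (TSV/XYZ).
- Real-library benchmarks (the deposited capture MNase-seq accession)
  require download and alignment and are not part of the test suite;
  all shipped validation is generator-backed.
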