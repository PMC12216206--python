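# nucleodyn

Targeted MNase-seq nucleosome-dynamics analysis and chromatin-ensemble
statistics, built around the cold-induced repositioning of the +1
nucleosome at the Arabidopsis *FLC* locus.

Micrococcal nuclease (MNase) digests linker DNA and leaves
nucleosome-protected fragments; sequencing both ends of each fragment
gives its exact genomic interval and length. Over a hybridization-capture
target panel this resolves individual nucleosome footprints: octasomes
protect ~147 bp, hexasomes ~110 bp, and a repositioning event shows up as
a shift of the fragment-center distribution. `nucleodyn` implements the
analysis chain for such targeted libraries, plus the ensemble statistics
used on coarse-grained chromatin simulations of the same locus, and a
synthetic digestion generator so the whole chain is testable without any
sequencing data.

## What it computes

For fragments reconstituted per proper read pair as
`[POS, POS + |TLEN|)`:

- **Length-resolved frequency maps (V-maps).** For each fragment species
  `(start, end)`, frequency = count / total fragments over the locus, per
  biological replicate, then replicate-averaged.
- **TSS-centered profiles.** Histogram of fragment centers
  (`start + ⌊length/2⌋`) of a 20,000-fragment random pool within TSS ± 250 bp,
  after keeping the 100–150 bp nucleosomal band.
- **Most-probable positions and linkers.** Gaussian-kernel density of
  centers (default 10 bp bandwidth), its `k` strongest separated peaks as
  dyads `d_i`, and edge-to-edge linkers
  `ℓ_i = (d_{i+1} − d_i) − 147` — the parameterization used to set up
  chromatin models (warm: 143/1/21 bp; cold: 92/34/39 bp).
- **The +1 repositioning statistic.** Per replicate,
  `r = n_proximal / n_distal` over two disjoint TSS-relative windows;
  cold values are normalized by the warm mean ratio and compared with a
  two-tailed pooled-variance Student's t-test.
- **Occupancy normalization** of window counts to the summed fragment
  totals of two control loci (*ACT7* + *GAPDH*) per library.
- **Capture-bait tiling.** 80-nt probes every 40 nt spanning each target
  region (right-anchored final probe), with sequence extraction from a
  genome FASTA.
- **Ensemble statistics** on bead trajectories: radius of gyration
  `Rg = √(Σ w_i |r_i − r̄|² / Σ w_i)` per frame after burn-in, the median
  with a 10,000-resample percentile-bootstrap 95% CI, pairwise
  inter-nucleosome centroid distances, and positional drift.

The synthetic generator (`nucleodyn.synthetic`) encodes the four array
conditions — `warm` (with the 140 bp octasome / 110 bp hexasome
overlapping-di-nucleosome-like +1/+2 pair), `cold` (+1 shifted 51 bp
toward the TSS), `vrn1_cold` (cold positions, 3× fuzzier +1/+2) and
`warm_3nuc` (three particles, linkers 260/52 bp) — plus digestion edge
jitter and uniform background.

## Worked example

Generate the bundled synthetic demo (three warm + three cold replicate
libraries of 20,000 fragments over a minus-strand *FLC*-like locus,
written as SAM) and run the full pipeline on it:

```bash
nucleodyn demo --outdir demo --seed 1
```

prints

```
cold/warm normalized repositioning: [19640.98, 18316.67, 24470.14] (p = 0.00037)
```

and `demo/results/manifest.json` records, per condition, the called
positions

```
WT_warm: dyads (TSS-relative) [-145, 145, 293, 461], linkers [143, 1, 21]
WT_cold: dyads (TSS-relative) [-145, 94, 275, 461],  linkers [92, 34, 39]
```

i.e. the analysis recovers the designed warm and cold linker spacings
exactly and detects the 51-bp TSS-ward shift of the +1 nucleosome: each
cold replicate's proximal/distal ratio (~100) is four orders of
magnitude above the warm mean ratio (~0.005, background only), and the
t-test on the raw ratios gives t = 11.1, df = 4, p = 3.7 × 10⁻⁴.
Per-sample fragment counts, drop reasons, V-map and center-profile TSVs
are written alongside.

Library use mirrors the CLI, e.g.:

```python
from nucleodyn import (build_array_config, sample_fragments, DigestParams,
                       filter_by_length, dyad_density, call_positions,
                       linker_spacings)

cfg = build_array_config("cold")
fs = filter_by_length(sample_fragments(cfg, DigestParams(20000, seed=1)), 100, 150)
call = call_positions(dyad_density(fs, 10), k=4, min_separation=120)
print(linker_spacings(call.dyads))   # [92, 34, 39]
```

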