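"""Synthetic MNase-digestion generator for positioned nucleosome arrays.

Emulates the fragment populations a targeted MNase-seq library produces
over a short promoter-proximal nucleosome array, with the statistical
structure the downstream analysis assumes:

* positioned particles (octasomes ~147 bp, hexasomes ~110 bp protected)
  with per-particle positional fuzziness,
* MNase edge trimming as independent Gaussian jitter on both fragment
  ends,
* a uniform background of sub- to supra-nucleosomal fragments.

The built-in array conditions reproduce the FLC 5'-end configurations of
the vernalization system: a warm (active) state with canonical linkers
143/1/21 bp — the +1/+2 pair forming an overlapping-di-nucleosome-like
structure with ~140 bp and ~110 bp footprints — a cold state with the +1
nucleosome repositioned 51 bp toward the TSS (linkers 92/34/39 bp), a
cold state with elevated +1/+2 fuzziness mimicking H2A.Z
hyperaccumulation in the vrn1 mutant, and an alternative three-particle
warm state (linkers 260/52 bp).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pysam

from .core import FragmentSet, flip_interval
from .trajstats import TrajectoryEnsemble

log = logging.getLogger(__name__)

__all__ = [
    "NucleosomeSpec",
    "ArrayConfig",
    "DigestParams",
    "CONDITIONS",
    "CANONICAL_FOOTPRINT",
    "build_array_config",
    "sample_fragments",
    "write_alignments",
    "make_trajectory_fixture",
]

#: Canonical nucleosome footprint used for linker arithmetic (bp).
CANONICAL_FOOTPRINT = 147

#: Default modal protected lengths by particle kind (bp).
OCTASOME_FOOTPRINT = 147
HEXASOME_FOOTPRINT = 110

_KINDS = {"octasome", "hexasome"}


@dataclass(frozen=True)
class NucleosomeSpec:
    """One positioned particle in an array.

    Parameters
    ----------
    label : nucleosome name in promoter nomenclature ("-1", "+1", ...).
    dyad : signed bp offset of the dyad relative to the TSS,
        transcription-oriented (downstream positive).
    kind : "octasome" or "hexasome".
    footprint_modal : modal protected fragment length (bp).
    footprint_sd : SD of the protected length (bp).
    fuzziness_sd : SD of the dyad position between sampled fragments (bp).
    weight : relative sampling probability (>= 0, dimensionless).
    """

    label: str
    dyad: int
    kind: str = "octasome"
    footprint_modal: int = OCTASOME_FOOTPRINT
    footprint_sd: float = 4.0
    fuzziness_sd: float = 5.0
    weight: float = 1.0

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown particle kind {self.kind!r}; valid: {sorted(_KINDS)}")
        if not 90 <= self.footprint_modal <= 160:
            raise ValueError(
                f"footprint_modal {self.footprint_modal} outside [90, 160] bp "
                "for a single particle"
            )
        if self.fuzziness_sd < 0 or self.footprint_sd < 0:
            raise ValueError("spread parameters must be >= 0")
        if self.weight < 0:
            raise ValueError("weight must be >= 0")

    @property
    def footprint_start(self) -> int:
        """TSS-relative start of the canonical 147-bp footprint (half-open)."""
        return self.dyad - CANONICAL_FOOTPRINT // 2

    @property
    def footprint_end(self) -> int:
        return self.footprint_start + CANONICAL_FOOTPRINT


@dataclass(frozen=True)
class ArrayConfig:
    """A positioned nucleosome array plus sampling context.

    ``region`` is a half-open TSS-relative interval that contains every
    footprint; background fragments are drawn uniformly over it.
    """

    locus_name: str
    chrom: str
    tss: int
    strand: str
    nucleosomes: tuple
    background_rate: float = 0.05
    region: tuple = None

    def __post_init__(self):
        if self.strand not in {"+", "-"}:
            raise ValueError("strand must be + or -")
        if not 0.0 <= self.background_rate <= 1.0:
            raise ValueError("background_rate must be in [0, 1]")
        dyads = [n.dyad for n in self.nucleosomes]
        if any(b <= a for a, b in zip(dyads, dyads[1:])):
            raise ValueError("nucleosome dyads must be strictly increasing")
        if self.region is None:
            lo = min(n.footprint_start for n in self.nucleosomes) - 200
            hi = max(n.footprint_end for n in self.nucleosomes) + 200
            object.__setattr__(self, "region", (lo, hi))
        lo, hi = self.region
        for n in self.nucleosomes:
            if n.footprint_start < lo or n.footprint_end > hi:
                raise ValueError(f"footprint of {n.label} outside region {self.region}")

    @property
    def dyads(self) -> np.ndarray:
        """TSS-relative dyad offsets, transcription-oriented."""
        return np.array([n.dyad for n in self.nucleosomes])

    def linkers(self, footprint: int = CANONICAL_FOOTPRINT) -> list:
        """Edge-to-edge linker lengths assuming ``footprint``-bp particles."""
        d = self.dyads
        return [int(x) for x in np.diff(d) - footprint]


@dataclass(frozen=True)
class DigestParams:
    """MNase digestion / library parameters for fragment sampling."""

    n_fragments: int
    edge_jitter_sd: float = 5.0
    read_length: int = 75
    seed: int = 0

    def __post_init__(self):
        if self.n_fragments <= 0:
            raise ValueError("n_fragments must be > 0")
        if self.edge_jitter_sd < 0:
            raise ValueError("edge_jitter_sd must be >= 0")
        if self.read_length <= 0:
            raise ValueError("read_length must be > 0")


def _chain_dyads(anchor: int, linkers) -> list:
    """Dyads from a -1 anchor and edge-to-edge linkers (147-bp particles)."""
    dyads = [anchor]
    for lk in linkers:
        dyads.append(dyads[-1] + CANONICAL_FOOTPRINT + lk)
    return dyads


def _warm(anchor, fuzz):
    dyads = _chain_dyads(anchor, [143, 1, 21])
    return (
        NucleosomeSpec("-1", dyads[0], "octasome", OCTASOME_FOOTPRINT, fuzziness_sd=fuzz),
        NucleosomeSpec("+1", dyads[1], "octasome", 140, fuzziness_sd=fuzz),
        NucleosomeSpec("+2", dyads[2], "hexasome", HEXASOME_FOOTPRINT, fuzziness_sd=fuzz),
        NucleosomeSpec("+3", dyads[3], "octasome", OCTASOME_FOOTPRINT, fuzziness_sd=fuzz),
    )


def _cold(anchor, fuzz):
    dyads = _chain_dyads(anchor, [92, 34, 39])
    return tuple(
        NucleosomeSpec(lbl, d, "octasome", OCTASOME_FOOTPRINT, fuzziness_sd=fuzz)
        for lbl, d in zip(("-1", "+1", "+2", "+3"), dyads)
    )


def _vrn1_cold(anchor, fuzz):
    # cold positions, but +1/+2 three times fuzzier: attenuated, more
    # variable repositioning with constitutive H2A.Z
    return tuple(
        replace(n, fuzziness_sd=3 * n.fuzziness_sd) if n.label in {"+1", "+2"} else n
        for n in _cold(anchor, fuzz)
    )


def _warm_3nuc(anchor, fuzz):
    dyads = _chain_dyads(anchor, [260, 52])
    return tuple(
        NucleosomeSpec(lbl, d, "octasome", OCTASOME_FOOTPRINT, fuzziness_sd=fuzz)
        for lbl, d in zip(("-1", "+1", "+2"), dyads)
    )


CONDITIONS = {
    "warm": _warm,
    "cold": _cold,
    "vrn1_cold": _vrn1_cold,
    "warm_3nuc": _warm_3nuc,
}


def build_array_config(
    condition: str,
    anchor: int = -145,
    tss: int = 0,
    strand: str = "+",
    chrom: str = "chrSim",
    locus_name: str = None,
    fuzziness_sd: float = 5.0,
    background_rate: float = 0.05,
) -> ArrayConfig:
    """Build a named nucleosome-array condition.

    ``anchor`` is the TSS-relative dyad of the -1 nucleosome; it is held
    at -145 by default across conditions so that condition differences
    isolate +1/+2/+3 repositioning.  Linkers are edge-to-edge distances
    between canonical 147-bp footprints: warm 143/1/21, cold 92/34/39,
    warm_3nuc 260/52.
    """
    try:
        builder = CONDITIONS[condition]
    except KeyError:
        raise ValueError(
            f"unknown condition {condition!r}; valid: {sorted(CONDITIONS)}"
        ) from None
    return ArrayConfig(
        locus_name=locus_name or f"sim_{condition}",
        chrom=chrom,
        tss=tss,
        strand=strand,
        nucleosomes=builder(anchor, fuzziness_sd),
        background_rate=background_rate,
    )


def sample_fragments(
    config: ArrayConfig, digest: DigestParams, label: str = "sim"
) -> FragmentSet:
    """Draw MNase-protected fragments from a nucleosome array.

    Each non-background fragment picks a particle proportionally to its
    weight, displaces the dyad by Normal(0, fuzziness_sd), draws a
    protected length Normal(footprint_modal, footprint_sd) rounded to
    integer bp and truncated to [50, 400], then jitters both ends
    independently by Normal(0, edge_jitter_sd).  Background fragments
    are uniform over the region with lengths uniform in [50, 250].
    Deterministic given ``digest.seed``; coordinates are absolute in the
    transcription-oriented frame (``tss`` + offset).
    """
    weights = np.array([n.weight for n in config.nucleosomes], dtype=float)
    wsum = weights.sum()
    if wsum == 0 and config.background_rate == 0:
        raise ValueError("degenerate array: all weights zero and background_rate 0")

    rng = np.random.default_rng(digest.seed)
    n = digest.n_fragments
    lo, hi = config.region

    if wsum > 0:
        p = weights / wsum
        idx = rng.choice(len(p), size=n, p=p)
        bg = rng.random(n) < config.background_rate
    else:
        idx = np.zeros(n, dtype=int)
        bg = np.ones(n, dtype=bool)

    dyad = np.array([n_.dyad for n_ in config.nucleosomes])[idx]
    fuzz = np.array([n_.fuzziness_sd for n_ in config.nucleosomes])[idx]
    modal = np.array([n_.footprint_modal for n_ in config.nucleosomes])[idx]
    fsd = np.array([n_.footprint_sd for n_ in config.nucleosomes])[idx]

    dyad_c = dyad + np.rint(rng.normal(0.0, 1.0, n) * fuzz).astype(np.int64)
    length = np.clip(
        np.rint(rng.normal(0.0, 1.0, n) * fsd + modal), 50, 400
    ).astype(np.int64)
    start = dyad_c - length // 2
    end = start + length
    jit = np.rint(rng.normal(0.0, digest.edge_jitter_sd, (n, 2))).astype(np.int64)
    start = start + jit[:, 0]
    end = np.maximum(end + jit[:, 1], start + 2)

    # background: uniform placement, broad length range
    bg_len = rng.integers(50, 251, size=n)
    bg_start = lo + rng.integers(0, np.maximum(hi - lo - bg_len, 1), size=n)
    start = np.where(bg, bg_start, start)
    end = np.where(bg, bg_start + bg_len, end)

    return FragmentSet(
        locus_name=config.locus_name,
        chrom=config.chrom,
        tss=config.tss,
        strand=config.strand,
        label=label,
        starts=_abs(start, config.tss),
        ends=_abs(end, config.tss),
    )


def _abs(offsets: np.ndarray, tss: int) -> np.ndarray:
    """TSS-relative offsets to absolute transcription-oriented coordinates."""
    return offsets + tss


def write_alignments(
    fragments: FragmentSet,
    path,
    format: str = "SAM",
    read_length: int = 75,
    reference_length: int = None,
) -> Path:
    """Write a FragmentSet as a SAM file of proper read pairs, or as BED3.

    Coordinates are emitted genomic (the transcription-orientation flip
    is undone for minus-strand loci); SAM POS is 1-based per the
    standard, |TLEN| equals the fragment length, and the pair carries
    proper-pairing FLAGs so the reader reconstitutes the identical
    FragmentSet.
    """
    fmt = format.upper()
    if fmt not in {"SAM", "BED"}:
        raise ValueError(f"unknown format {format!r}; valid: SAM, BED")
    if read_length < 1:
        raise ValueError("read_length must be >= 1")
    if np.any(fragments.lengths < 2):
        raise ValueError("fragments shorter than 2 bp cannot be written as pairs")

    path = Path(path)
    gstart, gend = fragments.genomic_intervals()

    if fmt == "BED":
        with open(path, "w") as fh:
            for s, e in zip(gstart, gend):
                fh.write(f"{fragments.chrom}\t{s}\t{e}\n")
        return path

    if reference_length is None:
        reference_length = int(gend.max()) + 1000 if len(fragments) else 1000
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": fragments.chrom, "LN": int(reference_length)}],
        }
    )
    lengths = gend - gstart
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i, (s, e, L) in enumerate(zip(gstart, gend, lengths)):
            r = int(min(read_length, L))
            qname = f"frag{i:07d}"
            fwd = pysam.AlignedSegment(header)
            fwd.query_name = qname
            fwd.flag = 99  # paired, proper, mate reverse, first in pair
            fwd.reference_id = 0
            fwd.reference_start = int(s)
            fwd.mapping_quality = 60
            fwd.cigarstring = f"{r}M"
            fwd.next_reference_id = 0
            fwd.next_reference_start = int(e) - r
            fwd.template_length = int(L)
            fwd.query_sequence = "N" * r
            fwd.query_qualities = pysam.qualitystring_to_array("I" * r)

            rev = pysam.AlignedSegment(header)
            rev.query_name = qname
            rev.flag = 147  # paired, proper, reverse, second in pair
            rev.reference_id = 0
            rev.reference_start = int(e) - r
            rev.mapping_quality = 60
            rev.cigarstring = f"{r}M"
            rev.next_reference_id = 0
            rev.next_reference_start = int(s)
            rev.template_length = -int(L)
            rev.query_sequence = "N" * r
            rev.query_qualities = pysam.qualitystring_to_array("I" * r)

            out.write(fwd)
            out.write(rev)
    return path


def make_trajectory_fixture(kind: str, seed: int = 0, **params) -> TrajectoryEnsemble:
    """Build small bead-trajectory ensembles with known statistics.

    Kinds
    -----
    line : ``n`` beads equally spaced by ``spacing`` on the x axis,
        repeated for ``n_frames`` frames (closed-form
        ``Rg^2 = spacing^2 (n^2 - 1) / 12``).
    square : 4 beads at the corners of a square of side ``side``
        (``Rg = side / sqrt(2)``).
    gaussian_cloud : ``n`` i.i.d. isotropic Normal(0, ``sd``) beads,
        redrawn each frame.
    two_state : two beads whose separation alternates between ``d_a``
        and ``d_b`` on consecutive frames (bimodality fixture); groups
        "n1"/"n2" mark the two beads.
    """
    n_frames = int(params.pop("n_frames", 1))
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    if kind == "line":
        n = int(params.pop("n", 2))
        spacing = float(params.pop("spacing", 1.0))
        if n < 1:
            raise ValueError("n must be >= 1")
        frame = np.zeros((n, 3))
        frame[:, 0] = np.arange(n) * spacing
        coords = np.repeat(frame[None], n_frames, axis=0)
        return TrajectoryEnsemble(coords)
    if kind == "square":
        side = float(params.pop("side", 1.0))
        frame = np.array(
            [[0, 0, 0], [side, 0, 0], [0, side, 0], [side, side, 0]], dtype=float
        )
        return TrajectoryEnsemble(np.repeat(frame[None], n_frames, axis=0))
    if kind == "gaussian_cloud":
        n = int(params.pop("n", 10))
        sd = float(params.pop("sd", 1.0))
        if n < 1:
            raise ValueError("n must be >= 1")
        return TrajectoryEnsemble(rng.normal(0.0, sd, size=(n_frames, n, 3)))
    if kind == "two_state":
        d_a = float(params.pop("d_a", 5.0))
        d_b = float(params.pop("d_b", 15.0))
        coords = np.zeros((n_frames, 2, 3))
        seps = np.where(np.arange(n_frames) % 2 == 0, d_a, d_b)
        coords[:, 1, 0] = seps
        return TrajectoryEnsemble(
            coords, groups={"n1": np.array([0]), "n2": np.array([1])}
        )
    raise ValueError(
        f"unknown fixture kind {kind!r}; valid: line, square, gaussian_cloud, two_state"
    )
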