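"""Hybridization-capture bait tiling over target loci.

Baits are 80-nt oligos overlapping by 40 nt spanning the entire target
region; when the region length is not a multiple of the step, one extra
probe is appended anchored at the region's right edge so coverage stays
complete without shortening any probe.  Probes are emitted on the plus
strand regardless of gene strand (capture is strand-agnostic).
"""

from __future__ import annotations

from dataclasses import dataclass

from pyfaidx import Fasta

from .core import TargetLocus

__all__ = ["BaitSet", "tile_baits", "bait_fasta", "write_bait_fasta", "write_bait_bed"]


@dataclass
class BaitSet:
    """Tiled probes over one target locus (0-based half-open intervals)."""

    locus_id: str
    chrom: str
    probes: list  # list of (start, end) tuples
    probe_len: int
    step: int

    def __len__(self) -> int:
        return len(self.probes)


def tile_baits(locus: TargetLocus, probe_len: int = 80, step: int = 40) -> BaitSet:
    """Tile ``probe_len``-nt probes every ``step`` nt across a locus.

    Probes start at ``region_start + i*step`` while they fit; if the last
    regular probe stops short of the region end, a final probe anchored
    at ``region_end - probe_len`` is appended.  Full coverage of the
    region is guaranteed whenever ``step <= probe_len``.
    """
    if probe_len < 1 or step < 1:
        raise ValueError("probe_len and step must be >= 1")
    if locus.length < probe_len:
        raise ValueError(
            f"locus {locus.locus_id} ({locus.length} bp) is shorter than one "
            f"{probe_len}-nt probe; pad the region before tiling"
        )
    probes = []
    start = locus.start
    while start + probe_len <= locus.end:
        probes.append((start, start + probe_len))
        start += step
    if probes[-1][1] < locus.end:
        probes.append((locus.end - probe_len, locus.end))
    return BaitSet(locus.locus_id, locus.chrom, probes, probe_len, step)


def bait_fasta(baits: BaitSet, genome) -> list:
    """Extract plus-strand probe sequences from a genome FASTA.

    ``genome`` is a path or an open ``pyfaidx.Fasta``.  Returns
    ``(header, sequence)`` pairs with headers
    ``locus_id:chrom:start-end`` in 1-based inclusive coordinates.
    """
    fa = genome if isinstance(genome, Fasta) else Fasta(str(genome))
    if baits.chrom not in fa:
        raise ValueError(f"chromosome {baits.chrom!r} not in genome FASTA")
    chrom_len = len(fa[baits.chrom])
    records = []
    for start, end in baits.probes:
        if start < 0 or end > chrom_len:
            raise ValueError(
                f"probe [{start}, {end}) outside chromosome {baits.chrom} "
                f"(length {chrom_len})"
            )
        seq = fa[baits.chrom][start:end].seq
        records.append((f"{baits.locus_id}:{baits.chrom}:{start + 1}-{end}", seq))
    return records


def write_bait_fasta(records, path) -> None:
    with open(path, "w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n{seq}\n")


def write_bait_bed(baits: BaitSet, path) -> None:
    with open(path, "w") as fh:
        for start, end in baits.probes:
            fh.write(f"{baits.chrom}\t{start}\t{end}\t{baits.locus_id}\n")
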