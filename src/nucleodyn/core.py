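"""Core containers for targeted MNase-seq fragment analysis.

Coordinate conventions
----------------------
All intervals are 0-based half-open internally; 1-based inclusive
coordinates appear only at I/O boundaries (SAM POS, printed target
tables, FASTA headers).

Analysis happens in a *transcription-oriented* frame: for a locus on the
minus strand, genomic coordinates are reflected about the TSS on ingest
so that the +1 nucleosome always lies downstream (at positive offsets
from the TSS).  The reflection maps base ``p`` to ``2*tss - p`` and the
half-open interval ``[s, e)`` to ``[2*tss - e + 1, 2*tss - s + 1)``; it
is an involution, so applying it twice restores genomic coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

__all__ = [
    "FragmentRecord",
    "FragmentSet",
    "TargetLocus",
    "flip_interval",
    "flip_position",
]


def flip_position(pos, tss: int):
    """Reflect a base coordinate about ``tss`` (strand flip, involution)."""
    return 2 * tss - np.asarray(pos)


def flip_interval(start, end, tss: int):
    """Reflect half-open interval(s) ``[start, end)`` about ``tss``.

    Returns the reflected ``(start, end)`` pair, again half-open with
    ``end > start``.
    """
    start = np.asarray(start)
    end = np.asarray(end)
    return 2 * tss - end + 1, 2 * tss - start + 1


@dataclass(frozen=True)
class FragmentRecord:
    """One MNase-protected fragment as a genomic interval."""

    chrom: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(
                f"fragment end must exceed start: [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        """Fragment center, ``start + floor(length / 2)`` (left-of-middle)."""
        return self.start + self.length // 2


@dataclass(frozen=True)
class TargetLocus:
    """One capture/analysis target region (a row of the bait-order table).

    ``start``/``end`` are stored 0-based half-open; the constructors from
    printed tables convert from 1-based inclusive.
    """

    chrom: str
    start: int
    end: int
    strand: str
    locus_id: str
    gene_name: str
    tss_override: int = None

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"locus {self.locus_id}: end must exceed start")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"locus {self.locus_id}: strand must be + or -")

    @classmethod
    def from_printed(cls, chrom, start1, end1, strand, locus_id, gene_name):
        """Build from printed 1-based inclusive coordinates."""
        strand = str(strand).replace("−", "-")  # unicode minus
        return cls(str(chrom), int(start1) - 1, int(end1), strand,
                   str(locus_id), str(gene_name))

    @property
    def start1(self) -> int:
        """1-based inclusive start, as printed."""
        return self.start + 1

    @property
    def end1(self) -> int:
        """1-based inclusive end, as printed."""
        return self.end

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        """0-based coordinate of the transcription start site.

        ``tss_override`` when set (capture regions usually extend beyond
        the gene, so the TSS is interior); otherwise the strand-dependent
        region edge: ``start`` for plus-strand loci, ``end - 1`` for
        minus-strand loci.
        """
        if self.tss_override is not None:
            return self.tss_override
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class FragmentSet:
    """A set of MNase fragments for one locus and one sample.

    Fragments are stored in the transcription-oriented frame (see module
    docstring): for minus-strand loci the genomic intervals have been
    reflected about ``tss`` so downstream of the TSS is always to the
    right.  ``starts``/``ends`` are parallel int arrays, 0-based half-open.
    """

    locus_name: str
    chrom: str
    tss: int
    strand: str
    label: str = ""
    starts: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    ends: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    dropped: dict = field(default_factory=dict)

    def __post_init__(self):
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        if self.starts.shape != self.ends.shape:
            raise ValueError("starts and ends must have equal length")
        if np.any(self.ends <= self.starts):
            raise ValueError("all fragments must satisfy end > start")
        if self.strand not in {"+", "-"}:
            raise ValueError("strand must be + or -")

    def __len__(self) -> int:
        return self.starts.size

    def __iter__(self) -> Iterator[FragmentRecord]:
        for s, e in zip(self.starts, self.ends):
            yield FragmentRecord(self.chrom, int(s), int(e))

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def centers(self) -> np.ndarray:
        """Fragment centers, ``start + floor(length / 2)``."""
        return self.starts + self.lengths // 2

    def subset(self, mask) -> "FragmentSet":
        """New FragmentSet keeping fragments where ``mask`` is true."""
        mask = np.asarray(mask)
        return FragmentSet(
            self.locus_name, self.chrom, self.tss, self.strand, self.label,
            self.starts[mask], self.ends[mask], dict(self.dropped),
        )

    def replace(self, starts, ends) -> "FragmentSet":
        return FragmentSet(
            self.locus_name, self.chrom, self.tss, self.strand, self.label,
            starts, ends, dict(self.dropped),
        )

    def genomic_intervals(self):
        """Fragment intervals in genomic coordinates (undo the strand flip)."""
        if self.strand == "+":
            return self.starts.copy(), self.ends.copy()
        gs, ge = flip_interval(self.starts, self.ends, self.tss)
        return gs, ge

    def sort(self) -> "FragmentSet":
        """Fragments sorted by (start, end); stable."""
        order = np.lexsort((self.ends, self.starts))
        return self.replace(self.starts[order], self.ends[order])
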