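"""Read paired-end alignments and target-locus tables.

Nucleosomal fragments are reconstituted per read pair from the leftmost
mate position and the template length (|TLEN|), i.e. the sequenced
insert, after dropping unpaired, secondary/supplementary, low-MAPQ and
zero-TLEN records.  The "quality under 10" filter of the original
per-locus BAM split is applied as a MAPQ threshold (configurable via
``mapq_min``).
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .core import FragmentSet, TargetLocus, flip_interval

log = logging.getLogger(__name__)

__all__ = ["load_targets", "packaged_targets", "read_fragments"]

_SCHEMA = [
    "chromosome",
    "start_coordinate",
    "end_coordinate",
    "strand",
    "locus_identifier",
    "gene_name",
]


def load_targets(path) -> list:
    """Load a tab-separated target-locus table into TargetLocus records.

    The table uses the bait-order schema (chromosome, start_coordinate,
    end_coordinate, strand, locus_identifier, gene_name) with printed
    1-based inclusive coordinates; these are converted to internal
    0-based half-open intervals.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != _SCHEMA:
        raise ValueError(
            f"target table header {list(df.columns)} does not match {_SCHEMA}"
        )
    if df.empty:
        log.warning("target table %s is empty", path)
        return []
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out.append(
                TargetLocus.from_printed(
                    row.chromosome,
                    row.start_coordinate,
                    row.end_coordinate,
                    row.strand,
                    row.locus_identifier,
                    row.gene_name,
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed target table row {i}: {exc}") from exc
    return out


def packaged_targets() -> list:
    """The bundled bait-order target table (TAIR10 coordinates)."""
    with resources.as_file(
        resources.files("nucleodyn.data").joinpath("target_loci.tsv")
    ) as p:
        return load_targets(p)


def read_fragments(
    alignment_path,
    locus: TargetLocus,
    mapq_min: int = 10,
    label: str = "",
) -> FragmentSet:
    """Reconstitute MNase fragments overlapping ``locus`` from SAM/BAM.

    One FragmentRecord per proper pair, built as ``[pos, pos + |TLEN|)``
    from the leftmost mate.  Pairs are dropped (and counted by reason in
    ``FragmentSet.dropped``) when unpaired, secondary/supplementary,
    below ``mapq_min`` on either mate, with TLEN 0, or with a missing
    mate.  Coordinates are flipped to the transcription-oriented frame
    for minus-strand loci.
    """
    path = Path(alignment_path)
    dropped = {
        "unpaired": 0,
        "secondary_supplementary": 0,
        "low_mapq": 0,
        "tlen_zero": 0,
        "mate_missing": 0,
    }
    # per read name: [leftmost_start, |tlen|, min_mapq, n_mates_seen]
    pairs: dict = {}

    with pysam.AlignmentFile(str(path), require_index=False) as af:
        if path.suffix.lower() == ".bam" and af.has_index():
            it = af.fetch(locus.chrom, locus.start, locus.end)
        else:
            if path.suffix.lower() == ".bam":
                raise ValueError(
                    f"{path}: BAM region query requires an index; run "
                    "'samtools index' or supply SAM"
                )
            it = af.fetch(until_eof=True)
        for rec in it:
            if rec.is_unmapped or rec.reference_name != locus.chrom:
                continue
            if not rec.is_paired or not rec.is_proper_pair:
                dropped["unpaired"] += 1
                continue
            if rec.is_secondary or rec.is_supplementary:
                dropped["secondary_supplementary"] += 1
                continue
            info = pairs.setdefault(rec.query_name, [None, None, 255, 0])
            info[2] = min(info[2], rec.mapping_quality)
            info[3] += 1
            if rec.template_length > 0:
                info[0] = rec.reference_start
                info[1] = rec.template_length
            elif rec.template_length == 0:
                info[1] = 0

    starts, ends = [], []
    for name, (pos, tlen, mq, nseen) in pairs.items():
        if tlen == 0:
            dropped["tlen_zero"] += 1
            continue
        if nseen < 2:
            dropped["mate_missing"] += 1
            continue
        if mq < mapq_min:
            dropped["low_mapq"] += 1
            continue
        if pos is None:
            dropped["mate_missing"] += 1
            continue
        s, e = pos, pos + tlen
        if e <= locus.start or s >= locus.end:
            continue
        starts.append(s)
        ends.append(e)

    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if locus.strand == "-" and starts.size:
        starts, ends = flip_interval(starts, ends, locus.tss)
    for reason, count in dropped.items():
        if count:
            log.info("%s @ %s: dropped %d records (%s)", path.name,
                     locus.gene_name, count, reason)
    return FragmentSet(
        locus_name=locus.gene_name,
        chrom=locus.chrom,
        tss=locus.tss,
        strand=locus.strand,
        label=label,
        starts=starts,
        ends=ends,
        dropped=dropped,
    )
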