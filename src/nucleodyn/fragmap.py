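"""Length-resolved fragment frequency maps and center profiles.

The V-map records, per (start, end) fragment species, the fraction of
all fragments over the locus with exactly that interval, per biological
replicate and replicate-averaged; it is the tabular form of the
position-versus-length segment plot used to read nucleosome footprints.
The center profile is a 1-bp histogram of fragment centers around the
TSS built from a fixed-size random pool of nucleosomal fragments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import FragmentSet

log = logging.getLogger(__name__)

__all__ = [
    "VMap",
    "CenterProfile",
    "filter_by_length",
    "build_vmap",
    "center_profile",
    "modal_length",
]

#: Mono-/sub-nucleosomal analysis band (bp, inclusive).
MONO_BAND = (100, 150)
#: Adjacent di-nucleosome analysis band (bp, inclusive).
DI_BAND = (230, 300)


def filter_by_length(fragments: FragmentSet, lo: int, hi: int) -> FragmentSet:
    """Keep fragments with ``lo <= length <= hi`` (inclusive), order kept."""
    if lo > hi:
        raise ValueError(f"lo ({lo}) must not exceed hi ({hi})")
    lengths = fragments.lengths
    return fragments.subset((lengths >= lo) & (lengths <= hi))


@dataclass
class VMap:
    """Per-locus fragment-species frequency table.

    ``table`` columns: start, end, length, one ``freq_<label>`` column
    per replicate, and ``mean_freq`` (their unweighted mean).  Each
    replicate's frequencies sum to 1 over the locus.
    """

    locus_name: str
    table: pd.DataFrame
    replicate_labels: list

    @property
    def freq_columns(self) -> list:
        return [f"freq_{lab}" for lab in self.replicate_labels]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def build_vmap(replicates) -> VMap:
    """Build the replicate-averaged (start, end) frequency map.

    The frequency of a fragment species is its count divided by the
    replicate's total fragment count over the locus (after whatever
    filters the caller applied); species absent from a replicate
    contribute frequency 0 to the average.
    """
    replicates = list(replicates)
    if not replicates:
        raise ValueError("at least one replicate required")
    locus = replicates[0].locus_name
    if any(r.locus_name != locus for r in replicates):
        raise ValueError("all replicates must come from the same locus")

    labels = []
    per_rep = []
    for i, rep in enumerate(replicates):
        lab = rep.label or f"rep{i + 1}"
        labels.append(lab)
        if len(rep) == 0:
            log.warning("replicate %s is empty; contributes zeros", lab)
            per_rep.append(pd.Series(dtype=float, name=f"freq_{lab}"))
            continue
        df = pd.DataFrame({"start": rep.starts, "end": rep.ends})
        counts = df.value_counts(["start", "end"]).sort_index()
        per_rep.append((counts / len(rep)).rename(f"freq_{lab}"))

    wide = pd.concat(per_rep, axis=1).fillna(0.0)
    wide["mean_freq"] = wide[[f"freq_{lab}" for lab in labels]].mean(axis=1)
    wide = wide.reset_index()
    wide["start"] = wide["start"].astype(np.int64)
    wide["end"] = wide["end"].astype(np.int64)
    wide["length"] = wide["end"] - wide["start"]
    cols = ["start", "end", "length"] + [f"freq_{lab}" for lab in labels] + ["mean_freq"]
    return VMap(locus, wide[cols].sort_values(["start", "end"]).reset_index(drop=True), labels)


@dataclass
class CenterProfile:
    """Histogram of pooled fragment centers around the TSS.

    ``positions`` are TSS-relative (transcription-oriented) bp on a 1-bp
    grid spanning ±``half_window``; ``counts[i]`` is the number of pooled
    fragment centers at ``positions[i]``.
    """

    locus_name: str
    positions: np.ndarray
    counts: np.ndarray
    pool_n: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"position": self.positions, "count": self.counts})


def center_profile(
    replicates,
    tss: int = None,
    half_window: int = 250,
    pool_n: int = 20000,
    seed: int = 0,
) -> CenterProfile:
    """Pool fragments across replicates and histogram their centers.

    ``pool_n`` fragments (20,000 by default) are drawn without
    replacement from the concatenated replicates; if fewer are available
    all are used with a warning.  The center of a fragment is
    ``start + floor(length/2)``.  Callers should length-filter to the
    nucleosomal band (100-150 bp) first.
    """
    if pool_n <= 0:
        raise ValueError("pool_n must be > 0")
    if isinstance(replicates, FragmentSet):
        replicates = [replicates]
    replicates = list(replicates)
    if not replicates:
        raise ValueError("no fragments supplied")
    if tss is None:
        tss = replicates[0].tss
    centers = np.concatenate([r.centers for r in replicates])
    rng = np.random.default_rng(seed)
    if centers.size > pool_n:
        centers = rng.choice(centers, size=pool_n, replace=False)
    elif centers.size < pool_n:
        log.warning(
            "only %d fragments available for a pool of %d; using all",
            centers.size, pool_n,
        )
    rel = centers - tss
    positions = np.arange(-half_window, half_window + 1)
    in_win = (rel >= -half_window) & (rel <= half_window)
    counts = np.bincount(rel[in_win] + half_window, minlength=positions.size)
    return CenterProfile(
        locus_name=replicates[0].locus_name,
        positions=positions,
        counts=counts,
        pool_n=int(centers.size),
        seed=seed,
    )


def modal_length(fragments: FragmentSet, window) -> int:
    """Most frequent fragment length among fragments centered in ``window``.

    ``window`` is a half-open absolute interval in the oriented frame.
    Ties break toward the smaller length.  Raises if no fragment center
    falls in the window (distinct from any valid mode).
    """
    lo, hi = window
    if hi <= lo:
        raise ValueError("window must be non-empty")
    centers = fragments.centers
    sel = (centers >= lo) & (centers < hi)
    if not sel.any():
        raise ValueError(f"no fragments centered in window [{lo}, {hi})")
    lengths = fragments.lengths[sel]
    counts = np.bincount(lengths)
    return int(counts.argmax())  # argmax takes the first (smallest) on ties
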