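"""Ensemble statistics for coarse-grained chromatin trajectories.

Operates on saved bead coordinates (frames x beads x 3), not on the
simulation engine: radius-of-gyration distributions with a percentile
bootstrap CI of the median, pairwise inter-nucleosome distance
distributions from group centroids, and positional drift of scalar
series.  An initial burn-in block of frames is discarded before any
statistic is computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "TrajectoryEnsemble",
    "RgSummary",
    "DistanceDistributions",
    "radius_of_gyration",
    "frame_rg",
    "bootstrap_median_ci",
    "rg_summary",
    "internucleosome_distances",
    "positional_drift",
    "read_trajectory_tsv",
    "read_trajectory_xyz",
]


@dataclass
class TrajectoryEnsemble:
    """Frames x beads x 3 coordinates (nm) with burn-in and bead groups.

    ``groups`` maps a nucleosome label to the indices of its beads;
    groups must be disjoint and non-empty.
    """

    coords: np.ndarray
    burn_in: int = 0
    groups: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_beads, 3)")
        if not 0 <= self.burn_in < self.n_frames:
            raise ValueError("burn_in must be < frame count")
        seen = set()
        for label, idx in self.groups.items():
            idx = np.asarray(idx, dtype=int)
            if idx.size == 0:
                raise ValueError(f"group {label!r} is empty")
            if seen & set(idx.tolist()):
                raise ValueError("groups must be disjoint")
            seen |= set(idx.tolist())
            self.groups[label] = idx

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_beads(self) -> int:
        return self.coords.shape[1]

    def production(self, burn_in: int = None) -> np.ndarray:
        """Frames after discarding the burn-in block."""
        b = self.burn_in if burn_in is None else burn_in
        if not 0 <= b < self.n_frames:
            raise ValueError("burn_in must be < frame count")
        return self.coords[b:]


def radius_of_gyration(coords, weights=None) -> float:
    """Radius of gyration of one frame: RMS distance from the centroid.

    ``Rg = sqrt(sum_i w_i |r_i - rbar|^2 / sum_i w_i)`` with ``rbar`` the
    (weighted) centroid; unweighted by default.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coords must have shape (n_beads, 3)")
    if coords.shape[0] < 1:
        raise ValueError("need at least one bead")
    if weights is None:
        weights = np.ones(coords.shape[0])
    weights = np.asarray(weights, dtype=float)
    total = weights.sum()
    if total <= 0:
        raise ValueError("total weight must be > 0")
    centroid = (weights[:, None] * coords).sum(axis=0) / total
    sq = ((coords - centroid) ** 2).sum(axis=1)
    return float(np.sqrt((weights * sq).sum() / total))


def frame_rg(ensemble: TrajectoryEnsemble, burn_in: int = None, weights=None) -> np.ndarray:
    """Per-frame Rg over the production (post-burn-in) frames."""
    frames = ensemble.production(burn_in)
    if weights is None:
        w = np.ones(frames.shape[1])
    else:
        w = np.asarray(weights, dtype=float)
    total = w.sum()
    centroid = (w[None, :, None] * frames).sum(axis=1) / total
    sq = ((frames - centroid[:, None, :]) ** 2).sum(axis=2)
    return np.sqrt((w[None, :] * sq).sum(axis=1) / total)


def bootstrap_median_ci(values, n_boot: int = 10000, seed: int = 0,
                        percentiles=(2.5, 97.5)):
    """Percentile-bootstrap CI for the median.

    Resamples the values with replacement ``n_boot`` times, takes the
    median of each resample, and returns the requested percentiles of
    the bootstrap medians as ``(median, lo, hi)``.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least two values")
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    if n_boot < 100:
        log.warning("n_boot=%d is small; CI will be unstable", n_boot)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    medians = np.median(values[idx], axis=1)
    lo, hi = np.percentile(medians, percentiles)
    return float(np.median(values)), float(lo), float(hi)


@dataclass
class RgSummary:
    """Median Rg with percentile-bootstrap 95% CI."""

    median: float
    ci_low: float
    ci_high: float
    n_boot: int
    percentiles: tuple
    n_frames: int
    seed: int

    def summary(self) -> str:
        return (
            f"Rg median {self.median:.4g} nm, "
            f"{self.percentiles[0]:g}-{self.percentiles[1]:g}% bootstrap CI "
            f"[{self.ci_low:.4g}, {self.ci_high:.4g}] nm "
            f"({self.n_frames} frames, {self.n_boot} resamples)"
        )


def rg_summary(
    ensemble: TrajectoryEnsemble,
    burn_in: int = None,
    n_boot: int = 10000,
    seed: int = 0,
    weights=None,
) -> RgSummary:
    """Median per-frame Rg after burn-in, with 95% bootstrap CI."""
    rgs = frame_rg(ensemble, burn_in, weights)
    if rgs.size < 2:
        raise ValueError("need at least two post-burn-in frames")
    med, lo, hi = bootstrap_median_ci(rgs, n_boot=n_boot, seed=seed)
    return RgSummary(
        median=med, ci_low=lo, ci_high=hi, n_boot=n_boot,
        percentiles=(2.5, 97.5), n_frames=int(rgs.size), seed=seed,
    )


@dataclass
class DistanceDistributions:
    """Per-frame centroid distances for each unordered nucleosome pair."""

    distances: dict  # (label_i, label_j) -> np.ndarray over frames
    medians: dict    # (label_i, label_j) -> float

    def get(self, a, b) -> np.ndarray:
        return self.distances[(a, b)] if (a, b) in self.distances else self.distances[(b, a)]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (a, b), d in self.distances.items():
            for frame, val in enumerate(d):
                rows.append((a, b, frame, val))
        return pd.DataFrame(rows, columns=["group_a", "group_b", "frame", "distance"])


def internucleosome_distances(
    ensemble: TrajectoryEnsemble, groups: dict = None, burn_in: int = None
) -> DistanceDistributions:
    """Pairwise centroid-to-centroid distances between nucleosome groups.

    For every unordered pair of groups, computes the Euclidean distance
    between the group centroids in each post-burn-in frame; the full
    per-frame distributions and their medians are returned.
    """
    groups = ensemble.groups if groups is None else groups
    if len(groups) < 2:
        raise ValueError("need at least two nucleosome groups")
    frames = ensemble.production(burn_in)
    centroids = {
        label: frames[:, np.asarray(idx, dtype=int), :].mean(axis=1)
        for label, idx in groups.items()
    }
    distances, medians = {}, {}
    for a, b in combinations(groups, 2):
        d = np.linalg.norm(centroids[a] - centroids[b], axis=1)
        distances[(a, b)] = d
        medians[(a, b)] = float(np.median(d))
    return DistanceDistributions(distances, medians)


def positional_drift(series, reference: float = None):
    """RMS and max absolute deviation of a scalar series from a reference.

    ``reference`` defaults to the first value; measures how robustly a
    nucleosome position is maintained along a trajectory.
    """
    series = np.asarray(series, dtype=float)
    if series.size < 1:
        raise ValueError("need at least one frame")
    ref = series[0] if reference is None else float(reference)
    dev = series - ref
    return float(np.sqrt((dev ** 2).mean())), float(np.abs(dev).max())


def read_trajectory_tsv(path, burn_in: int = 0, groups: dict = None) -> TrajectoryEnsemble:
    """Read a plain-table trajectory with columns frame, bead, x, y, z."""
    df = pd.read_csv(path, sep="\t")
    required = {"frame", "bead", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValueError(f"trajectory table must have columns {sorted(required)}")
    frames = np.sort(df["frame"].unique())
    beads = np.sort(df["bead"].unique())
    wide = df.set_index(["frame", "bead"]).sort_index()
    coords = wide[["x", "y", "z"]].to_numpy().reshape(frames.size, beads.size, 3)
    return TrajectoryEnsemble(coords, burn_in=burn_in, groups=groups or {})


def read_trajectory_xyz(path, burn_in: int = 0, groups: dict = None) -> TrajectoryEnsemble:
    """Read a multi-frame XYZ file (count line, comment line, atom lines)."""
    frames = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header.strip():
                break
            n = int(header)
            fh.readline()  # comment
            frame = np.array(
                [fh.readline().split()[1:4] for _ in range(n)], dtype=float
            )
            frames.append(frame)
    if not frames:
        raise ValueError(f"no frames found in {path}")
    return TrajectoryEnsemble(np.stack(frames), burn_in=burn_in, groups=groups or {})
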