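"""Simulation studies that validate the analysis chain end to end.

Each function runs a self-contained in-silico experiment built from the
synthetic digestion generator: linker-parameter recovery, modal-length
recovery, repositioning power and null calibration, bootstrap-CI
coverage, and the SAM round-trip check.  They are used both by the test
suite and by the results-reproduction script.
"""

from __future__ import annotations

import tempfile
from dataclasses import replace
from pathlib import Path

import numpy as np

from .core import TargetLocus
from .fragmap import filter_by_length, modal_length
from .io import read_fragments
from .positioning import call_positions, dyad_density, linker_spacings
from .repositioning import DEFAULT_WINDOWS, repositioning_ratio
from .synthetic import DigestParams, build_array_config, sample_fragments, write_alignments
from .trajstats import bootstrap_median_ci

__all__ = [
    "recover_linkers",
    "modal_length_recovery",
    "simulate_repositioning_experiment",
    "repositioning_power",
    "null_calibration",
    "bootstrap_median_coverage",
    "sam_roundtrip_mismatches",
]


def recover_linkers(condition: str, n_fragments: int = 20000, seed: int = 0,
                    edge_jitter_sd: float = 5.0, fuzziness_sd: float = 5.0):
    """Sample a condition and call its linkers back from the fragments.

    Returns ``(called_linkers, true_linkers)`` using the full analysis
    chain: length filter 100-150, center density (10-bp bandwidth), peak
    calling, edge-to-edge linker conversion with 147-bp footprints.
    """
    config = build_array_config(condition, fuzziness_sd=fuzziness_sd)
    digest = DigestParams(n_fragments=n_fragments, edge_jitter_sd=edge_jitter_sd,
                          seed=seed)
    fragments = filter_by_length(sample_fragments(config, digest), 100, 150)
    call = call_positions(dyad_density(fragments, 10.0), k=len(config.nucleosomes),
                          min_separation=120.0)
    return linker_spacings(call.dyads), config.linkers()


def modal_length_recovery(n_per_nucleosome: int = 5000, footprint_sd: float = 4.0,
                          seed: int = 0):
    """Modal protected length of the warm +1 (octasome) and +2 (hexasome).

    Draws ``n_per_nucleosome`` fragments from each particle alone with
    only the protected-length spread active (no edge jitter), and takes
    the most frequent fragment length; expected modes are 140 and 110 bp.
    """
    warm = build_array_config("warm", background_rate=0.0)
    modes = {}
    for i, label in ((1, "+1"), (2, "+2")):
        spec = replace(warm.nucleosomes[i], footprint_sd=footprint_sd)
        solo = replace(warm, nucleosomes=(spec,), background_rate=0.0)
        digest = DigestParams(n_fragments=n_per_nucleosome, edge_jitter_sd=0.0,
                              seed=seed + i)
        fs = sample_fragments(solo, digest)
        lo, hi = solo.region
        modes[label] = modal_length(fs, (fs.tss + lo, fs.tss + hi))
    return modes["+1"], modes["+2"]


def simulate_repositioning_experiment(seed: int, cold_condition: str = "cold",
                                      n_fragments: int = 20000, n_rep: int = 3):
    """One cold-vs-warm experiment: sample replicates, test repositioning."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=2 * n_rep)
    warm_cfg = build_array_config("warm")
    cold_cfg = build_array_config(cold_condition)
    warm = [
        sample_fragments(warm_cfg, DigestParams(n_fragments=n_fragments, seed=int(s)),
                         label=f"warm_r{i+1}")
        for i, s in enumerate(seeds[:n_rep])
    ]
    cold = [
        sample_fragments(cold_cfg, DigestParams(n_fragments=n_fragments, seed=int(s)),
                         label=f"cold_r{i+1}")
        for i, s in enumerate(seeds[n_rep:])
    ]
    warm = [filter_by_length(w, 100, 150) for w in warm]
    cold = [filter_by_length(c, 100, 150) for c in cold]
    return repositioning_ratio(cold, warm, DEFAULT_WINDOWS)


def repositioning_power(n_experiments: int = 200, seed: int = 0,
                        n_fragments: int = 20000, n_rep: int = 3) -> float:
    """Fraction of cold-vs-warm experiments detected.

    Detection = every normalized cold replicate > 1 and two-tailed
    p < 0.05.  The cold +1 dyad is 51 bp more TSS-proximal than warm by
    construction, so power should be near 1.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_experiments):
        res = simulate_repositioning_experiment(int(rng.integers(0, 2**31 - 1)),
                                                n_fragments=n_fragments, n_rep=n_rep)
        if res.p < 0.05 and np.all(res.normalized > 1):
            hits += 1
    return hits / n_experiments


def null_calibration(n_experiments: int = 1000, seed: int = 0,
                     n_fragments: int = 20000, n_rep: int = 3) -> float:
    """Rejection rate when both groups are drawn from the warm generator."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_experiments):
        res = simulate_repositioning_experiment(int(rng.integers(0, 2**31 - 1)),
                                                cold_condition="warm",
                                                n_fragments=n_fragments, n_rep=n_rep)
        if res.p < 0.05:
            rejections += 1
    return rejections / n_experiments


def bootstrap_median_coverage(n_datasets: int = 500, n: int = 200, mu: float = 10.0,
                              sigma: float = 1.0, n_boot: int = 10000,
                              seed: int = 0) -> float:
    """Coverage of the percentile-bootstrap median CI for Normal data.

    Fraction of simulated Normal(mu, sigma) datasets of size ``n`` whose
    95% bootstrap CI for the median covers mu (the true median).
    """
    rng = np.random.default_rng(seed)
    covered = 0
    for _ in range(n_datasets):
        values = rng.normal(mu, sigma, n)
        _, lo, hi = bootstrap_median_ci(values, n_boot=n_boot,
                                        seed=int(rng.integers(0, 2**31 - 1)))
        covered += lo <= mu <= hi
    return covered / n_datasets


def sam_roundtrip_mismatches(n_fragments: int = 10000, seed: int = 0,
                             strand: str = "-") -> int:
    """Generator -> SAM -> reader round trip; number of differing intervals."""
    tss = 12000
    config = build_array_config("warm", tss=tss, strand=strand, chrom="chrSim")
    fs = sample_fragments(config, DigestParams(n_fragments=n_fragments, seed=seed))
    locus = TargetLocus("chrSim", 9000, 15000, strand, "SIM0001", "SIMLOC",
                        tss_override=tss)
    with tempfile.TemporaryDirectory() as d:
        sam = Path(d) / "roundtrip.sam"
        write_alignments(fs, sam, "SAM", reference_length=20000)
        back = read_fragments(sam, locus)
    if len(back) != len(fs):
        return abs(len(back) - len(fs)) + int(
            np.sum(back.starts[: len(fs)] != fs.starts[: len(back)])
        )
    return int(np.sum((back.starts != fs.starts) | (back.ends != fs.ends)))
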