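"""End-to-end orchestration: config, demo generation, run manifest.

A run is described by a TOML config (paths, sample sheet, analysis
parameters).  ``run_pipeline`` executes, per locus: fragment
reconstitution, length filtering, V-map, pooled center profile,
position/linker calling, the cold-vs-warm repositioning statistic, and
control-normalized occupancy; every stage's outputs are TSV/JSON and a
manifest records all parameters, seeds and dropped-record counts,
including the interpretation choices in force (MAPQ rule, window
coordinates, linker definition).
"""

from __future__ import annotations

import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .core import TargetLocus
from .fragmap import build_vmap, center_profile, filter_by_length
from .io import load_targets, packaged_targets, read_fragments
from .positioning import call_positions, dyad_density, linker_spacings
from .repositioning import WindowPair, repositioning_ratio, window_count
from .synthetic import DigestParams, build_array_config, sample_fragments, write_alignments

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "make_demo"]


@dataclass
class RunConfig:
    """Validated run configuration (paths, sample sheet, parameters)."""

    targets_path: Path = None  # None -> packaged bait-order table
    outdir: Path = Path("nucleodyn_out")
    samples: list = field(default_factory=list)  # dicts: genotype/treatment/replicate/alignments
    loci: list = field(default_factory=list)     # gene names to analyse
    length_lo: int = 100
    length_hi: int = 150
    mapq_min: int = 10
    pool_n: int = 20000
    bandwidth: float = 10.0
    min_separation: float = 120.0
    k: int = 4
    proximal: tuple = (10, 120)
    distal: tuple = (130, 240)
    n_boot: int = 10000
    seed: int = 0
    tss_overrides: dict = field(default_factory=dict)  # locus name -> genomic TSS

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        paths = raw.get("paths", {})
        analysis = raw.get("analysis", {})
        cfg = cls(
            targets_path=Path(paths["targets"]) if "targets" in paths else None,
            outdir=Path(paths.get("outdir", "nucleodyn_out")),
            samples=raw.get("samples", []),
            loci=analysis.get("loci", []),
            length_lo=int(analysis.get("length_lo", 100)),
            length_hi=int(analysis.get("length_hi", 150)),
            mapq_min=int(analysis.get("mapq_min", 10)),
            pool_n=int(analysis.get("pool_n", 20000)),
            bandwidth=float(analysis.get("bandwidth", 10.0)),
            min_separation=float(analysis.get("min_separation", 120.0)),
            k=int(analysis.get("k", 4)),
            proximal=tuple(analysis.get("proximal", (10, 120))),
            distal=tuple(analysis.get("distal", (130, 240))),
            n_boot=int(analysis.get("n_boot", 10000)),
            seed=int(analysis.get("seed", 0)),
            tss_overrides={k: int(v) for k, v in analysis.get("tss", {}).items()},
        )
        cfg.validate(base=Path(path).parent)
        return cfg

    def validate(self, base: Path = Path(".")) -> None:
        if not self.samples:
            raise ValueError("config lists no samples")
        for s in self.samples:
            for key in ("genotype", "treatment", "replicate", "alignments"):
                if key not in s:
                    raise ValueError(f"sample entry missing {key!r}: {s}")
            p = Path(s["alignments"])
            if not p.is_absolute():
                p = base / p
            if not p.exists():
                raise FileNotFoundError(f"alignments file not found: {p}")
            s["alignments"] = str(p)
        if self.targets_path is not None and not Path(self.targets_path).exists():
            raise FileNotFoundError(f"targets table not found: {self.targets_path}")


def _locus_by_name(targets, name: str) -> TargetLocus:
    for t in targets:
        if t.gene_name == name or t.locus_id == name:
            return t
    raise KeyError(f"locus {name!r} not in target table")


def run_pipeline(config: RunConfig) -> dict:
    """Run the full per-locus analysis; returns the manifest dict.

    Partial failures are isolated per locus: remaining loci still run,
    the manifest lists the error, and the caller decides the exit code.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    targets = (
        load_targets(config.targets_path) if config.targets_path else packaged_targets()
    )
    windows = WindowPair(tuple(config.proximal), tuple(config.distal))
    manifest = {
        "version": __version__,
        "parameters": {
            "length_band": [config.length_lo, config.length_hi],
            "mapq_min": config.mapq_min,
            "pool_n": config.pool_n,
            "bandwidth_bp": config.bandwidth,
            "min_separation_bp": config.min_separation,
            "k": config.k,
            "proximal_window": list(windows.proximal),
            "distal_window": list(windows.distal),
            "n_boot": config.n_boot,
            "seed": config.seed,
        },
        "interpretations": {
            "quality_filter": f"MAPQ < {config.mapq_min} dropped (per-locus split-step filter)",
            "windows": "TSS-relative half-open intervals; membership by fragment center",
            "linkers": "edge-to-edge spacing assuming canonical 147-bp footprints",
            "length_bounds": "inclusive",
            "center": "start + floor(length/2)",
        },
        "loci": {},
        "errors": {},
    }

    for name in config.loci:
        try:
            manifest["loci"][name] = _run_locus(config, targets, name, windows, outdir)
        except Exception as exc:  # isolate per-locus failures
            log.exception("locus %s failed", name)
            manifest["errors"][name] = str(exc)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _run_locus(config, targets, name, windows, outdir) -> dict:
    locus = _locus_by_name(targets, name)
    if name in config.tss_overrides:
        from dataclasses import replace as _dc_replace

        locus = _dc_replace(locus, tss_override=config.tss_overrides[name])
    ldir = outdir / name
    ldir.mkdir(parents=True, exist_ok=True)
    entry = {"locus": {
        "chrom": locus.chrom, "start": locus.start, "end": locus.end,
        "strand": locus.strand, "locus_id": locus.locus_id,
        "gene_name": locus.gene_name, "tss": locus.tss,
    }, "samples": {}}

    by_group = {}
    for s in config.samples:
        label = f"{s['genotype']}_{s['treatment']}_r{s['replicate']}"
        fs = read_fragments(s["alignments"], locus, mapq_min=config.mapq_min, label=label)
        filt = filter_by_length(fs, config.length_lo, config.length_hi)
        entry["samples"][label] = {
            "fragments_total": len(fs),
            "fragments_in_band": len(filt),
            "dropped": fs.dropped,
            "proximal_count": window_count(filt, windows.proximal),
            "distal_count": window_count(filt, windows.distal),
        }
        by_group.setdefault((s["genotype"], s["treatment"]), []).append(filt)

    for (genotype, treatment), reps in sorted(by_group.items()):
        tag = f"{genotype}_{treatment}"
        vmap = build_vmap(reps)
        vmap.to_tsv(ldir / f"vmap_{tag}.tsv")
        prof = center_profile(reps, tss=locus.tss, pool_n=config.pool_n, seed=config.seed)
        prof.to_frame().to_csv(ldir / f"centers_{tag}.tsv", sep="\t", index=False)
        pooled = reps[0]
        for r in reps[1:]:
            pooled = pooled.replace(
                np.concatenate([pooled.starts, r.starts]),
                np.concatenate([pooled.ends, r.ends]),
            )
        try:
            call = call_positions(
                dyad_density(pooled, config.bandwidth), config.k, config.min_separation
            )
            dyads_rel = (call.dyads - locus.tss).tolist()
            linkers = linker_spacings(call.dyads)
            with open(ldir / f"positions_{tag}.tsv", "w") as fh:
                fh.write("dyad_tss_relative\tdensity\n")
                for d, v in zip(dyads_rel, call.densities):
                    fh.write(f"{d}\t{v:.6g}\n")
            entry.setdefault("positions", {})[tag] = {
                "dyads_tss_relative": dyads_rel, "linkers_bp": linkers,
            }
        except ValueError as exc:
            entry.setdefault("positions", {})[tag] = {"error": str(exc)}

    # repositioning: cold vs warm within each genotype
    genotypes = sorted({g for g, _ in by_group})
    for g in genotypes:
        cold = by_group.get((g, "cold"))
        warm = by_group.get((g, "warm"))
        if not cold or not warm or len(cold) < 2 or len(warm) < 2:
            continue
        res = repositioning_ratio(cold, warm, windows)
        entry.setdefault("repositioning", {})[g] = {
            "warm_ratios": res.warm_ratios.tolist(),
            "cold_ratios": res.cold_ratios.tolist(),
            "normalized": res.normalized.tolist(),
            "t": res.t, "df": res.df, "p": res.p,
            "windows": {"proximal": list(windows.proximal),
                        "distal": list(windows.distal)},
        }
        with open(ldir / f"repositioning_{g}.json", "w") as fh:
            json.dump(entry["repositioning"][g], fh, indent=2)
    return entry


def make_demo(outdir, seed: int = 0, n_fragments: int = 20000,
              n_warm: int = 3, n_cold: int = 3) -> Path:
    """Write a self-contained synthetic demo dataset and its TOML config.

    Simulates warm and cold replicate libraries over a synthetic FLC-like
    locus (minus strand), writes them as SAM, and returns the path of a
    config runnable with :func:`run_pipeline`.
    """
    outdir = Path(outdir)
    (outdir / "alignments").mkdir(parents=True, exist_ok=True)
    tss = 12000  # 0-based genomic TSS, interior to the capture region
    chrom_len = 20000
    samples = []
    targets_path = outdir / "targets.tsv"
    # minus-strand demo locus, FLC-like: gene body left of the TSS, the
    # capture region extending past the promoter on the right
    with open(targets_path, "w") as fh:
        fh.write("chromosome\tstart_coordinate\tend_coordinate\tstrand\t"
                 "locus_identifier\tgene_name\n")
        fh.write("chrSim\t10500\t13000\t-\tSIM0001\tSIMLOC\n")
    for treatment, n_rep, seed_off in (("warm", n_warm, 0), ("cold", n_cold, 100)):
        cfg = build_array_config(treatment, tss=tss, strand="-", chrom="chrSim",
                                 locus_name="SIMLOC")
        for rep in range(1, n_rep + 1):
            digest = DigestParams(n_fragments=n_fragments, seed=seed + seed_off + rep)
            fs = sample_fragments(cfg, digest, label=f"WT_{treatment}_r{rep}")
            sam = outdir / "alignments" / f"WT_{treatment}_r{rep}.sam"
            write_alignments(fs, sam, "SAM", reference_length=chrom_len)
            samples.append((treatment, rep, sam))
    config_path = outdir / "demo_config.toml"
    with open(config_path, "w") as fh:
        fh.write(f'[paths]\ntargets = "{targets_path.resolve()}"\n'
                 f'outdir = "{(outdir / "results").resolve()}"\n\n')
        for treatment, rep, sam in samples:
            fh.write('[[samples]]\ngenotype = "WT"\n'
                     f'treatment = "{treatment}"\nreplicate = {rep}\n'
                     f'alignments = "{sam.resolve()}"\n\n')
        fh.write(f'[analysis]\nloci = ["SIMLOC"]\nseed = {seed}\n\n'
                 f'[analysis.tss]\nSIMLOC = {tss}\n')
    return config_path
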