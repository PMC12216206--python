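import numpy as np
import pytest

from nucleodyn.core import FragmentSet, TargetLocus
from nucleodyn.synthetic import (
    ArrayConfig,
    DigestParams,
    NucleosomeSpec,
    build_array_config,
    sample_fragments,
)


@pytest.fixture
def warm_config():
    return build_array_config("warm")


@pytest.fixture
def cold_config():
    return build_array_config("cold")


@pytest.fixture
def zero_noise_octasome():
    """Single octasome, dyad at TSS+145, all spreads zero, no background."""
    spec = NucleosomeSpec("+1", 145, "octasome", 147, footprint_sd=0.0,
                          fuzziness_sd=0.0)
    return ArrayConfig("solo", "chrSim", 0, "+", (spec,), background_rate=0.0)


def zero_noise_condition(condition: str, tss: int = 0, strand: str = "+"):
    """A named condition with every stochastic spread set to zero."""
    from dataclasses import replace

    cfg = build_array_config(condition, tss=tss, strand=strand, fuzziness_sd=0.0,
                             background_rate=0.0)
    nucs = tuple(replace(n, footprint_sd=0.0) for n in cfg.nucleosomes)
    return replace(cfg, nucleosomes=nucs)


@pytest.fixture
def warm_fragments(warm_config):
    return sample_fragments(warm_config, DigestParams(n_fragments=20000, seed=11))


def make_fragset(starts, ends, tss=0, strand="+", label="", name="test"):
    return FragmentSet(name, "chrT", tss, strand, label,
                       np.asarray(starts), np.asarray(ends))


@pytest.fixture
def sim_locus():
    return TargetLocus("chrSim", 9000, 15000, "-", "SIM0001", "SIMLOC",
                       tss_override=12000)
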