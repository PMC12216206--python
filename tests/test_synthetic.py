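"""Generator: array conditions, fragment sampling, trajectory fixtures."""

import numpy as np
import pytest

from nucleodyn.synthetic import (
    ArrayConfig,
    DigestParams,
    NucleosomeSpec,
    build_array_config,
    make_trajectory_fixture,
    sample_fragments,
)
from nucleodyn.trajstats import radius_of_gyration

from conftest import zero_noise_condition


class TestBuildArrayConfig:
    def test_warm_geometry(self):
        """-1 dyad at TSS-145 with a 143-bp linker puts +1 at dyad TSS+145."""
        cfg = build_array_config("warm", anchor=-145)
        plus1 = cfg.nucleosomes[1]
        assert plus1.dyad == 145
        assert plus1.footprint_start == 72  # canonical footprint starts TSS+72
        assert cfg.nucleosomes[0].footprint_end == -71  # -1 ends at TSS-71

    def test_cold_moves_plus1_51bp_toward_tss(self):
        warm = build_array_config("warm")
        cold = build_array_config("cold")
        assert cold.nucleosomes[1].dyad == 94
        assert cold.nucleosomes[1].footprint_start == 21
        assert warm.nucleosomes[1].dyad - cold.nucleosomes[1].dyad == 51

    @pytest.mark.parametrize(
        "condition, linkers",
        [("warm", [143, 1, 21]), ("cold", [92, 34, 39]), ("warm_3nuc", [260, 52]),
         ("vrn1_cold", [92, 34, 39])],
    )
    def test_linkers(self, condition, linkers):
        assert build_array_config(condition).linkers() == linkers

    def test_warm_oldn_footprints(self):
        """Warm +1 is a 140-bp octasome, +2 a 110-bp hexasome (OLDN-like)."""
        cfg = build_array_config("warm")
        assert (cfg.nucleosomes[1].kind, cfg.nucleosomes[1].footprint_modal) == ("octasome", 140)
        assert (cfg.nucleosomes[2].kind, cfg.nucleosomes[2].footprint_modal) == ("hexasome", 110)

    def test_warm_3nuc_has_three_particles(self):
        assert len(build_array_config("warm_3nuc").nucleosomes) == 3

    def test_vrn1_cold_triples_plus1_plus2_fuzziness(self):
        cold = build_array_config("cold")
        vrn1 = build_array_config("vrn1_cold")
        for i in (1, 2):
            assert vrn1.nucleosomes[i].fuzziness_sd == 3 * cold.nucleosomes[i].fuzziness_sd
        assert vrn1.nucleosomes[0].fuzziness_sd == cold.nucleosomes[0].fuzziness_sd

    def test_unknown_condition_lists_valid_set(self):
        with pytest.raises(ValueError, match="cold"):
            build_array_config("tropical")

    def test_invariants_rejected(self):
        spec = NucleosomeSpec("+1", 0)
        with pytest.raises(ValueError, match="increasing"):
            ArrayConfig("x", "c", 0, "+", (spec, spec))
        with pytest.raises(ValueError, match="footprint_modal"):
            NucleosomeSpec("+1", 0, footprint_modal=200)
        with pytest.raises(ValueError, match="background_rate"):
            ArrayConfig("x", "c", 0, "+", (spec,), background_rate=1.5)


class TestSampleFragments:
    def test_zero_noise_collapse(self, zero_noise_octasome):
        """All spreads zero: every fragment is the canonical footprint."""
        fs = sample_fragments(zero_noise_octasome,
                              DigestParams(n_fragments=10, edge_jitter_sd=0.0, seed=1))
        assert len(fs) == 10
        assert np.all(fs.starts == 72) and np.all(fs.ends == 219)
        assert np.all(fs.lengths == 147)

    def test_determinism_and_seed_sensitivity(self, warm_config):
        d = DigestParams(n_fragments=2000, seed=42)
        a = sample_fragments(warm_config, d)
        b = sample_fragments(warm_config, d)
        c = sample_fragments(warm_config, DigestParams(n_fragments=2000, seed=43))
        assert np.array_equal(a.starts, b.starts) and np.array_equal(a.ends, b.ends)
        assert not np.array_equal(a.starts, c.starts)

    def test_fragments_near_dyads_without_background(self):
        cfg = build_array_config("warm", background_rate=0.0)
        fs = sample_fragments(cfg, DigestParams(n_fragments=5000, seed=7))
        dyads = cfg.dyads
        max_fuzz = max(n.fuzziness_sd for n in cfg.nucleosomes)
        reach = max_fuzz * 6 + 200 // 2 + 30
        assert np.all(np.min(np.abs(fs.centers[:, None] - dyads[None, :]), axis=1) < reach)

    def test_dyad_mean_recovery_zero_jitter(self):
        """Empirical dyad mean per nucleosome within 1 bp at n=20,000."""
        cfg = build_array_config("warm", background_rate=0.0)
        fs = sample_fragments(
            cfg, DigestParams(n_fragments=20000, edge_jitter_sd=0.0, seed=5)
        )
        for spec in cfg.nucleosomes:
            sel = np.abs(fs.centers - spec.dyad) < 70
            # center = dyad + (L//2 - ceil(L/2) drift) is symmetric here
            assert abs(fs.centers[sel].mean() - spec.dyad) < 1.0

    def test_mixture_weights_recovered(self):
        cfg = build_array_config("cold", background_rate=0.0)
        n = 20000
        fs = sample_fragments(cfg, DigestParams(n_fragments=n, seed=9))
        p = 1 / len(cfg.nucleosomes)
        tol = 3 * np.sqrt(p * (1 - p) / n)
        for spec in cfg.nucleosomes:
            share = np.mean(np.abs(fs.centers - spec.dyad) < 70)
            assert abs(share - p) < tol + 0.01  # +1% for boundary/jitter leakage

    def test_degenerate_config_rejected(self):
        spec = NucleosomeSpec("+1", 0, weight=0.0)
        cfg = ArrayConfig("x", "c", 0, "+", (spec,), background_rate=0.0)
        with pytest.raises(ValueError, match="degenerate"):
            sample_fragments(cfg, DigestParams(n_fragments=10, seed=0))


class TestTrajectoryFixtures:
    def test_line_two_beads(self):
        ens = make_trajectory_fixture("line", n=2, spacing=2.0)
        assert radius_of_gyration(ens.coords[0]) == pytest.approx(1.0)

    def test_single_bead_rg_zero(self):
        ens = make_trajectory_fixture("line", n=1, spacing=2.0)
        assert radius_of_gyration(ens.coords[0]) == 0.0

    def test_square_rg(self):
        ens = make_trajectory_fixture("square", side=2.0)
        assert radius_of_gyration(ens.coords[0]) == pytest.approx(np.sqrt(2), abs=1e-12)

    def test_gaussian_cloud_shape_and_seeding(self):
        a = make_trajectory_fixture("gaussian_cloud", n=7, n_frames=5, seed=3)
        b = make_trajectory_fixture("gaussian_cloud", n=7, n_frames=5, seed=3)
        assert a.coords.shape == (5, 7, 3)
        assert np.array_equal(a.coords, b.coords)

    def test_two_state_alternates(self):
        ens = make_trajectory_fixture("two_state", d_a=5.0, d_b=15.0, n_frames=4)
        seps = np.linalg.norm(ens.coords[:, 1] - ens.coords[:, 0], axis=1)
        assert seps.tolist() == [5.0, 15.0, 5.0, 15.0]

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            make_trajectory_fixture("line", n=0)
        with pytest.raises(ValueError, match="kind"):
            make_trajectory_fixture("helix")


def test_zero_noise_condition_reproduces_design_exactly():
    """Zero-noise warm sampling yields only the four designed footprints."""
    cfg = zero_noise_condition("warm")
    fs = sample_fragments(cfg, DigestParams(n_fragments=400, edge_jitter_sd=0.0, seed=2))
    species = set(zip(fs.starts.tolist(), fs.ends.tolist()))
    expected = set()
    for n in cfg.nucleosomes:
        start = n.dyad - n.footprint_modal // 2
        expected.add((start, start + n.footprint_modal))
    assert species == expected
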