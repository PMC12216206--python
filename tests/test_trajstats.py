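"""Rg, bootstrap CI of the median, inter-nucleosome distances, drift."""

import numpy as np
import pytest

from nucleodyn.synthetic import make_trajectory_fixture
from nucleodyn.trajstats import (
    TrajectoryEnsemble,
    bootstrap_median_ci,
    frame_rg,
    internucleosome_distances,
    positional_drift,
    radius_of_gyration,
    read_trajectory_tsv,
    read_trajectory_xyz,
    rg_summary,
)


class TestRadiusOfGyration:
    def test_single_bead_zero(self):
        assert radius_of_gyration([[1.0, 2.0, 3.0]]) == 0.0

    def test_two_beads_two_apart(self):
        assert radius_of_gyration([[0, 0, 0], [2, 0, 0]]) == pytest.approx(1.0)

    def test_square_side_two(self):
        ens = make_trajectory_fixture("square", side=2.0)
        assert radius_of_gyration(ens.coords[0]) == pytest.approx(np.sqrt(2), abs=1e-9)

    @pytest.mark.parametrize("n", [2, 3, 10])
    def test_line_closed_form(self, n):
        d = 1.7
        ens = make_trajectory_fixture("line", n=n, spacing=d)
        expected = np.sqrt(d * d * (n * n - 1) / 12)
        assert radius_of_gyration(ens.coords[0]) == pytest.approx(expected, abs=1e-9)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(0)
        coords = rng.normal(size=(20, 3))
        base = radius_of_gyration(coords)
        for _ in range(5):
            # random rotation via QR, plus translation
            q, _r = np.linalg.qr(rng.normal(size=(3, 3)))
            moved = coords @ q + rng.normal(size=3) * 50
            assert radius_of_gyration(moved) == pytest.approx(base, abs=1e-9)

    def test_weights(self):
        # all mass on one bead: Rg -> 0
        assert radius_of_gyration([[0, 0, 0], [5, 0, 0]], weights=[1, 0]) == 0.0
        with pytest.raises(ValueError, match="weight"):
            radius_of_gyration([[0, 0, 0]], weights=[0.0])


class TestBootstrapCI:
    def test_constant_data_zero_width(self):
        ens = make_trajectory_fixture("square", side=2.0, n_frames=50)
        summ = rg_summary(ens, n_boot=500, seed=1)
        c = np.sqrt(2)
        assert summ.median == pytest.approx(c)
        assert summ.ci_low == pytest.approx(c) and summ.ci_high == pytest.approx(c)

    def test_ci_ordering_and_bounds(self):
        rng = np.random.default_rng(2)
        values = rng.normal(10, 1, 300)
        med, lo, hi = bootstrap_median_ci(values, n_boot=2000, seed=3)
        assert lo <= med <= hi
        assert values.min() <= lo and hi <= values.max()

    def test_seed_reproducibility_and_stability(self):
        ens = make_trajectory_fixture("gaussian_cloud", n=10, n_frames=500, seed=4)
        a = rg_summary(ens, n_boot=2000, seed=5)
        b = rg_summary(ens, n_boot=2000, seed=5)
        c = rg_summary(ens, n_boot=2000, seed=6)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)
        width = a.ci_high - a.ci_low
        assert abs(c.ci_low - a.ci_low) < width / 2
        assert abs(c.ci_high - a.ci_high) < width / 2

    def test_ci_width_shrinks_with_frames(self):
        widths = []
        for n_frames in (100, 400):
            ens = make_trajectory_fixture("gaussian_cloud", n=10,
                                          n_frames=n_frames, seed=7)
            s = rg_summary(ens, n_boot=2000, seed=8)
            widths.append(s.ci_high - s.ci_low)
        # ~1/sqrt(n): quadrupling frames should roughly halve the width
        assert widths[1] < widths[0] * 0.75

    def test_small_nboot_warns_tiny_rejected(self, caplog):
        values = np.arange(10.0)
        with caplog.at_level("WARNING"):
            bootstrap_median_ci(values, n_boot=50, seed=0)
        assert "unstable" in caplog.text
        with pytest.raises(ValueError):
            bootstrap_median_ci(values, n_boot=1)


class TestInterNucleosomeDistances:
    def test_static_pair(self):
        coords = np.zeros((5, 2, 3))
        coords[:, 1, 0] = 5.0
        ens = TrajectoryEnsemble(coords, groups={"a": [0], "b": [1]})
        dd = internucleosome_distances(ens)
        assert np.allclose(dd.distances[("a", "b")], 5.0)
        assert dd.medians[("a", "b")] == 5.0

    def test_symmetry_accessor(self):
        ens = make_trajectory_fixture("two_state", d_a=5, d_b=15, n_frames=6)
        dd = internucleosome_distances(ens)
        assert np.array_equal(dd.get("n1", "n2"), dd.get("n2", "n1"))

    def test_two_state_bimodal_median(self):
        ens = make_trajectory_fixture("two_state", d_a=5.0, d_b=15.0, n_frames=100)
        dd = internucleosome_distances(ens)
        d = dd.distances[("n1", "n2")]
        assert set(np.unique(d)) == {5.0, 15.0}
        assert dd.medians[("n1", "n2")] == pytest.approx(10.0)

    def test_group_centroids_used(self):
        coords = np.zeros((3, 4, 3))
        coords[:, 1, 0] = 2.0   # group a beads at x=0 and 2 -> centroid 1
        coords[:, 2, 0] = 10.0
        coords[:, 3, 0] = 12.0  # group b centroid 11
        ens = TrajectoryEnsemble(coords, groups={"a": [0, 1], "b": [2, 3]})
        dd = internucleosome_distances(ens)
        assert np.allclose(dd.distances[("a", "b")], 10.0)

    def test_invalid_groups(self):
        coords = np.zeros((2, 2, 3))
        with pytest.raises(ValueError, match="two"):
            internucleosome_distances(TrajectoryEnsemble(coords, groups={"a": [0]}))
        with pytest.raises(ValueError, match="empty"):
            TrajectoryEnsemble(coords, groups={"a": [0], "b": []})
        with pytest.raises(ValueError, match="disjoint"):
            TrajectoryEnsemble(coords, groups={"a": [0], "b": [0]})


class TestPositionalDrift:
    def test_constant_series(self):
        assert positional_drift([3.0, 3.0, 3.0]) == (0.0, 0.0)

    def test_closed_form(self):
        rms, peak = positional_drift([0.0, 3.0, 4.0], reference=0.0)
        assert rms == pytest.approx(np.sqrt(25 / 3), abs=1e-12)
        assert peak == 4.0

    def test_translation_invariance(self):
        series = np.array([0.0, 3.0, 4.0])
        assert positional_drift(series + 7, reference=7.0) == positional_drift(series, 0.0)


class TestBurnIn:
    def test_burn_in_discards_frames(self):
        coords = np.zeros((10, 2, 3))
        coords[:, 1, 0] = np.arange(10)  # Rg grows with frame index
        ens = TrajectoryEnsemble(coords, burn_in=4)
        assert frame_rg(ens).size == 6
        assert frame_rg(ens, burn_in=0).size == 10

    def test_monotone_frame_count(self):
        ens = make_trajectory_fixture("gaussian_cloud", n=4, n_frames=20, seed=1)
        counts = [frame_rg(ens, burn_in=b).size for b in range(0, 19, 3)]
        assert counts == sorted(counts, reverse=True)

    def test_invalid_burn_in(self):
        coords = np.zeros((5, 1, 3))
        with pytest.raises(ValueError):
            TrajectoryEnsemble(coords, burn_in=5)


class TestReaders:
    def test_tsv_roundtrip(self, tmp_path):
        import pandas as pd

        ens = make_trajectory_fixture("gaussian_cloud", n=3, n_frames=4, seed=9)
        rows = []
        for f in range(4):
            for b in range(3):
                rows.append((f, b, *ens.coords[f, b]))
        df = pd.DataFrame(rows, columns=["frame", "bead", "x", "y", "z"])
        p = tmp_path / "traj.tsv"
        df.to_csv(p, sep="\t", index=False)
        back = read_trajectory_tsv(p)
        assert np.allclose(back.coords, ens.coords)

    def test_xyz_roundtrip(self, tmp_path):
        ens = make_trajectory_fixture("gaussian_cloud", n=3, n_frames=2, seed=10)
        p = tmp_path / "traj.xyz"
        with open(p, "w") as fh:
            for f in range(2):
                fh.write("3\nframe\n")
                for b in range(3):
                    x, y, z = ens.coords[f, b]
                    fh.write(f"C {x:.8f} {y:.8f} {z:.8f}\n")
        back = read_trajectory_xyz(p)
        assert back.coords.shape == (2, 3, 3)
        assert np.allclose(back.coords, ens.coords, atol=1e-7)
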