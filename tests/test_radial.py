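"""Radial profiling: center estimation, binning oracle, averaging,
normalization, dot summaries, boundary recovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import micropattern as mp
from conftest import brute_force_profile


def _geometry(center, radius):
    return mp.ColonyGeometry(center_um=center, fitted_radius_um=radius)


class TestEstimateCenter:
    def test_symmetric_disc_center_exact(self, disc_mask):
        geom = mp.estimate_center(disc_mask)
        assert geom.center_um[0] == pytest.approx(128.0, abs=2.0)
        assert geom.center_um[1] == pytest.approx(128.0, abs=2.0)
        assert geom.fitted_radius_um == pytest.approx(100.0, rel=0.05)

    def test_missing_wedge_small_shift(self, disc_mask):
        prob = disc_mask.probability.copy()
        n = prob.shape[1]
        xs = (np.arange(n) + 0.5) * 2.0 - 128.0
        theta = np.arctan2(xs[:, None], xs[None, :])
        wedge = (theta >= 0) & (theta < 2 * np.pi * 0.10)  # 10% angular wedge
        prob[:, wedge] = 0.0
        cut = mp.NuclearMask(prob, voxel_spacing_um=disc_mask.voxel_spacing_um)
        geom = mp.estimate_center(cut)
        # oracle: exact centroid of the modified mask
        zc, yc, xc = np.nonzero(cut.binary)
        ex = ((xc + 0.5) * 2.0).mean()
        ey = ((yc + 0.5) * 2.0).mean()
        assert geom.center_um[0] == pytest.approx(ex, abs=1e-6)
        assert geom.center_um[1] == pytest.approx(ey, abs=1e-6)
        # analytic shift for a deleted sector of fraction f: f·d/(1−f),
        # where d = 4R·sin(α/2)/(3α) is the sector centroid distance
        f, alpha, radius = 0.10, 2 * np.pi * 0.10, 100.0
        d = 4 * radius * np.sin(alpha / 2) / (3 * alpha)
        shift = np.hypot(geom.center_um[0] - 128.0, geom.center_um[1] - 128.0)
        assert shift == pytest.approx(f * d / (1 - f), rel=0.05)

    def test_empty_mask_errors(self):
        empty = mp.NuclearMask(np.zeros((2, 8, 8)), voxel_spacing_um=(1, 1, 1))
        with pytest.raises(mp.DegenerateImageError):
            mp.estimate_center(empty)

    def test_fitted_radius_within_15pct_of_nominal(self, noisy_mask):
        geom = mp.estimate_center(noisy_mask, nominal_radius_um=250.0)
        assert abs(geom.fitted_radius_um - 250.0) / 250.0 < 0.15


class TestRadialProfile:
    def test_three_voxel_enumeration(self):
        data = np.zeros((1, 1, 1, 40), dtype=np.float32)
        prob = np.zeros((1, 1, 40))
        # voxel centers at x = (i + 0.5); center at x=0, y=0.5 -> radius = x
        for x_idx, val in ((4, 10.0), (14, 20.0), (24, 30.0)):
            data[0, 0, 0, x_idx] = val
            prob[0, 0, x_idx] = 1.0
        grid = mp.VoxelGrid(data, ["c"], (1.0, 1.0, 1.0))
        mask = mp.NuclearMask(prob, voxel_spacing_um=(1, 1, 1))
        prof = mp.radial_profile(grid, mask, _geometry((0.0, 0.5), 30.0),
                                 bin_width_um=10.0)
        assert list(prof.n_voxels) == [1, 1, 1]
        assert np.allclose(prof.means["c"], [10.0, 20.0, 30.0])

    def test_uniform_channel_constant_bins(self, noise_free_colony, noise_free_mask):
        _, grid, _ = noise_free_colony
        geom = mp.estimate_center(noise_free_mask)
        # a truly constant channel: every populated bin mean equals c exactly
        const = grid.with_intensities(
            np.full_like(grid.intensities, 42.0, dtype=np.float32))
        prof = mp.radial_profile(const, noise_free_mask, geom)
        populated = prof.n_voxels > 0
        assert np.all(prof.means["m"][populated] == 42.0)
        # a uniform painted marker: flat profile (blob shoulders lower the
        # per-voxel mean uniformly, so bins agree with each other)
        prof2 = mp.radial_profile(grid, noise_free_mask, geom)
        vals = prof2.means["m"][prof2.n_voxels >= 100]
        assert np.std(vals) / np.mean(vals) < 0.02

    def test_empty_mask_all_bins_undefined(self):
        grid = mp.VoxelGrid(np.ones((1, 1, 8, 8), dtype=np.float32), ["c"], (1, 1, 1))
        mask = mp.NuclearMask(np.zeros((1, 8, 8)), voxel_spacing_um=(1, 1, 1))
        prof = mp.radial_profile(grid, mask, _geometry((4.0, 4.0), 4.0), 1.0)
        assert np.all(prof.n_voxels == 0)
        assert np.all(np.isnan(prof.means["c"]))

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            nz, ny, nx = rng.integers(1, 4), rng.integers(6, 14), rng.integers(6, 14)
            grid = mp.VoxelGrid(rng.random((2, nz, ny, nx)).astype(np.float32) * 100,
                                ["a", "b"], (1.5, 1.5, 1.0))
            mask = mp.NuclearMask(rng.random((nz, ny, nx)),
                                  voxel_spacing_um=(1.5, 1.5, 1.0))
            center = (float(rng.uniform(0, nx * 1.5)), float(rng.uniform(0, ny * 1.5)))
            radius = float(rng.uniform(4, 12))
            geom = _geometry(center, radius)
            prof = mp.radial_profile(grid, mask, geom, bin_width_um=2.0)
            means, counts = brute_force_profile(grid, mask, center, 2.0, radius)
            assert np.array_equal(prof.n_voxels, counts)
            for ch in ("a", "b"):
                assert np.allclose(prof.means[ch], means[ch],
                                   rtol=1e-9, equal_nan=True)

    def test_voxel_count_conservation(self, noisy_colony, noisy_mask):
        _, grid, _ = noisy_colony
        geom = mp.estimate_center(noisy_mask)
        prof = mp.radial_profile(grid, noisy_mask, geom)
        binary = noisy_mask.binary
        r_map = grid.xy_radius_map_um(geom.center_um)
        zc, yc, xc = np.nonzero(binary)
        expected = int(np.sum(r_map[yc, xc] <= min(geom.fitted_radius_um,
                                                   prof.bin_edges_um[-1])))
        assert int(prof.n_voxels.sum()) == expected

    def test_rotation_invariance(self):
        rng = np.random.default_rng(7)
        n = 32
        data = rng.random((1, 2, n, n)).astype(np.float32)
        prob = (rng.random((2, n, n)) > 0.4).astype(float)
        grid = mp.VoxelGrid(data, ["c"], (1.0, 1.0, 1.0))
        mask = mp.NuclearMask(prob, voxel_spacing_um=(1, 1, 1))
        geom = _geometry((n / 2.0, n / 2.0), n / 2.0)
        prof = mp.radial_profile(grid, mask, geom, 2.0)
        rot_grid = grid.with_intensities(np.rot90(data, axes=(2, 3)).copy())
        rot_mask = mp.NuclearMask(np.rot90(prob, axes=(1, 2)).copy(),
                                  voxel_spacing_um=(1, 1, 1))
        rot = mp.radial_profile(rot_grid, rot_mask, geom, 2.0)
        assert np.array_equal(prof.n_voxels, rot.n_voxels)
        assert np.allclose(prof.means["c"], rot.means["c"],
                           rtol=1e-9, equal_nan=True)

    def test_bin_width_larger_than_radius_rejected(self, disc_mask):
        grid = mp.VoxelGrid(np.ones((1,) + disc_mask.probability.shape, dtype=np.float32),
                            ["c"], disc_mask.voxel_spacing_um)
        with pytest.raises(mp.InputError):
            mp.radial_profile(grid, disc_mask, _geometry((128.0, 128.0), 100.0), 150.0)


class TestAverageProfiles:
    def _prof(self, means_a, n_vox, colony_id="c"):
        return mp.RadialProfile(np.array([0.0, 10.0, 20.0]),
                                {"a": np.asarray(means_a, dtype=float)},
                                np.asarray(n_vox), colony_id=colony_id)

    def test_idempotent_on_identical_profiles(self):
        p = self._prof([5.0, 6.0], [3, 4])
        avg = mp.average_profiles([p, p])
        assert np.allclose(avg.means["a"], [5.0, 6.0])
        assert list(avg.n_voxels) == [6, 8]

    def test_arithmetic_mean(self):
        avg = mp.average_profiles([self._prof([10.0, 10.0], [1, 1]),
                                   self._prof([30.0, 30.0], [1, 1])])
        assert np.allclose(avg.means["a"], [20.0, 20.0])

    def test_missing_bin_averages_available_colonies(self):
        p1 = self._prof([10.0, np.nan], [1, 0], "c1")
        p2 = self._prof([30.0, 8.0], [1, 2], "c2")
        avg = mp.average_profiles([p1, p2])
        assert avg.means["a"][0] == pytest.approx(20.0)
        assert avg.means["a"][1] == pytest.approx(8.0)  # only colony 2 has data
        assert list(avg.n_colonies) == [2, 1]

    def test_mismatched_bins_rejected(self):
        p1 = self._prof([1.0, 2.0], [1, 1])
        p2 = mp.RadialProfile(np.array([0.0, 5.0, 10.0]), {"a": np.array([1.0, 2.0])},
                              np.array([1, 1]))
        with pytest.raises(mp.InputError):
            mp.average_profiles([p1, p2])


class TestNormalize:
    def _prof(self, means, hoechst=None):
        ch = {"a": np.asarray(means, dtype=float)}
        if hoechst is not None:
            ch["hoechst"] = np.asarray(hoechst, dtype=float)
        return mp.RadialProfile(np.arange(len(means) + 1, dtype=float) * 10.0,
                                ch, np.ones(len(means), dtype=int))

    def test_max100_per_timepoint(self):
        out = mp.normalize_profile(self._prof([2.0, 4.0, 8.0]), "max100_per_timepoint")
        assert np.allclose(out.means["a"], [25.0, 50.0, 100.0])
        assert np.nanmax(out.means["a"]) == pytest.approx(100.0)

    def test_max100_across_timecourse(self):
        p0 = self._prof([2.0, 8.0])
        p24 = self._prof([4.0, 16.0])
        out = mp.normalize_profile(p0, "max100_across_timecourse",
                                   profile_set=[p0, p24])
        assert np.nanmax(out.means["a"]) == pytest.approx(50.0)

    def test_zero_max_rejected(self):
        with pytest.raises(mp.DegenerateImageError):
            mp.normalize_profile(self._prof([0.0, 0.0]), "max100_per_timepoint")

    def test_hoechst_relative(self):
        out = mp.normalize_profile(self._prof([5.0, 10.0], hoechst=[10.0, 40.0]),
                                   "hoechst_relative")
        assert np.allclose(out.means["a"], [0.5, 0.25])
        assert np.allclose(out.means["hoechst"], [1.0, 1.0])

    def test_hoechst_missing_rejected(self):
        with pytest.raises(mp.InputError):
            mp.normalize_profile(self._prof([1.0]), "hoechst_relative")


class TestDotSummaryAndBoundary:
    def test_radius_and_angle(self):
        cells = [mp.CellRecord((600.0, 500.0, 5.0), {"a": 1.0})]
        df = mp.dot_summary(cells, _geometry((500.0, 500.0), 500.0))
        assert df.loc[0, "radius_um"] == pytest.approx(100.0)
        assert df.loc[0, "angle_rad"] == pytest.approx(0.0)
        assert cells[0].radius_from_center_um == pytest.approx(100.0)

    def test_empty_cells_empty_table(self):
        df = mp.dot_summary([], _geometry((0.0, 0.0), 10.0))
        assert df.empty

    def test_edge_high_marker_ordering(self, noisy_colony, noisy_mask):
        spec = mp.SyntheticColonySpec(diameter_um=500.0, seed=13, marker_models=[
            mp.MarkerDomainModel("e", "edge_high", (150.0,), 5.0)])
        grid, truth = mp.generate_colony(spec, keep_clean=False)
        mask = mp.classify_nuclei(grid)
        geom = mp.estimate_center(mask, nominal_radius_um=250.0)
        cells = mp.detect_cell_centroids(mask, grid, min_separation_um=9.0)
        df = mp.dot_summary(cells, geom)
        outer = df[df.radius_um > 160.0]["e"].mean()
        inner = df[df.radius_um < 140.0]["e"].mean()
        assert outer > inner

    def test_flat_profile_no_crossing(self):
        prof = mp.RadialProfile(np.array([0.0, 10.0, 20.0]),
                                {"a": np.array([5.0, 5.0])}, np.array([1, 1]))
        with pytest.raises(mp.NoCrossingError):
            mp.recover_boundary(prof, "a")

    def test_step_crossing_at_bin_edge(self):
        prof = mp.RadialProfile(np.arange(5.0) * 10.0,
                                {"a": np.array([8.0, 8.0, 2.0, 2.0])},
                                np.ones(4, dtype=int))
        assert mp.recover_boundary(prof, "a") == pytest.approx(20.0)

    def test_logistic_profile_half_max(self):
        edges = np.arange(0.0, 510.0, 10.0)
        centers = 0.5 * (edges[:-1] + edges[1:])
        vals = 1.0 / (1.0 + np.exp((centers - 250.0) / 15.0))
        prof = mp.RadialProfile(edges, {"a": vals}, np.ones(len(centers), dtype=int))
        assert mp.recover_boundary(prof, "a") == pytest.approx(250.0, abs=10.0)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_profile_conservation_property(seed):
    """Σ n_voxels equals the number of masked voxels within the cutoff."""
    rng = np.random.default_rng(seed)
    nz, ny, nx = 2, int(rng.integers(5, 12)), int(rng.integers(5, 12))
    grid = mp.VoxelGrid(rng.random((1, nz, ny, nx)).astype(np.float32),
                        ["c"], (1.0, 1.0, 1.0))
    prob = (rng.random((nz, ny, nx)) > 0.5).astype(float)
    mask = mp.NuclearMask(prob, voxel_spacing_um=(1.0, 1.0, 1.0))
    center = (nx / 2.0, ny / 2.0)
    radius = float(rng.uniform(2.0, 8.0))
    prof = mp.radial_profile(grid, mask, _geometry(center, radius), 1.0)
    r_map = grid.xy_radius_map_um(center)
    zc, yc, xc = np.nonzero(mask.binary)
    expected = int(np.sum(r_map[yc, xc] <= min(radius, prof.bin_edges_um[-1])))
    assert int(prof.n_voxels.sum()) == expected
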