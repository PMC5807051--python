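"""Generator correctness: geometry, fidelity, determinism, time courses."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import micropattern as mp


def small_spec(**kw):
    kw.setdefault("diameter_um", 100.0)
    kw.setdefault("cell_density", 10.0 / (np.pi * 50.0**2 / 1000.0))  # 10 cells
    kw.setdefault("noise", mp.NoiseModel.off())
    kw.setdefault("marker_models", [])
    kw.setdefault("seed", 1)
    return mp.SyntheticColonySpec(**kw)


class TestGenerateColony:
    def test_no_markers_gives_single_nuclear_channel(self):
        grid, truth = mp.generate_colony(small_spec())
        assert grid.channel_names == ["hoechst"]
        assert truth.n_cells == 10

    def test_uniform_marker_is_exact_inside_cores(self, noise_free_colony):
        _, grid, truth = noise_free_colony
        core = truth.nuclear_core_mask()
        assert core.any()
        assert np.all(grid.channel("m")[core] == np.float32(7000.0))
        assert np.all(grid.channel("hoechst")[core] == np.float32(20000.0))

    def test_step_domain_assigns_levels_by_radius(self):
        m = mp.MarkerDomainModel("m", "center_high", (250.0,), 0.0,
                                 level_inside=100.0, level_outside=5.0)
        assert m.level_at(np.array([100.0]))[0] == 100.0
        assert m.level_at(np.array([400.0]))[0] == 5.0

    def test_generated_levels_match_domain_model(self):
        spec = small_spec(diameter_um=300.0, cell_density=2.0, marker_models=[
            mp.MarkerDomainModel("m", "center_high", (75.0,), 0.0,
                                 level_inside=100.0, level_outside=5.0)])
        _, truth = mp.generate_colony(spec)
        r = truth.cell_radii_um()
        levels = truth.marker_levels["m"]
        assert np.all(levels[r < 75.0] == 100.0)
        assert np.all(levels[r > 75.0] == 5.0)

    def test_determinism_bit_identical(self, tmp_path):
        spec = small_spec(noise=mp.NoiseModel())
        g1, t1 = mp.generate_colony(spec)
        g2, t2 = mp.generate_colony(spec)
        assert np.array_equal(g1.intensities, g2.intensities)
        assert np.array_equal(t1.centroids_um, t2.centroids_um)
        p1 = mp.io.write_stack(g1, tmp_path / "a")[0]
        p2 = mp.io.write_stack(g2, tmp_path / "b")[0]
        assert p1.read_bytes() == p2.read_bytes()

    def test_centroids_inside_disc_and_stack(self):
        spec = small_spec(diameter_um=300.0, cell_density=4.0)
        _, truth = mp.generate_colony(spec)
        assert np.all(truth.cell_radii_um() <= spec.radius_um)
        z = truth.centroids_um[:, 2]
        assert z.max() - z.min() <= spec.n_z_layers * spec.voxel_spacing_um[2]

    def test_realized_density_matches_request(self):
        spec = mp.SyntheticColonySpec(diameter_um=500.0, seed=6, marker_models=[],
                                      noise=mp.NoiseModel.off())
        _, truth = mp.generate_colony(spec, keep_clean=False)
        realized = truth.n_cells / (np.pi * spec.radius_um**2 / 1000.0)
        assert abs(realized - spec.cell_density) / spec.cell_density < 0.05

    def test_min_spacing_respected(self):
        spec = small_spec(diameter_um=300.0, cell_density=4.0)
        _, truth = mp.generate_colony(spec)
        from scipy.spatial import cKDTree
        d, _ = cKDTree(truth.centroids_um[:, :2]).query(truth.centroids_um[:, :2], k=2)
        assert d[:, 1].min() >= truth.min_spacing_um

    def test_infeasible_density_raises(self):
        with pytest.raises(mp.InfeasibleSpecError):
            spec = small_spec(diameter_um=200.0, cell_density=8.0, min_spacing_um=12.0)
            mp.generate_colony(spec)

    def test_boundary_radii_must_fit_colony(self):
        with pytest.raises(mp.InputError):
            small_spec(marker_models=[
                mp.MarkerDomainModel("m", "center_high", (80.0,))])


class TestTimecourse:
    def test_multiplier_halves_central_level_exactly(self):
        spec = small_spec(diameter_um=300.0, cell_density=3.0, marker_models=[
            mp.MarkerDomainModel("sox2", "center_high", (100.0,), 0.0)])
        series = mp.generate_timecourse(
            spec, {"sox2": mp.ChannelTransition([1.0, 0.5])}, [0.0, 24.0])
        (_, t0), (_, t24) = series
        r = t0.cell_radii_um()
        central = r < 100.0
        ratio = t24.marker_levels["sox2"][central].mean() / t0.marker_levels["sox2"][central].mean()
        assert ratio == pytest.approx(0.5, abs=1e-12)

    def test_identity_transitions_reproduce_0hr(self):
        spec = small_spec(noise=mp.NoiseModel(), marker_models=[
            mp.MarkerDomainModel("m", "uniform")])
        series = mp.generate_timecourse(
            spec, {"m": mp.ChannelTransition([1.0, 1.0])}, [0.0, 24.0])
        assert np.array_equal(series[0][0].intensities, series[1][0].intensities)

    def test_boundary_shift_recovered_by_profiling(self):
        spec = mp.SyntheticColonySpec(diameter_um=500.0, seed=12, marker_models=[
            mp.MarkerDomainModel("m", "center_high", (200.0,), 10.0)])
        series = mp.generate_timecourse(
            spec, {"m": mp.ChannelTransition([1.0, 1.0], [[200.0], [140.0]])},
            [24.0, 48.0])
        recovered = []
        for grid, truth in series:
            mask = mp.classify_nuclei(grid)
            geom = mp.estimate_center(mask, nominal_radius_um=250.0)
            prof = mp.radial_profile(grid, mask, geom)
            recovered.append(mp.recover_boundary(prof, "m"))
        assert series[0][1].boundary_radii_um["m"] == [200.0]
        assert series[1][1].boundary_radii_um["m"] == [140.0]
        assert recovered[1] < recovered[0]
        assert recovered[0] == pytest.approx(200.0, abs=15.0)
        assert recovered[1] == pytest.approx(140.0, abs=15.0)

    def test_timepoints_must_increase(self):
        spec = small_spec(marker_models=[mp.MarkerDomainModel("m", "uniform")])
        with pytest.raises(mp.InputError):
            mp.generate_timecourse(spec, {"m": mp.ChannelTransition([1, 1])},
                                   [24.0, 24.0])


class TestSectionFixture:
    REGIONS = [
        {"region_id": "A", "polygon_um": [(10, 10), (80, 10), (80, 80), (10, 80)],
         "channel_means": {"hoechst": 20.0, "m": 10.0}},
        {"region_id": "B", "polygon_um": [(110, 10), (180, 10), (180, 80), (110, 80)],
         "channel_means": {"hoechst": 20.0, "m": 30.0}},
    ]

    def test_hoechst_normalized_region_means(self):
        grid, truth = mp.generate_section_fixture(self.REGIONS, seed=1)
        for reg in truth["regions"]:
            res = mp.roi_mean(grid, dict(
                A=self.REGIONS[0], B=self.REGIONS[1])[reg["region_id"]]["polygon_um"])
            expected = reg["true_means"]["m"] / reg["true_means"]["hoechst"]
            assert res.hoechst_normalized["m"] == pytest.approx(expected)

    def test_single_region(self):
        grid, truth = mp.generate_section_fixture([self.REGIONS[0]], seed=1)
        assert len(truth["regions"]) == 1

    def test_overlapping_regions_rejected(self):
        bad = [self.REGIONS[0],
               {"region_id": "C", "polygon_um": [(50, 50), (120, 50), (120, 120), (50, 120)],
                "channel_means": {"hoechst": 20.0, "m": 1.0}}]
        with pytest.raises(mp.InputError):
            mp.generate_section_fixture(bad, seed=1)

    def test_noisy_region_mean_within_standard_error(self):
        sigma = 5.0
        grid, truth = mp.generate_section_fixture(self.REGIONS, seed=2,
                                                  noise_sigma=sigma)
        reg = truth["regions"][0]
        vals = grid.channel("m")[0][truth["masks"][0]]
        se = sigma / np.sqrt(reg["n_pixels"])
        assert abs(vals.mean() - reg["true_means"]["m"]) < 3 * se


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    kind=st.sampled_from(["uniform", "center_high", "edge_high", "annulus"]),
    sharp=st.floats(0.0, 50.0),
    inside=st.floats(0.0, 1e4),
    outside=st.floats(0.0, 1e4),
    r=st.floats(0.0, 500.0),
)
def test_domain_levels_bounded_by_model_levels(kind, sharp, inside, outside, r):
    radii = {"uniform": (), "center_high": (200.0,), "edge_high": (200.0,),
             "annulus": (150.0, 300.0)}[kind]
    m = mp.MarkerDomainModel("m", kind, radii, sharp,
                             level_inside=inside, level_outside=outside)
    level = float(m.level_at(np.array([r]))[0])
    lo, hi = min(inside, outside), max(inside, outside)
    assert lo - 1e-9 <= level <= hi + 1e-9
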