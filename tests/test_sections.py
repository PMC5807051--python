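"""ROI and point quantification on 2D sections, Hoechst normalization."""

import numpy as np
import pytest

import micropattern as mp


def _section(channel_arrays, pixel_um=1.0):
    names = list(channel_arrays)
    data = np.stack([np.asarray(channel_arrays[n], dtype=np.float32)[None]
                     for n in names])
    return mp.VoxelGrid(data, names, (pixel_um, pixel_um, 1.0))


SQUARE = [(2.0, 2.0), (10.0, 2.0), (10.0, 10.0), (2.0, 10.0)]


class TestRoiMean:
    def test_constant_ratio(self):
        sec = _section({"hoechst": np.full((16, 16), 20.0),
                        "m": np.full((16, 16), 10.0)})
        res = mp.roi_mean(sec, SQUARE)
        assert res.hoechst_normalized["m"] == pytest.approx(0.5)

    def test_2x2_pixel_enumeration(self):
        img = np.zeros((4, 4))
        img[1, 1], img[1, 2], img[2, 1], img[2, 2] = 1.0, 2.0, 3.0, 4.0
        sec = _section({"hoechst": np.ones((4, 4)), "m": img})
        # unit-square-style ROI containing exactly the 2x2 pixel centers
        res = mp.roi_mean(sec, [(1.0, 1.0), (3.0, 1.0), (3.0, 3.0), (1.0, 3.0)])
        assert res.n_pixels == 4
        assert res.means["m"] == pytest.approx(2.5)

    def test_roi_outside_image(self):
        sec = _section({"hoechst": np.ones((8, 8))})
        with pytest.raises(mp.InputError):
            mp.roi_mean(sec, [(50.0, 50.0), (60.0, 50.0), (60.0, 60.0)])

    def test_zero_hoechst_rejected(self):
        sec = _section({"hoechst": np.zeros((8, 8)), "m": np.ones((8, 8))})
        with pytest.raises(mp.DegenerateImageError):
            mp.roi_mean(sec, SQUARE[:3])

    def test_normalization_scale_invariant(self):
        rng = np.random.default_rng(4)
        ch = {"hoechst": rng.uniform(10, 50, (16, 16)),
              "m": rng.uniform(1, 20, (16, 16))}
        r1 = mp.roi_mean(_section(ch), SQUARE)
        r2 = mp.roi_mean(_section({k: 7.3 * v for k, v in ch.items()}), SQUARE)
        # float32 image storage limits agreement to single precision
        assert r1.hoechst_normalized["m"] == pytest.approx(
            r2.hoechst_normalized["m"], rel=1e-6)


class TestPointQuant:
    def test_constant_image_ratio(self):
        sec = _section({"hoechst": np.full((32, 32), 8.0),
                        "m": np.full((32, 32), 12.0)})
        res = mp.point_cell_quant(sec, [{"roi_id": "c1", "group": "epi",
                                         "coordinates_um": (16.0, 16.0)}], 5.0)
        assert res[0].hoechst_normalized["m"] == pytest.approx(1.5)

    def test_region_construction_recovered_exactly(self):
        regions = [
            {"region_id": "A", "polygon_um": [(0, 0), (30, 0), (30, 30), (0, 30)],
             "channel_means": {"hoechst": 20.0, "m": 30.0}},
            {"region_id": "B", "polygon_um": [(40, 0), (70, 0), (70, 30), (40, 30)],
             "channel_means": {"hoechst": 20.0, "m": 10.0}},
        ]
        sec, _ = mp.generate_section_fixture(regions, seed=1, image_size_um=(80, 40))
        pts = [{"roi_id": "a", "group": "A", "coordinates_um": (15.0, 15.0)},
               {"roi_id": "b", "group": "B", "coordinates_um": (55.0, 15.0)}]
        results = mp.point_cell_quant(sec, pts, radius_um=5.0)
        assert results[0].hoechst_normalized["m"] == pytest.approx(1.5)
        assert results[1].hoechst_normalized["m"] == pytest.approx(0.5)

    def test_group_sd_uses_n_minus_1(self):
        sec = _section({"hoechst": np.ones((8, 8))})
        results = [
            mp.RoiQuantResult("a", {"m": v}, {"m": v}, 1, group="g")
            for v in (1.0, 2.0, 4.0)
        ]
        summary = mp.group_summary(results)
        row = summary[(summary.group == "g") & (summary.channel == "m")].iloc[0]
        assert row["mean"] == pytest.approx(7.0 / 3.0)
        assert row["sd"] == pytest.approx(np.std([1.0, 2.0, 4.0], ddof=1))
        assert row["n"] == 3

    def test_noisy_group_mean_within_3se(self):
        rng = np.random.default_rng(6)
        sigma = 2.0
        hoechst = np.full((64, 64), 10.0)
        m = np.full((64, 64), 15.0) + rng.normal(0, sigma, (64, 64))
        sec = _section({"hoechst": hoechst, "m": m.clip(0)})
        pts = [{"roi_id": f"p{i}", "group": "g",
                "coordinates_um": (8.0 + 6.0 * i, 32.0)} for i in range(8)]
        results = mp.point_cell_quant(sec, pts, radius_um=2.5)
        vals = [r.hoechst_normalized["m"] for r in results]
        n_pix = results[0].n_pixels
        se = sigma / 10.0 / np.sqrt(n_pix * len(pts))
        assert abs(np.mean(vals) - 1.5) < 3 * se


class TestRoiFiles:
    def test_load_and_quantify(self, tmp_path):
        import json
        rois = {"rois": [
            {"roi_id": "r1", "group": "A", "type": "polygon",
             "coordinates_um": SQUARE},
            {"roi_id": "p1", "group": "B", "type": "point",
             "coordinates_um": [8.0, 8.0]},
        ]}
        path = tmp_path / "rois.json"
        path.write_text(json.dumps(rois))
        sec = _section({"hoechst": np.full((16, 16), 4.0),
                        "m": np.full((16, 16), 6.0)})
        results = mp.quantify_rois(sec, mp.load_rois(path), point_radius_um=3.0)
        assert [r.roi_id for r in results] == ["r1", "p1"]
        assert all(r.hoechst_normalized["m"] == pytest.approx(1.5) for r in results)

    def test_bad_roi_type_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"rois": [{"type": "circle", "coordinates_um": [1, 2]}]}')
        with pytest.raises(mp.InputError):
            mp.load_rois(path)
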