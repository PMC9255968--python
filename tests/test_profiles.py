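"""Two-color profile, correlation and islet-segmentation tests."""

import numpy as np
import pytest

import podonano as pn
from podonano.core import CoreSet, Image2D

from conftest import row_layout, single_core_layout

PS = 32.25


def _ring_image(centers_radii, shape=(400, 400), amplitude=100.0,
                sigma_px=1.5):
    """Closed Gaussian-profile rings (adhesion-border phantom)."""
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    img = np.zeros(shape)
    for cx, cy, radius in centers_radii:
        rho = np.hypot(xx - cx, yy - cy)
        img += amplitude * np.exp(-(rho - radius) ** 2 / (2 * sigma_px ** 2))
    return Image2D(img, PS, "adhesion")


class TestBeltAngle:
    def test_horizontal_row_gives_zero_degrees(self):
        cores = CoreSet.from_arrays(np.arange(5) * 500.0, np.zeros(5))
        belt = pn.local_belt_angle(cores, 2)
        assert belt.angle_deg == pytest.approx(0.0, abs=1e-9)
        assert belt.confident

    def test_line_at_30_degrees_recovered(self):
        t = np.arange(6) * 400.0
        cores = CoreSet.from_arrays(t * np.cos(np.deg2rad(30)),
                                    t * np.sin(np.deg2rad(30)))
        belt = pn.local_belt_angle(cores, 3)
        assert belt.angle_deg == pytest.approx(30.0, abs=1.0)

    def test_rotation_equivariance_mod_180(self):
        rng = np.random.default_rng(0)
        pts = np.column_stack([rng.uniform(0, 2000, 12),
                               rng.uniform(0, 300, 12)])
        base = pn.local_belt_angle(CoreSet.from_arrays(*pts.T), 0).angle_deg
        theta = 40.0
        rot = np.deg2rad(theta)
        rmat = np.array([[np.cos(rot), -np.sin(rot)],
                         [np.sin(rot), np.cos(rot)]])
        rotated = pts @ rmat.T
        got = pn.local_belt_angle(CoreSet.from_arrays(*rotated.T), 0).angle_deg
        assert (got - base - theta) % 180.0 == pytest.approx(0.0, abs=1.0) \
            or (got - base - theta) % 180.0 == pytest.approx(180.0, abs=1.0)

    def test_isotropic_neighborhood_flagged(self):
        ang = np.linspace(0, 2 * np.pi, 13)[:-1]
        cores = CoreSet.from_arrays(500 * np.cos(ang), 500 * np.sin(ang))
        belt = pn.local_belt_angle(cores, 0, neighborhood_radius_nm=2000.0)
        assert not belt.confident

    def test_too_few_neighbors_rejected(self):
        cores = CoreSet.from_arrays([0.0, 5000.0], [0.0, 5000.0])
        with pytest.raises(ValueError):
            pn.local_belt_angle(cores, 0, neighborhood_radius_nm=100.0)


class TestExtractLineProfiles:
    def _setup(self):
        layout = row_layout([2000.0, 2600.0, 3200.0], 1500.0,
                            field=(5200.0, 3000.0))
        actin = pn.render_frame(layout, noise=False)
        edge = pn.edge_transform(actin)
        cores = CoreSet.from_arrays(layout.cores.x_nm, layout.cores.y_nm,
                                    core_id=layout.cores.core_id)
        return layout, actin, edge, cores

    def test_marker_equal_to_actin_gives_identical_profiles(self):
        _, actin, edge, cores = self._setup()
        lp = pn.extract_line_profiles(actin, edge, actin, cores,
                                      np.zeros(len(cores)))
        np.testing.assert_allclose(lp.channels["marker"],
                                   lp.channels["actin"])

    def test_ring_marker_flanks_the_actin_peak(self):
        layout, actin, edge, cores = self._setup()
        ring = pn.render_frame(layout,
                               channel=pn.ProteinSpec(
                                   name="vinculin",
                                   lateral_model="ring_at_offset_nm",
                                   ring_offset_nm=200.0),
                               noise=False, background=0.0)
        lp = pn.extract_line_profiles(actin, edge, ring, cores,
                                      np.zeros(len(cores)))
        prof = lp.channels["marker"][0, 1]  # transverse, first core
        mid = len(prof) // 2
        left_peak = np.argmax(prof[:mid])
        right_peak = mid + np.argmax(prof[mid:])
        assert lp.positions_nm[left_peak] < -150.0
        assert lp.positions_nm[right_peak] > 150.0
        actin_peak = np.argmax(lp.channels["actin"][0, 1])
        assert left_peak < actin_peak < right_peak

    def test_center_sample_matches_width_averaged_lookup(self):
        rng = np.random.default_rng(1)
        img = Image2D(rng.uniform(0, 100, (80, 80)), PS)
        cores = CoreSet.from_arrays([40 * PS], [40 * PS])
        lp = pn.extract_line_profiles(img, img, img, cores, [0.0],
                                      width_nm=100.0)
        mid = len(lp.positions_nm) // 2
        expected = img.pixels[39:42, 40].mean()  # 3 samples across width
        assert lp.channels["actin"][0, 0, mid] == pytest.approx(expected)

    def test_border_cores_excluded_and_counted(self):
        _, actin, edge, _ = self._setup()
        cores = CoreSet.from_arrays([100.0, 2600.0], [1500.0, 1500.0])
        lp = pn.extract_line_profiles(actin, edge, actin, cores, [0.0, 0.0])
        assert lp.n_cores == 1
        assert lp.excluded_ids == [0]


class TestNormalizeAndPool:
    def _profiles(self, radii, seed=0):
        # spacing is a whole number of pixels so equal-radius cores render
        # with identical subpixel phase
        xs = 2000.0 + np.arange(len(radii)) * (56 * PS)
        layout = row_layout(xs, 2000.0,
                            field=(xs[-1] + 2000.0, 4000.0))
        layout.cores["radius_nm"] = radii
        actin = pn.render_frame(layout, noise=False)
        edge = pn.edge_transform(actin)
        cores = CoreSet.from_arrays(layout.cores.x_nm, layout.cores.y_nm,
                                    core_id=layout.cores.core_id)
        return pn.extract_line_profiles(actin, edge, actin, cores,
                                        np.zeros(len(cores)))

    def test_identical_cores_pool_to_single_profile(self):
        lp = self._profiles([100.0, 100.0, 100.0])
        pooled = pn.normalize_and_pool(lp)
        single = pn.normalize_and_pool(
            pn.LineProfileSet(lp.positions_nm, lp.core_ids[:1],
                              {k: v[:1] for k, v in lp.channels.items()}, []))
        assert pooled.median_radius_nm == pytest.approx(
            single.median_radius_nm, rel=1e-6)
        np.testing.assert_allclose(pooled.profiles["actin"],
                                   single.profiles["actin"], atol=1e-9)

    def test_intensity_doubling_leaves_normalized_profiles_unchanged(self):
        lp = self._profiles([80.0, 100.0, 120.0])
        doubled = pn.LineProfileSet(lp.positions_nm, lp.core_ids,
                                    {k: 2 * v for k, v in lp.channels.items()},
                                    [])
        a = pn.normalize_and_pool(lp)
        b = pn.normalize_and_pool(doubled)
        for name in a.profiles:
            np.testing.assert_allclose(a.profiles[name], b.profiles[name],
                                       atol=1e-12)

    def test_pooled_actin_half_width_near_one_radius_unit(self):
        lp = self._profiles([80.0, 100.0, 120.0])
        pooled = pn.normalize_and_pool(lp)
        prof = pooled.profiles["actin"]
        grid = pooled.positions_units
        # distance from center to the half-maximum crossing, in radius units
        mid = np.argmin(np.abs(grid))
        right = prof[mid:]
        cross = np.interp(0.5, right[::-1], grid[mid:][::-1])
        assert cross == pytest.approx(1.0, abs=0.35)

    def test_median_radius_close_to_planted(self):
        lp = self._profiles([100.0, 100.0, 100.0])
        pooled = pn.normalize_and_pool(lp)
        assert pooled.median_radius_nm == pytest.approx(100.0, abs=PS)

    def test_no_edge_maxima_rejected(self):
        positions = np.arange(-10, 11) * PS
        flat = {name: np.zeros((1, 2, len(positions)))
                for name in ("actin", "edge", "marker")}
        lp = pn.LineProfileSet(positions, np.array([0]), flat, [])
        with pytest.raises(ValueError):
            pn.normalize_and_pool(lp)


class TestCoreMarkerCorrelation:
    def test_marker_equal_to_actin_gives_r_one(self, default_frame,
                                               truth_cores):
        res = pn.core_marker_correlation(default_frame, default_frame,
                                         truth_cores)
        assert res.pearson_r == pytest.approx(1.0)

    def test_constant_marker_reported_undefined(self, default_frame,
                                                truth_cores):
        const = Image2D(np.full_like(default_frame.pixels, 5.0), PS)
        res = pn.core_marker_correlation(default_frame, const, truth_cores)
        assert np.isnan(res.pearson_r)
        assert "zero-variance" in res.reason

    def test_fewer_than_three_cores_undefined(self, default_frame):
        cores = CoreSet.from_arrays([3000.0, 6000.0], [3000.0, 6000.0])
        res = pn.core_marker_correlation(default_frame, default_frame, cores)
        assert np.isnan(res.pearson_r)

    def test_planted_population_correlation_recovered(self):
        # marker disc means = 0.8 * actin + independent noise, calibrated
        # to a population r of 0.8, measured through the image pathway
        rng = np.random.default_rng(42)
        n = 300
        ps = 64.5
        side = 40  # px per tile; one core per tile center
        tiles_per_row = 18
        h = w = side * ((n + tiles_per_row - 1) // tiles_per_row + 1)
        actin_px = np.zeros((h, w))
        marker_px = np.zeros((h, w))
        xs, ys = [], []
        a_level = rng.uniform(10, 100, n)
        noise_sd = np.std(a_level) * 0.8 * np.sqrt(1 / 0.8 ** 2 - 1)
        m_level = 0.8 * a_level + rng.normal(0, noise_sd, n)
        m_level -= m_level.min() - 1.0
        for i in range(n):
            r0 = (i // tiles_per_row) * side
            c0 = (i % tiles_per_row) * side
            actin_px[r0:r0 + side, c0:c0 + side] = a_level[i]
            marker_px[r0:r0 + side, c0:c0 + side] = m_level[i]
            ys.append((r0 + side // 2) * ps)
            xs.append((c0 + side // 2) * ps)
        cores = CoreSet.from_arrays(xs, ys)
        res = pn.core_marker_correlation(Image2D(actin_px, ps),
                                         Image2D(marker_px, ps), cores,
                                         radius_nm=1000.0)
        assert res.pearson_r == pytest.approx(0.8, abs=0.08)


class TestSegmentIslets:
    def test_single_ring_encloses_its_cores(self):
        img = _ring_image([(120, 120, 80)])
        rng = np.random.default_rng(0)
        ang = rng.uniform(0, 2 * np.pi, 5)
        rad = rng.uniform(0, 50, 5)
        cores = CoreSet.from_arrays((120 + rad * np.cos(ang)) * PS,
                                    (120 + rad * np.sin(ang)) * PS)
        stats, labels = pn.segment_islets(img, cores, min_area_um2=0.5)
        assert len(stats) == 1
        assert stats.n_cores[0] == 5
        planted = np.pi * (80 * PS / 1000.0) ** 2
        assert stats.area_um2[0] == pytest.approx(planted, rel=0.10)

    def test_two_disjoint_rings_give_two_islets(self):
        img = _ring_image([(100, 100, 70), (280, 260, 90)])
        xs = np.concatenate([100 + np.array([-20, 0, 20]),
                             280 + np.array([-30, 0, 30, -15, 15, 0, 10])])
        ys = np.concatenate([100 + np.array([0, 15, -10]),
                             260 + np.array([0, -25, 20, 15, -10, 35, 0])])
        cores = CoreSet.from_arrays(xs * PS, ys * PS)
        stats, _ = pn.segment_islets(img, cores, min_area_um2=0.5)
        assert len(stats) == 2
        assert sorted(stats.n_cores) == [3, 7]

    def test_no_adhesion_signal_gives_no_islets(self):
        img = Image2D(np.zeros((100, 100)), PS)
        cores = CoreSet.from_arrays([1000.0], [1000.0])
        stats, labels = pn.segment_islets(img, cores)
        assert len(stats) == 0
        assert not labels.any()

    def test_open_ring_leaks_to_border_and_is_dropped(self):
        img = _ring_image([(120, 120, 80)])
        img.pixels[118:123, 30:45] = 0.0  # cut the ring open
        from scipy import ndimage as ndi
        img.pixels[115:126, 25:50] = ndi.gaussian_filter(
            img.pixels[115:126, 25:50], 2.0)
        cores = CoreSet.from_arrays([120 * PS], [120 * PS])
        stats, _ = pn.segment_islets(img, cores, min_area_um2=0.5)
        assert len(stats) == 0
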