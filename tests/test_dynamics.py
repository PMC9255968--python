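"""Dynamics tests: bleach correction, signals, synchrony, spectra, rates."""

import numpy as np
import pandas as pd
import pytest

import podonano as pn
from podonano.core import CoreSet, Image2D, ImageStack

from conftest import row_layout

PS = 32.25


def _stack(frames, dt=2.4):
    return ImageStack(np.asarray(frames, float), dt, PS)


class TestBleachCorrect:
    def test_identical_frames_unchanged(self):
        rng = np.random.default_rng(0)
        frame = rng.uniform(0, 100, (40, 40))
        stack = _stack([frame, frame, frame])
        out = pn.bleach_correct(stack)
        np.testing.assert_allclose(out.frames, stack.frames)

    def test_scaled_frame_restored_to_reference(self):
        rng = np.random.default_rng(1)
        frame = rng.uniform(0, 200, (60, 60))
        stack = _stack([frame, 0.5 * frame])
        out = pn.bleach_correct(stack)
        # quantile-exact up to histogram discretization
        assert np.abs(out.frames[1] - frame).max() < 1e-6

    def test_quantiles_match_reference_after_correction(self):
        rng = np.random.default_rng(2)
        stack = _stack([rng.uniform(0, 100, (80, 80)),
                        rng.uniform(20, 60, (80, 80)),
                        rng.uniform(0, 30, (80, 80))])
        out = pn.bleach_correct(stack)
        q = np.linspace(0.01, 0.99, 256)
        ref_q = np.quantile(out.frames[0], q)
        bin_w = np.ptp(out.frames[0]) / 256
        for t in (1, 2):
            assert np.abs(np.quantile(out.frames[t], q) - ref_q).max() < bin_w

    def test_constant_frame_identity(self):
        stack = _stack([np.arange(100.0).reshape(10, 10),
                        np.full((10, 10), 5.0)])
        out = pn.bleach_correct(stack)
        np.testing.assert_allclose(out.frames[1], 5.0)


class TestExtractSignals:
    def test_constant_stack_gives_constant_signals(self):
        stack = _stack([np.full((30, 30), 7.0)] * 4)
        cores = CoreSet.from_arrays([15 * PS], [15 * PS])
        sig = pn.extract_signals(stack, cores)
        np.testing.assert_allclose(sig.values, 7.0)

    def test_signals_linear_in_frame_intensity(self, default_frame):
        stack = _stack([default_frame.pixels, 2 * default_frame.pixels])
        cores = CoreSet.from_arrays([5000.0, 6000.0], [5000.0, 4000.0])
        sig = pn.extract_signals(stack, cores)
        np.testing.assert_allclose(sig.values[:, 1], 2 * sig.values[:, 0])

    def test_movie_roundtrip_correlates_with_truth(self):
        layout = row_layout([2000.0, 4000.0, 6000.0], 2000.0)
        osc = pn.OscSpec(components=[(0.04, 0.4)], phase_model="independent",
                         noise_sd_fraction=0.0)
        stack, truth = pn.simulate_movie(layout, osc, noise=False, rng=1)
        cores = CoreSet.from_arrays(layout.cores.x_nm, layout.cores.y_nm,
                                    core_id=layout.cores.core_id)
        sig = pn.extract_signals(stack, cores)
        for i in range(3):
            r = np.corrcoef(sig.values[i], truth.signals[i])[0, 1]
            assert r > 0.99

    def test_tiny_radius_rejected(self):
        stack = _stack([np.zeros((30, 30))] * 2)
        cores = CoreSet.from_arrays([15 * PS + PS / 2], [15 * PS + PS / 2])
        with pytest.raises(ValueError):
            pn.extract_signals(stack, cores, radius_nm=PS / 4)


class TestPairwiseSynchrony:
    def _signals(self, values, coords=None):
        values = np.asarray(values, float)
        n = len(values)
        coords = (np.column_stack([np.arange(n) * 1000.0, np.zeros(n)])
                  if coords is None else np.asarray(coords, float))
        return pn.SignalMatrix(np.arange(n), coords, values, 2.4)

    def test_identical_signals_give_r_one(self):
        t = np.linspace(0, 4 * np.pi, 50)
        sig = self._signals([np.sin(t), np.sin(t)])
        table = pn.pairwise_synchrony(sig, detrend=False)
        assert table.pearson_r[0] == pytest.approx(1.0)

    def test_antiphase_sinusoids_give_r_minus_one(self):
        t = np.linspace(0, 4 * np.pi, 51)[:-1]  # whole periods
        sig = self._signals([np.sin(t), -np.sin(t)])
        table = pn.pairwise_synchrony(sig, detrend=False)
        assert table.pearson_r[0] == pytest.approx(-1.0)

    def test_zero_variance_signal_reported_undefined(self):
        t = np.linspace(0, 2 * np.pi, 30)
        sig = self._signals([np.sin(t), np.full_like(t, 3.0), np.cos(t)])
        table = pn.pairwise_synchrony(sig, detrend=False)
        flat_pairs = table[(table.core_i == 1) | (table.core_j == 1)]
        assert flat_pairs.pearson_r.isna().all()
        assert table.attrs["n_zero_variance"] == 1

    def test_r_invariant_under_affine_intensity_transform(self):
        rng = np.random.default_rng(4)
        raw = rng.normal(0, 1, (4, 40)).cumsum(axis=1)
        a = pn.pairwise_synchrony(self._signals(raw))
        gains = rng.uniform(0.5, 3.0, 4)[:, None]
        offsets = rng.uniform(-10, 10, 4)[:, None]
        b = pn.pairwise_synchrony(self._signals(raw * gains + offsets))
        np.testing.assert_allclose(a.pearson_r, b.pearson_r, atol=1e-10)

    def test_distance_column_is_euclidean(self):
        sig = self._signals(np.random.default_rng(0).normal(0, 1, (2, 20)),
                            coords=[[0.0, 0.0], [300.0, 400.0]])
        table = pn.pairwise_synchrony(sig)
        assert table.distance_nm[0] == pytest.approx(500.0)


class TestSynchronyCurve:
    def test_constant_r_curve_has_no_half_decay(self):
        table = pd.DataFrame({"core_i": 0, "core_j": 1,
                              "distance_nm": np.linspace(50, 3000, 100),
                              "pearson_r": 1.0})
        curve = pn.synchrony_curve(table)
        assert np.allclose(curve.mean_r[curve.counts > 0], 1.0)
        assert np.isnan(curve.half_decay_nm)

    def test_exponential_decay_recovers_lambda_ln2(self):
        lam = 800.0
        d = np.linspace(10, 5000, 2000)
        table = pd.DataFrame({"core_i": 0, "core_j": 1, "distance_nm": d,
                              "pearson_r": np.exp(-d / lam)})
        curve = pn.synchrony_curve(table, bin_width_nm=100.0)
        assert curve.half_decay_nm == pytest.approx(lam * np.log(2), abs=100.0)

    def test_all_undefined_rejected(self):
        table = pd.DataFrame({"core_i": [0], "core_j": [1],
                              "distance_nm": [100.0],
                              "pearson_r": [np.nan]})
        with pytest.raises(ValueError):
            pn.synchrony_curve(table)


class TestSpectrum:
    def test_bin_centered_sinusoid_dominates(self):
        tlen, dt = 128, 2.4
        t = np.arange(tlen) * dt
        f0 = 10 / (tlen * dt)
        spec = pn.spectrum(np.sin(2 * np.pi * f0 * t), dt)
        k = int(np.argmax(spec.magnitudes))
        assert spec.frequencies_Hz[k] == pytest.approx(f0)
        others = np.delete(spec.magnitudes, k)
        assert spec.magnitudes[k] >= 10 * others.max()

    def test_constant_signal_zero_after_detrend(self):
        spec = pn.spectrum(np.full(32, 17.0), 2.4)
        assert np.allclose(spec.magnitudes, 0.0, atol=1e-9)

    def test_parseval_identity(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, 64)
        from scipy.signal import detrend as lin_detrend
        resid = lin_detrend(x - x.mean())
        full = np.abs(np.fft.fft(resid)) ** 2
        assert full.sum() / len(x) == pytest.approx(
            (resid ** 2).sum(), rel=1e-6)
        spec = pn.spectrum(x, 1.0)
        np.testing.assert_allclose(spec.magnitudes,
                                   np.abs(np.fft.rfft(resid)))

    def test_axis_runs_to_nyquist(self):
        spec = pn.spectrum(np.arange(40.0), 2.4)
        assert len(spec.frequencies_Hz) == 21
        assert spec.frequencies_Hz[-1] == pytest.approx(1 / (2 * 2.4))

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            pn.spectrum(np.array([1.0, np.nan] * 8), 2.4)


class TestNaturalFrequencies:
    def test_planted_components_recovered_within_one_bin(self):
        tlen, dt = 167, 2.4  # ~400 s window
        t = np.arange(tlen) * dt
        df = 1 / (tlen * dt)
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x = sum(3.0 * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
                    for f in (0.01, 0.04, 0.15))
            x = x + rng.normal(0, 1.0, tlen)  # amplitude/noise SNR = 3
            det = pn.natural_frequencies(pn.spectrum(x, dt), k_median=5.0)
            assert len(det) == 3
            for f in (0.01, 0.04, 0.15):
                assert np.abs(det - f).min() <= df

    def test_white_noise_yields_no_detections_at_k20(self):
        hits = 0
        for seed in range(40):
            x = np.random.default_rng(seed).normal(0, 1, 167)
            hits += len(pn.natural_frequencies(pn.spectrum(x, 2.4), 20.0)) > 0
        assert hits <= 2

    def test_detections_invariant_to_signal_scaling(self):
        t = np.arange(167) * 2.4
        x = np.sin(2 * np.pi * 0.04 * t) + \
            0.1 * np.random.default_rng(0).normal(0, 1, 167)
        a = pn.natural_frequencies(pn.spectrum(x, 2.4))
        b = pn.natural_frequencies(pn.spectrum(123.0 * x, 2.4))
        np.testing.assert_allclose(a, b)


class TestRateMovie:
    def test_static_stack_gives_zero_rates(self):
        stack = _stack([np.full((20, 20), 9.0)] * 5)
        rate = pn.rate_movie(stack)
        assert np.allclose(rate.values, 0.0)

    def test_raw_differences_telescope(self):
        rng = np.random.default_rng(1)
        stack = _stack(rng.uniform(0, 100, (6, 30, 30)))
        rate = pn.rate_movie(stack, gaussian_radius_nm=None,
                             temporal_window=1)
        total = rate.values.sum(axis=0)
        expected = stack.frames[-1] - stack.frames[0]
        np.testing.assert_allclose(total, expected, rtol=1e-6, atol=1e-9)

    def test_growth_and_decay_phases_have_correct_sign(self):
        layout = row_layout([2000.0], 2000.0, field=(4000.0, 4000.0))
        osc = pn.OscSpec(components=[(0.02, 0.5)], phase_model="global",
                         noise_sd_fraction=0.0, n_frames=30)
        stack, truth = pn.simulate_movie(layout, osc, noise=False, rng=2)
        rate = pn.rate_movie(stack)
        disc = slice(57, 68), slice(57, 68)  # pixels around the core
        dtruth = np.diff(truth.signals[0])
        for t in (int(np.argmax(dtruth)), int(np.argmin(dtruth))):
            mean_rate = rate.values[t][disc].mean()
            assert np.sign(mean_rate) == np.sign(dtruth[t])


class TestSegmentRateClusters:
    def test_zero_ratemap_has_no_regions(self):
        rate = pn.rate_movie(_stack([np.zeros((30, 30))] * 4))
        regions = pn.segment_rate_clusters(rate)
        assert len(regions) == 0

    def test_planted_discs_recovered_with_sign_and_centroid(self):
        yy, xx = np.mgrid[0:120, 0:120]
        pos = 50.0 * np.exp(-((xx - 30) ** 2 + (yy - 40) ** 2) / (2 * 16.0))
        neg = -50.0 * np.exp(-((xx - 85) ** 2 + (yy - 80) ** 2) / (2 * 16.0))
        rng = np.random.default_rng(0)
        frame = pos + neg + rng.normal(0, 1.0, (120, 120))
        rate = pn.RateMap(frame[None], 2.4, PS, None, 1)
        regions = pn.segment_rate_clusters(rate, z_thresh=3.0,
                                           min_area_um2=0.01)
        grow = regions[regions.sign == "growing"]
        decay = regions[regions.sign == "decreasing"]
        assert len(grow) == 1 and len(decay) == 1
        assert np.hypot(grow.centroid_x_nm.iloc[0] - 30 * PS,
                        grow.centroid_y_nm.iloc[0] - 40 * PS) <= 2 * PS
        assert np.hypot(decay.centroid_x_nm.iloc[0] - 85 * PS,
                        decay.centroid_y_nm.iloc[0] - 80 * PS) <= 2 * PS

    def test_islet_shared_phases_cosegment_more_than_independent(self):
        frac = {}
        for model in ("islet_shared", "independent"):
            together = 0
            total = 0
            for seed in range(3):
                layout = pn.make_layout(pn.LayoutParams(
                    field_size_nm=(6000.0, 6000.0), n_islets=4,
                    islet_radius_nm=350.0, cores_per_islet_mean=5.0,
                    hard_core_nm=250.0, seed=seed))
                osc = pn.OscSpec(components=[(0.04, 0.5)], phase_model=model,
                                 noise_sd_fraction=0.0, n_frames=20)
                stack, truth = pn.simulate_movie(layout, osc, rng=seed)
                rate = pn.rate_movie(stack)
                regions = pn.segment_rate_clusters(
                    rate, z_thresh=1.5, min_area_um2=0.05,
                    cores=pn.CoreSet.from_arrays(layout.cores.x_nm,
                                                 layout.cores.y_nm,
                                                 core_id=layout.cores.core_id))
                members = dict(zip(layout.cores.core_id,
                                   layout.cores.islet_id))
                by_islet = layout.cores.groupby("islet_id").core_id.apply(set)
                for _, row in regions.iterrows():
                    got = set(row.core_ids)
                    if not got:
                        continue
                    islets = {members[c] for c in got}
                    total += 1
                    if len(islets) == 1 and by_islet[islets.pop()] <= got:
                        together += 1
            frac[model] = together / max(total, 1)
        assert frac["islet_shared"] > frac["independent"]


class TestKymograph:
    def test_static_stack_gives_identical_columns(self):
        rng = np.random.default_rng(0)
        frame = rng.uniform(0, 50, (60, 60))
        stack = _stack([frame] * 4)
        kymo = pn.kymograph(stack, [[200.0, 500.0], [1500.0, 900.0]])
        assert np.allclose(kymo.values, kymo.values[:, :1])

    def test_height_is_arc_length_in_pixels(self):
        stack = _stack([np.zeros((80, 80))] * 2)
        poly = [[100.0, 100.0], [100.0 + 700.0, 100.0]]
        kymo = pn.kymograph(stack, poly)
        assert kymo.values.shape[0] == int(np.ceil(700.0 / PS))

    def test_blinking_core_trace_matches_truth(self):
        layout = row_layout([2000.0, 4000.0], 2000.0)
        osc = pn.OscSpec(components=[(0.03, 0.5)], phase_model="independent",
                         noise_sd_fraction=0.0, n_frames=40)
        stack, truth = pn.simulate_movie(layout, osc, noise=False, rng=3)
        kymo = pn.kymograph(stack, [[1000.0, 2000.0], [5000.0, 2000.0]],
                            width_nm=100.0)
        row = int(round((2000.0 - 1000.0) / PS))
        r = np.corrcoef(kymo.values[row], truth.signals[0])[0, 1]
        assert r > 0.99

    def test_degenerate_polyline_rejected(self):
        stack = _stack([np.zeros((30, 30))] * 2)
        with pytest.raises(ValueError):
            pn.kymograph(stack, [[500.0, 500.0], [500.0, 500.0]])
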