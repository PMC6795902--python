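import numpy as np
import pytest
from scipy.stats import t as t_dist

from apdmap.containers import FluorescenceMovie
from apdmap.presets import get_preset
from apdmap.processing import (detect_beats, extract_beat_table,
                               grubbs_critical, grubbs_filter, pixel_qc,
                               spatial_filter, temporal_derivatives)
from apdmap.protocols import make_random
from apdmap.synth import (WaveformParams, build_parameter_maps, render_movie,
                          simulate_apd_series, _sigmoid, XSTAR,
                          _repol_detector_offset)


def movie_from_frames(frames, stim=(200.0, 500.0)):
    return FluorescenceMovie(frames=np.asarray(frames, dtype=float),
                             stim_times_ms=np.asarray(stim))


class TestSpatialFilter:
    def test_constant_frame_unchanged(self):
        m = movie_from_frames(np.full((5, 8, 8), 3.7))
        out = spatial_filter(m)
        np.testing.assert_allclose(out.frames, 3.7)

    def test_impulse_mass_preserved(self):
        f = np.zeros((1, 9, 9))
        f[0, 4, 4] = 1.0
        out = spatial_filter(movie_from_frames(f))
        assert out.frames.sum() == pytest.approx(1.0)
        assert out.frames[0, 4, 4] == pytest.approx(4 / 16)

    def test_linear_ramp_unchanged_in_interior(self):
        rr, cc = np.mgrid[0:10, 0:12]
        f = (2.0 * rr + 3.0 * cc - 5.0)[None].astype(float)
        out = spatial_filter(movie_from_frames(f))
        np.testing.assert_allclose(out.frames[0, 1:-1, 1:-1],
                                   f[0, 1:-1, 1:-1], atol=1e-12)

    def test_too_small_grid(self):
        with pytest.raises(ValueError):
            spatial_filter(movie_from_frames(np.zeros((2, 2, 2))))


class TestTemporalDerivatives:
    def test_cubic_reproduced_exactly(self):
        t = np.arange(60.0)
        x = 0.5 * t ** 3 - 2 * t ** 2 + 3 * t - 7
        d1, d2 = temporal_derivatives(x)
        inner = slice(6, -6)
        np.testing.assert_allclose(d1[inner],
                                   (1.5 * t ** 2 - 4 * t + 3)[inner],
                                   rtol=1e-9)
        np.testing.assert_allclose(d2[inner], (3 * t - 4)[inner], rtol=1e-9)

    def test_sine_derivative_accuracy(self):
        f = 5.0  # Hz
        t = np.arange(0, 1000.0)  # ms
        x = np.sin(2 * np.pi * f * t / 1000.0)
        d1, _ = temporal_derivatives(x)
        true = 2 * np.pi * f / 1000.0 * np.cos(2 * np.pi * f * t / 1000.0)
        assert np.abs(d1[10:-10] - true[10:-10]).max() < 2e-4

    def test_constant_trace_zero_derivatives(self):
        d1, d2 = temporal_derivatives(np.full(40, 2.0))
        np.testing.assert_allclose(d1, 0.0, atol=1e-12)
        np.testing.assert_allclose(d2, 0.0, atol=1e-12)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            temporal_derivatives(np.zeros(12))


class TestDetectBeats:
    def make_trace(self, act_times, apds, T=1200, tau_dn=3.0):
        t = np.arange(float(T))
        f = np.zeros(T)
        off = _repol_detector_offset(tau_dn)
        for a, d in zip(act_times, apds):
            c = a + d - XSTAR * tau_dn - off
            f += _sigmoid((t - a) / 1.5) - _sigmoid((t - c) / tau_dn)
        return f

    def test_round_trip_on_templates(self):
        acts = [200.3, 480.9, 770.4]
        apds = [180.0, 165.5, 201.2]
        f = self.make_trace(acts, apds)
        act, rep, ok = detect_beats(f, np.array([195.0, 475.0, 765.0]))
        assert ok.all()
        np.testing.assert_allclose(act, acts, atol=0.5)
        np.testing.assert_allclose(rep - act, apds, atol=1.0)

    def test_flat_trace_all_invalid(self):
        act, rep, ok = detect_beats(np.zeros(900),
                                    np.array([200.0, 500.0]))
        assert not ok.any()
        assert np.isnan(act).all()

    def test_tie_broken_to_earlier_index(self):
        # two identical upstrokes inside one stimulus window: dF/dt maxima
        # are bit-identical, the earlier one must win
        f = self.make_trace([300.0, 500.0], [150.0, 150.0], T=1000)
        act, rep, ok = detect_beats(f, np.array([250.0]))
        assert ok[0]
        assert abs(act[0] - 300.0) < 1.0


class TestPixelQC:
    @pytest.fixture(scope="class")
    def noisy_movie(self):
        rng = np.random.default_rng(0)
        p = get_preset("lqt2")
        maps = build_parameter_maps(p, grid=(10, 10), seed=0)
        maps.amplitude[:] = 1.0
        maps.amplitude[4, 4] = 0.0      # dead pixel
        maps.amplitude[5, 5] = 10.0     # strong pixel
        prot = make_random(p.erp_ms, 50, n_beats=6, seed=0)
        beats = simulate_apd_series(maps, prot, noise_sd=0, seed=0)
        return render_movie(beats, maps, snr=50.0, seed=0)

    def test_dead_pixel_excluded_strong_included(self, noisy_movie):
        mask = pixel_qc(noisy_movie, exclude_edge=False)
        assert not mask.include[4, 4]
        assert mask.reasons["low_snr"][4, 4]
        assert mask.include[5, 5]

    def test_noise_free_pixel_included_at_zero_threshold(self):
        p = get_preset("lqt2")
        maps = build_parameter_maps(p, grid=(10, 10), seed=1)
        prot = make_random(p.erp_ms, 50, n_beats=5, seed=1)
        beats = simulate_apd_series(maps, prot, noise_sd=0, seed=1)
        movie = render_movie(beats, maps, snr=np.inf, seed=1)
        mask = pixel_qc(movie, exclude_edge=False)
        assert mask.include.all()

    def test_edge_reason_code(self, noisy_movie):
        mask = pixel_qc(noisy_movie, exclude_edge=True)
        assert mask.reasons["edge"][0, 0]
        assert not mask.include[0, :].any()

    def test_requires_baseline(self, noisy_movie):
        short = FluorescenceMovie(frames=noisy_movie.frames[150:],
                                  stim_times_ms=noisy_movie.stim_times_ms - 150)
        with pytest.raises(ValueError):
            pixel_qc(short)

    def test_qc_monotone_in_snr(self):
        # weak pixels survive at high SNR and are excluded as noise grows
        p = get_preset("lqt2")
        counts = []
        for snr in (40.0, 3.0):
            ns = []
            for seed in range(3):
                maps = build_parameter_maps(p, grid=(12, 12), seed=seed)
                maps.amplitude[:] = 1.0
                maps.amplitude[::3, ::3] = 0.1  # weak pixels
                prot = make_random(p.erp_ms, 50, n_beats=6, seed=seed)
                beats = simulate_apd_series(maps, prot, noise_sd=0, seed=seed)
                movie = render_movie(beats, maps, snr=snr, seed=seed)
                ns.append(pixel_qc(movie, exclude_edge=False).n_included)
            counts.append(np.mean(ns))
        assert counts[1] < counts[0]


class TestGrubbs:
    def test_worked_example(self):
        vals = np.array([100.0, 101, 99, 102, 100, 140])
        out = grubbs_filter(vals, alpha=0.05)
        assert out.tolist() == [False] * 5 + [True]
        # oracle: Grubbs statistic and critical value from first principles
        g = np.abs(vals - vals.mean()).max() / vals.std(ddof=1)
        n = 6
        tq = t_dist.ppf(1 - 0.05 / (2 * n), n - 2)
        gcrit = (n - 1) / np.sqrt(n) * np.sqrt(tq ** 2 / (n - 2 + tq ** 2))
        assert g == pytest.approx(2.0372, abs=1e-4)
        assert gcrit == pytest.approx(grubbs_critical(6, 0.05))
        assert g > gcrit

    def test_all_equal_none_removed(self):
        assert not grubbs_filter(np.full(10, 5.0)).any()

    def test_symmetric_extremes_removed_one_per_iteration(self):
        # one-at-a-time removal: both symmetric extremes eventually flagged
        vals = np.array([10.0] * 18 + [10 - 6, 10 + 6])
        out = grubbs_filter(vals, alpha=0.05)
        assert out[-2:].all() and not out[:-2].any()

    def test_too_few_values_no_test(self):
        assert not grubbs_filter(np.array([1.0, 2.0])).any()

    def test_false_positive_rate_bounded(self):
        # clean Gaussian maps: removal fraction stays near the alpha level
        rng = np.random.default_rng(1)
        fracs = [grubbs_filter(rng.normal(180, 5, 400), 0.05).mean()
                 for _ in range(30)]
        assert np.mean(fracs) <= 0.05

    def test_grubbs_removes_outlier_pixel_in_chain(self):
        p = get_preset("lqt1")
        maps = build_parameter_maps(p, grid=(10, 10), seed=3)
        # one aberrant pixel: gross APD offset via the intercept
        maps.c_ms[5, 5] += 30.0
        prot = make_random(p.erp_ms, 50, n_beats=8, seed=3)
        beats = simulate_apd_series(maps, prot, noise_sd=0, seed=3)
        movie = render_movie(beats, maps, snr=np.inf, seed=3)
        # unfiltered: 3x3 smoothing would blend the single aberrant pixel
        # into its neighbours before the outlier test could see it
        table = extract_beat_table(movie, apply_grubbs=True,
                                   apply_spatial_filter=False)
        assert not table.valid[3:, 5, 5].any()
        assert table.meta["n_grubbs_removed"] > 0


class TestExtractBeatTable:
    def test_cl_from_consecutive_activations(self, lqt2_scan):
        meas = lqt2_scan.measured
        cl = meas.cl_prev_ms
        act = meas.activation_ms
        ok = np.isfinite(cl)
        np.testing.assert_allclose(cl[ok], (act[1:] - act[:-1])[ok[1:]])

    def test_noise_free_apds_match_ground_truth(self):
        p = get_preset("lqt1")  # mild heterogeneity: the 3x3 smoothing
        maps = build_parameter_maps(p, grid=(16, 16), seed=2)  # blends
        prot = make_random(p.erp_ms, 50, n_beats=8, seed=2)  # little here
        truth = simulate_apd_series(maps, prot, noise_sd=0, seed=2)
        movie = render_movie(truth, maps, snr=np.inf, seed=2)
        meas = extract_beat_table(movie)
        ok = meas.valid & truth.valid
        err = (meas.apd_ms - (truth.repol_ms - truth.activation_ms))[ok]
        assert np.abs(err).max() < 3.0
        assert np.abs(np.median(err)) < 1.0  # detector bias

    def test_masked_pixel_absent_from_maps(self, lqt2_scan):
        meas = lqt2_scan.measured
        excluded = ~meas.pixel_include
        assert np.isnan(meas.apd_map(5)[excluded]).all()

    def test_requires_two_stimuli(self, lqt2_scan):
        with pytest.raises(ValueError):
            extract_beat_table(lqt2_scan.movie, stim_times=np.array([200.0]))
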