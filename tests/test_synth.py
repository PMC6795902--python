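import dataclasses

import numpy as np
import pytest

from apdmap.containers import BeatTable
from apdmap.presets import PRESETS, get_preset
from apdmap.protocols import make_random
from apdmap.synth import (build_parameter_maps, read_movie, render_movie,
                          simulate_apd_series, write_movie)
from conftest import make_uniform_maps

LQT2 = get_preset("lqt2")


def protocol_from_cls(cls):
    from apdmap.protocols import _from_cls
    return _from_cls("random", np.asarray(cls, float), {})


class TestParameterMaps:
    @pytest.mark.parametrize("name", sorted(PRESETS))
    def test_exact_sample_moments(self, name):
        p = get_preset(name)
        maps = build_parameter_maps(p, grid=(40, 40), seed=5)
        a1, a2 = maps.alpha
        if p.transmural:
            endo = maps.region_mask("endo")
            assert a1[endo].mean() == pytest.approx(p.region_alpha1[0],
                                                    abs=1e-9)
            assert a1[~endo].mean() == pytest.approx(p.region_alpha1[1],
                                                     abs=1e-9)
        else:
            assert a1.mean() == pytest.approx(p.mean_alpha1, abs=1e-9)
            assert a1.std() == pytest.approx(p.sd_alpha1_map, abs=1e-9)
        assert a2.mean() == pytest.approx(p.mean_alpha2, abs=1e-9)
        r = np.corrcoef(a1.ravel(), a2.ravel())[0, 1]
        # target correlation holds exactly by construction (spec band 0.05)
        assert r == pytest.approx(p.corr_alpha1_alpha2, abs=1e-9)

    def test_zero_heterogeneity_gives_uniform_map(self):
        p = dataclasses.replace(LQT2, sd_alpha1_map=0.0)
        maps = build_parameter_maps(p, grid=(16, 16), seed=0)
        assert maps.alpha[0].std() == 0.0

    def test_gain_pattern_orthogonal_to_coefficient_maps(self):
        maps = build_parameter_maps(LQT2, grid=(32, 32), seed=2)
        for j in (0, 1):
            dev = maps.alpha[j] - maps.alpha[j].mean()
            assert abs((dev * maps.apd_pattern_ms).mean()) < 1e-9

    def test_invalid_corr_target(self):
        p = dataclasses.replace(LQT2, corr_alpha1_alpha2=1.0)
        with pytest.raises(ValueError):
            build_parameter_maps(p, grid=(16, 16), seed=0)

    def test_small_grid_rejected(self):
        with pytest.raises(ValueError):
            build_parameter_maps(LQT2, grid=(4, 4), seed=0)


class TestSimulate:
    def test_hand_computed_apd(self, uniform_maps):
        # C=150, a1=0.32, a2=-0.053; CL_{n-1}=300, CL_{n-2}=250
        prot = protocol_from_cls([250, 300])
        beats = simulate_apd_series(uniform_maps, prot, noise_sd=0, seed=0)
        apd = beats.repol_ms[2] - beats.activation_ms[2]
        np.testing.assert_allclose(apd, 150 + 0.32 * 300 - 0.053 * 250)
        assert float(np.unique(apd.round(9))[0]) == pytest.approx(232.75)

    def test_zero_coefficients_give_constant_apd(self):
        maps = make_uniform_maps(c=180.0, alpha=(0.0, 0.0))
        prot = make_random(250, 50, n_beats=12, seed=1)
        beats = simulate_apd_series(maps, prot, noise_sd=0, seed=0)
        apd = beats.repol_ms - beats.activation_ms
        np.testing.assert_allclose(apd, 180.0)

    def test_memory_term_contribution_28ms(self):
        # a 700-ms increase of CL_{n-2} at |a2| = 0.04 shifts APD by 28 ms
        maps = make_uniform_maps(c=150.0, alpha=(0.0, -0.04))
        short = simulate_apd_series(maps, protocol_from_cls([300, 300]),
                                    noise_sd=0, seed=0)
        long_ = simulate_apd_series(maps, protocol_from_cls([1000, 300]),
                                    noise_sd=0, seed=0)
        apd_s = (short.repol_ms - short.activation_ms)[2]
        apd_l = (long_.repol_ms - long_.activation_ms)[2]
        np.testing.assert_allclose(apd_s - apd_l, 28.0, atol=1e-9)

    def test_first_k_beats_invalid(self):
        maps = make_uniform_maps(c=140.0)
        prot = make_random(250, 50, n_beats=10, seed=3)
        beats = simulate_apd_series(maps, prot, noise_sd=0, seed=0)
        assert not beats.valid[:2].any()
        assert beats.valid[2:].all()

    def test_activation_map_affine_in_distance(self, uniform_maps):
        prot = make_random(250, 50, n_beats=5, seed=2)
        beats = simulate_apd_series(uniform_maps, prot, noise_sd=0, seed=0,
                                    t0_ms=150.0)
        delay = beats.activation_ms[3] - (150.0 + prot.stim_times_ms[3])
        np.testing.assert_allclose(delay, uniform_maps.conduction_delay_ms(),
                                   atol=1e-9)

    def test_blocked_beat_flagged_not_captured(self):
        maps = make_uniform_maps(c=240.0, alpha=(0.0, 0.0))
        prot = protocol_from_cls([250, 250, 250])
        beats = simulate_apd_series(maps, prot, noise_sd=0, seed=0,
                                    di_min=20.0)
        # APD 240 at CL 250 leaves DI 10 < 20: every other beat blocked
        assert beats.meta["n_blocked"] > 0
        assert not beats.valid[1].any()

    def test_determinism(self):
        maps = build_parameter_maps(LQT2, grid=(12, 12), seed=4)
        prot = make_random(LQT2.erp_ms, 50, n_beats=15, seed=4)
        kw = dict(noise_sd=2.0, dispersion_gain_sd=0.4, seed=9)
        a = simulate_apd_series(maps, prot, **kw)
        b = simulate_apd_series(maps, prot, **kw)
        np.testing.assert_array_equal(a.repol_ms, b.repol_ms)


class TestRenderAndIO:
    @pytest.fixture(scope="class")
    def small_movie(self):
        maps = build_parameter_maps(LQT2, grid=(12, 12), seed=1)
        prot = make_random(LQT2.erp_ms, 50, n_beats=8, seed=1)
        beats = simulate_apd_series(maps, prot, noise_sd=0, seed=1)
        movie = render_movie(beats, maps, snr=np.inf, seed=1)
        return maps, beats, movie

    def test_noise_free_detector_round_trip(self, small_movie):
        from apdmap.processing import extract_beat_table

        maps, truth, movie = small_movie
        # noise-free input: skip the 3x3 smoothing (a noise-suppression
        # step that would blend neighbouring pixels of this coarse grid)
        meas = extract_beat_table(movie, apply_grubbs=False,
                                  apply_spatial_filter=False)
        ok = meas.valid & truth.valid
        assert ok[2:].all()
        act_err = (meas.activation_ms - truth.activation_ms)[ok]
        rep_err = (meas.repol_ms - truth.repol_ms)[ok]
        assert np.abs(act_err).max() < 2.0
        assert np.abs(rep_err).max() < 3.0

    def test_movie_frame_count_covers_last_repolarization(self, small_movie):
        _, truth, movie = small_movie
        assert movie.n_frames >= np.nanmax(truth.repol_ms)
        assert movie.frame_interval_ms == 1.0

    def test_float_round_trip_bit_identical(self, small_movie, tmp_path):
        _, _, movie = small_movie
        write_movie(movie, tmp_path / "m.tif")
        back = read_movie(tmp_path / "m.tif")
        np.testing.assert_array_equal(back.frames, movie.frames)
        np.testing.assert_array_equal(back.stim_times_ms, movie.stim_times_ms)

    def test_16bit_quantization_bound(self, small_movie, tmp_path):
        _, _, movie = small_movie
        write_movie(movie, tmp_path / "q.tif", quantize_16bit=True)
        back = read_movie(tmp_path / "q.tif")
        step = (movie.frames.max() - movie.frames.min()) / 65535.0
        err = np.abs(back.frames.astype(np.float64)
                     - movie.frames.astype(np.float64))
        assert err.max() <= step / 2 + 1e-6

    def test_missing_sidecar_field_rejected(self, small_movie, tmp_path):
        import json
        _, _, movie = small_movie
        write_movie(movie, tmp_path / "bad.tif")
        sc = tmp_path / "bad.json"
        doc = json.loads(sc.read_text())
        del doc["stim_times_ms"]
        sc.write_text(json.dumps(doc))
        with pytest.raises(ValueError, match="stim_times_ms"):
            read_movie(tmp_path / "bad.tif")

    def test_render_rejects_bad_snr(self, small_movie):
        maps, beats, _ = small_movie
        with pytest.raises(ValueError):
            render_movie(beats, maps, snr=0.0)

    def test_render_determinism(self, small_movie):
        maps, beats, _ = small_movie
        a = render_movie(beats, maps, snr=20.0, seed=5)
        b = render_movie(beats, maps, snr=20.0, seed=5)
        np.testing.assert_array_equal(a.frames, b.frames)
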