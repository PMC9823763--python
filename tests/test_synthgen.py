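"""Unit tests for the synthetic generator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emoradar import synthgen
from emoradar.synthgen import (
    EMOTIONS, DisplacementModel, RadarConfig, SlowTimeSeries, StaticReflector,
    analytic_profile, default_presets, default_profile, load_cube,
    make_dataset, make_displacement, read_raw_int16, reduced_profile,
    render_face_frames, save_cube, simulate_if_cube,
)


class TestRadarConfig:
    def test_slope_bandwidth_invariant_holds_by_construction(self):
        for cfg in (default_profile(), analytic_profile(), reduced_profile()):
            assert cfg.freq_slope * cfg.chirp_duration == pytest.approx(
                cfg.bandwidth, rel=1e-12)

    def test_default_profile_values(self):
        cfg = default_profile()
        assert cfg.carrier_freq == 77e9
        assert cfg.bandwidth == 4e9
        assert cfg.chirp_duration == 60e-6
        assert cfg.frame_rate == pytest.approx(20.0)
        assert cfg.freq_slope == pytest.approx(4e9 / 60e-6)

    def test_analytic_profile_slope(self):
        cfg = analytic_profile()
        assert cfg.freq_slope == pytest.approx(50e12)  # 50 MHz/us
        assert cfg.chirp_duration == 40e-6

    def test_wavelength(self):
        assert default_profile().wavelength == pytest.approx(
            299792458.0 / 77e9)

    def test_round_trip_dict(self):
        cfg = default_profile()
        assert RadarConfig.from_dict(cfg.to_dict()) == cfg

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            RadarConfig(carrier_freq=-1, bandwidth=4e9, chirp_duration=60e-6,
                        frame_period=50e-3, chirps_per_frame=1,
                        samples_per_chirp=64, adc_rate=1e6)


class TestSlowTimeSeries:
    def test_csv_round_trip(self, tmp_path):
        s = SlowTimeSeries(values=np.sin(np.arange(50) / 7.0), rate=20.0,
                           units="mm")
        s.to_csv(tmp_path / "s.csv")
        back = SlowTimeSeries.from_csv(tmp_path / "s.csv")
        assert back.rate == s.rate and back.units == s.units
        np.testing.assert_allclose(back.values, s.values, atol=1e-8)

    def test_rejects_2d(self):
        with pytest.raises(ValueError):
            SlowTimeSeries(values=np.zeros((3, 3)), rate=20.0)

    def test_rejects_nan(self):
        with pytest.raises(ValueError):
            SlowTimeSeries(values=np.array([1.0, np.nan]), rate=20.0)


class TestDisplacementModel:
    def test_band_validation(self):
        with pytest.raises(ValueError):
            DisplacementModel(resp_freq=0.05)
        with pytest.raises(ValueError):
            DisplacementModel(heart_freq=4.0)

    def test_heart_smaller_than_resp(self):
        with pytest.raises(ValueError):
            DisplacementModel(resp_amplitude=0.3, heart_amplitude=0.4)

    def test_nyquist_guard(self):
        model = DisplacementModel(heart_freq=3.0)   # harmonic at 6 Hz
        with pytest.raises(ValueError, match="Nyquist"):
            make_displacement(model, duration=10.0, rate=10.0, seed=0)

    def test_noiseless_is_deterministic_and_periodic(self):
        model = DisplacementModel(noise_sd=0.0, heart_harmonics=())
        d = make_displacement(model, duration=20.0, rate=20.0, seed=0)
        t = d.times
        expected = (model.resp_amplitude * np.sin(2 * np.pi * model.resp_freq * t)
                    + model.heart_amplitude * np.sin(2 * np.pi * model.heart_freq * t))
        np.testing.assert_allclose(d.values, expected, atol=1e-12)

    def test_same_seed_same_noise(self):
        model = DisplacementModel(noise_sd=0.1)
        a = make_displacement(model, 10.0, 20.0, seed=7)
        b = make_displacement(model, 10.0, 20.0, seed=7)
        np.testing.assert_array_equal(a.values, b.values)


class TestSimulateCube:
    def test_shapes_and_dtype(self, reduced_config):
        model = DisplacementModel()
        d = make_displacement(model, 5.0, reduced_config.frame_rate, seed=0)
        cube = simulate_if_cube(reduced_config, d, seed=0)
        assert cube.data.shape == (100, reduced_config.chirps_per_frame,
                                   reduced_config.samples_per_chirp)
        assert cube.data.dtype == np.float32
        cube_iq = simulate_if_cube(reduced_config, d, seed=0, complex_iq=True)
        assert cube_iq.data.dtype == np.complex64

    def test_static_only_needs_n_frames(self, reduced_config):
        with pytest.raises(ValueError):
            simulate_if_cube(reduced_config, None,
                             statics=[StaticReflector(0.9, 1.0)])

    def test_static_only_frames_identical_without_noise(self, reduced_config):
        cube = simulate_if_cube(reduced_config, None,
                                statics=[StaticReflector(0.9, 1.0)],
                                n_frames=10, seed=0)
        for f in range(1, 10):
            np.testing.assert_array_equal(cube.data[f], cube.data[0])

    def test_rejects_out_of_range_reflector(self, reduced_config):
        r = reduced_config.max_unambiguous_range * 1.01
        with pytest.raises(ValueError, match="unambiguous"):
            simulate_if_cube(reduced_config, None,
                             statics=[StaticReflector(r, 1.0)], n_frames=2)

    def test_if_tone_frequency_matches_closed_form(self, reduced_config):
        """The dominant fast-time frequency must sit at f_IF = 2 s R / c."""
        r = 0.5
        cube = simulate_if_cube(reduced_config, None,
                                statics=[StaticReflector(r, 1.0)],
                                n_frames=1, complex_iq=True)
        spec = np.abs(np.fft.fft(cube.data[0, 0]))
        ns = reduced_config.samples_per_chirp
        peak = np.argmax(spec[:ns // 2])
        f_if = 2 * reduced_config.freq_slope * r / synthgen.SPEED_OF_LIGHT
        assert peak == round(f_if / reduced_config.adc_rate * ns)

    def test_deterministic_given_seed(self, reduced_config):
        model = DisplacementModel()
        d = make_displacement(model, 3.0, reduced_config.frame_rate, seed=1)
        a = simulate_if_cube(reduced_config, d, phase_noise_sd=0.05, seed=3)
        b = simulate_if_cube(reduced_config, d, phase_noise_sd=0.05, seed=3)
        np.testing.assert_array_equal(a.data, b.data)


class TestCubeIO:
    def test_h5_round_trip(self, tmp_path, reduced_config):
        model = DisplacementModel()
        d = make_displacement(model, 2.0, reduced_config.frame_rate, seed=0)
        cube = simulate_if_cube(reduced_config, d, seed=0)
        save_cube(cube, tmp_path / "c.h5")
        back = load_cube(tmp_path / "c.h5")
        np.testing.assert_array_equal(back.data, cube.data)
        assert back.config == cube.config

    def test_read_raw_int16(self, tmp_path, reduced_config):
        nf, nc, ns = 3, reduced_config.chirps_per_frame, \
            reduced_config.samples_per_chirp
        raw = np.arange(nf * nc * ns, dtype=np.int16)
        raw.tofile(tmp_path / "raw.bin")
        cube = read_raw_int16(tmp_path / "raw.bin", reduced_config)
        assert cube.data.shape == (nf, nc, ns)
        assert cube.data[0, 0, 1] == pytest.approx(1.0 / 32768)

    def test_read_raw_rejects_partial_frame(self, tmp_path, reduced_config):
        np.arange(100, dtype=np.int16).tofile(tmp_path / "bad.bin")
        with pytest.raises(ValueError):
            read_raw_int16(tmp_path / "bad.bin", reduced_config)


class TestPresetsAndFaces:
    def test_presets_cover_emotions(self):
        presets = default_presets()
        assert set(presets) == set(EMOTIONS)

    def test_preset_boxes_within_physiological_bands(self):
        for p in default_presets().values():
            assert 0.1 <= p.resp_freq[0] <= p.resp_freq[1] <= 0.6
            assert 0.8 <= p.heart_freq[0] <= p.heart_freq[1] <= 3.3
            assert p.heart_amplitude[1] < p.resp_amplitude[0]

    def test_preset_amplitudes_bound_phase_step(self):
        """Worst-case per-frame phase step must stay below pi (no unwrap
        aliasing): ~1.01 rad per mm*Hz at 77 GHz / 20 fps per component."""
        lam_mm = 299792458.0 / 77e9 * 1e3
        coef = 4 * np.pi / lam_mm * 2 * np.pi / 20.0
        for p in default_presets().values():
            step = coef * (p.resp_amplitude[1] * p.resp_freq[1]
                           + p.heart_amplitude[1] * p.heart_freq[1]
                           + 0.3 * p.heart_amplitude[1] * 2 * p.heart_freq[1])
            assert step < np.pi - 0.5, f"{p.label} risks unwrap aliasing"

    def test_render_shapes_and_determinism(self):
        p = default_presets()["happy"]
        a = render_face_frames(p, 12, size=64, seed=5)
        b = render_face_frames(p, 12, size=64, seed=5)
        assert a.shape == (12, 64, 64, 3) and a.dtype == np.uint8
        np.testing.assert_array_equal(a, b)

    def test_zero_jitter_gives_identical_frames(self):
        p = default_presets()["sad"]
        frames = render_face_frames(p, 11, size=64, seed=2, jitter=0.0)
        for f in range(1, 11):
            np.testing.assert_array_equal(frames[f], frames[0])

    def test_needs_eleven_frames(self):
        with pytest.raises(ValueError):
            render_face_frames(default_presets()["happy"], 10)


class TestMakeDataset:
    def test_balance_metadata_and_determinism(self):
        a = make_dataset(n_per_class=2, seed=9, duration=10.0,
                         n_face_frames=11, face_size=64)
        b = make_dataset(n_per_class=2, seed=9, duration=10.0,
                         n_face_frames=11, face_size=64)
        assert len(a) == 8
        labels = [t.label for t in a]
        assert all(labels.count(e) == 2 for e in EMOTIONS)
        presets = default_presets()
        for t in a:
            p = presets[t.label]
            assert p.resp_freq[0] <= t.resp_freq_true <= p.resp_freq[1]
            assert p.heart_freq[0] <= t.heart_freq_true <= p.heart_freq[1]
            assert 0 <= t.seed < 2 ** 31
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.cube.data, y.cube.data)
            np.testing.assert_array_equal(x.face_frames, y.face_frames)

    def test_save_load_round_trip(self, tmp_path):
        trials = make_dataset(n_per_class=1, seed=4, duration=5.0,
                              n_face_frames=11, face_size=64)
        synthgen.save_dataset(trials, tmp_path)
        back = synthgen.load_dataset(tmp_path)
        assert len(back) == len(trials)
        by_id = {t.sample_id: t for t in back}
        for t in trials:
            r = by_id[t.sample_id]
            assert r.label == t.label and r.subject_id == t.subject_id
            np.testing.assert_allclose(r.cube.data, t.cube.data, atol=1e-6)
            np.testing.assert_array_equal(r.face_frames, t.face_frames)


@settings(max_examples=20, deadline=None)
@given(resp=st.floats(0.1, 0.6), heart=st.floats(0.8, 3.3),
       seed=st.integers(0, 2 ** 16))
def test_displacement_amplitude_bounded(resp, heart, seed):
    """|d| never exceeds the sum of component amplitudes + noise tails."""
    model = DisplacementModel(resp_amplitude=2.0, resp_freq=resp,
                              heart_amplitude=0.3, heart_freq=heart,
                              noise_sd=0.01)
    d = make_displacement(model, duration=10.0, rate=20.0, seed=seed)
    bound = 2.0 + 0.3 + 0.3 * 0.3 + 6 * 0.01
    assert np.max(np.abs(d.values)) <= bound
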