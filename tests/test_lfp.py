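"""LFP pipeline: filtering, gradients, events, paths, and feature estimates."""
import math

import numpy as np
import pytest
from scipy import stats

import termwave as tw
from termwave.lfp import Path, _smooth


def _sine_array(freq_hz, fs, dur_s=2.0, amp=1.0):
    t = np.arange(int(dur_s * fs)) / fs
    x = amp * np.sin(2 * np.pi * freq_hz * t)
    return np.tile(x[:, None, None], (1, 10, 10))


class TestPreprocess:
    def test_dc_offset_removed(self):
        raw = np.full((30000, 10, 10), 7.5)
        rec = tw.preprocess_lfp(raw, fs_in=30000.0)
        assert abs(rec.voltage.mean()) < 1e-10 * 7.5

    def test_passband_amplitude_preserved(self):
        rec = tw.preprocess_lfp(_sine_array(25.0, 30000.0), fs_in=30000.0)
        mid = rec.voltage[len(rec.voltage) // 4 : -len(rec.voltage) // 4, 0, 0]
        assert mid.max() == pytest.approx(1.0, rel=0.05)

    def test_stopband_attenuation_exceeds_40db(self):
        rec = tw.preprocess_lfp(_sine_array(500.0, 30000.0), fs_in=30000.0)
        mid = rec.voltage[len(rec.voltage) // 4 : -len(rec.voltage) // 4, 0, 0]
        assert mid.max() < 10 ** (-40 / 20)

    def test_output_rate_is_5000(self):
        rec = tw.preprocess_lfp(_sine_array(10.0, 30000.0), fs_in=30000.0)
        assert rec.sampling_rate == pytest.approx(5000.0)

    def test_low_input_rate_rejected(self):
        with pytest.raises(ValueError):
            tw.preprocess_lfp(np.zeros((100, 10, 10)), fs_in=80.0)

    def test_all_nan_channel_masked(self):
        raw = _sine_array(10.0, 30000.0)
        raw[:, 3, 4] = np.nan
        rec = tw.preprocess_lfp(raw, fs_in=30000.0)
        assert not rec.mask[3, 4]
        assert rec.mask.sum() == 99


class TestGradientField:
    @pytest.fixture()
    def plane_rec(self):
        a, b = 2.0e-3, -1.0e-3  # per um
        rows, cols = np.meshgrid(np.arange(10), np.arange(10), indexing="ij")
        frame = a * cols * 400.0 + b * rows * 400.0
        v = np.tile(frame[None], (10, 1, 1))
        return tw.ArrayRecording(voltage=v, sampling_rate=5000.0), a, b

    def test_linear_plane_gives_exact_constant_gradient(self, plane_rec):
        rec, a, b = plane_rec
        gx, gy, mag, ang = tw.gradient_field(rec, 0)
        interior = np.s_[1:-1, 1:-1]
        assert np.allclose(gx[interior], a, atol=1e-15)
        assert np.allclose(gy[interior], b, atol=1e-15)

    def test_uniform_field_gives_zero_magnitudes(self):
        rec = tw.ArrayRecording(voltage=np.ones((5, 10, 10)), sampling_rate=5000.0)
        _gx, _gy, mag, _ang = tw.gradient_field(rec, 0)
        assert np.nanmax(mag) == 0.0

    def test_masked_neighbors_omit_vector(self):
        v = np.random.default_rng(0).standard_normal((3, 10, 10))
        mask = np.ones((10, 10), bool)
        mask[4, 4] = False
        rec = tw.ArrayRecording(voltage=v, sampling_rate=5000.0, mask=mask)
        _gx, _gy, mag, _ang = tw.gradient_field(rec, 0)
        # electrodes flanking the dead channel lose their central difference
        assert np.isnan(mag[4, 3]) and np.isnan(mag[4, 5])

    def test_descent_angle_tracks_wave_direction(self):
        """Noise-free plane wave: descent angles align with propagation."""
        spec = tw.SynthSpec(speed=200.0, width=3000.0, direction=0.0,
                            tau=None, noise_sd=0.0)
        rec = tw.synth_plane_wave_recording(spec)
        z = tw.zscore(rec)
        # while the crest enters: pick the moment the center first exceeds 1
        center = z[:, 4:6, 4:6].mean(axis=(1, 2))
        t_idx = int(np.flatnonzero(center > 1.0)[0])
        _gx, _gy, mag, ang = tw.gradient_field(rec, t_idx, use_z=z)
        desc = (ang + 180.0) % 360.0
        ok = np.isfinite(mag) & (mag > 0)
        mean_angle = np.degrees(math.atan2(
            np.sum(mag[ok] * np.sin(np.radians(desc[ok]))),
            np.sum(mag[ok] * np.cos(np.radians(desc[ok])))))
        assert abs((mean_angle + 180) % 360 - 180) < 5.0


class TestAngleHistogram:
    def test_single_direction_concentrates_in_one_bin(self):
        angles = np.full(20, 90.0)
        mags = np.full(20, 2.0)
        _c, w, peak = tw.angle_histogram(angles, mags)
        assert w.max() == pytest.approx(40.0)
        assert (w > 0).sum() == 1
        assert peak == pytest.approx(95.0)  # center of the [90, 100) bin

    def test_total_weight_is_conserved(self):
        rng = np.random.default_rng(3)
        angles = rng.uniform(0, 360, 500)
        mags = rng.uniform(0, 2, 500)
        _c, w, _p = tw.angle_histogram(angles, mags)
        assert w.sum() == pytest.approx(mags.sum())

    def test_isotropic_vectors_are_statistically_flat(self):
        rng = np.random.default_rng(4)
        angles = rng.uniform(0, 360, 20000)
        mags = np.ones(20000)
        _c, w, _p = tw.angle_histogram(angles, mags)
        assert w.max() < 3.0 * w.mean()

    def test_all_zero_magnitudes_flagged_empty(self):
        _c, w, peak = tw.angle_histogram([10.0, 20.0], [0.0, 0.0])
        assert peak is None


class TestEventDetection:
    def test_pure_noise_has_no_events(self):
        rng = np.random.default_rng(11)
        rec = tw.ArrayRecording(
            voltage=rng.standard_normal((5000, 10, 10)), sampling_rate=5000.0)
        assert tw.detect_wave_events(rec) == []

    def test_single_wave_single_event_with_direction(self):
        spec = tw.SynthSpec(speed=180.0, width=3000.0, direction=0.0, tau=60.0, seed=1)
        rec = tw.synth_plane_wave_recording(spec)
        events = tw.detect_wave_events(rec)
        assert len(events) == 1
        ev = events[0]
        assert abs((ev.theta0 + 180) % 360 - 180) <= 10.0
        assert ev.t_initial <= ev.t0 <= ev.t_final

    def test_two_separated_waves_give_two_events(self):
        spec = tw.SynthSpec(speed=200.0, width=2500.0, direction=0.0, tau=None,
                            seed=2, duration=2500.0)
        rec1 = tw.synth_plane_wave_recording(spec)
        v = rec1.voltage.copy()
        shift = int(1200 * rec1.sampling_rate / 1000)
        v[shift:] += rec1.voltage[:-shift]
        rec = tw.ArrayRecording(voltage=v, sampling_rate=rec1.sampling_rate)
        events = tw.detect_wave_events(rec)
        assert len(events) == 2
        for ev in events:
            assert ev.t_initial <= ev.t0 <= ev.t_final


class TestBuildPaths:
    def _event(self, theta):
        return tw.WaveEvent(t0=100.0, theta0=theta, theta1=(theta + 180) % 360,
                            t_initial=90.0, t_final=130.0)

    def _rec(self, rows=10, cols=10):
        return tw.ArrayRecording(
            voltage=np.zeros((10, rows, cols)), sampling_rate=5000.0)

    def test_near_axis_angle_gives_ten_horizontal_paths(self):
        ps = tw.build_paths(self._event(3.0), self._rec())
        assert ps.direction_deg == 0.0
        assert len(ps.paths) == 10
        assert all(p.complete and len(p.electrodes) == 10 for p in ps.paths)
        assert all(p.step_um == 400.0 for p in ps.paths)
        # last electrode is the one farthest along +x
        assert all(p.last_electrode[1] == 9 for p in ps.paths)

    def test_diagonal_angle_keeps_only_long_diagonals(self):
        ps = tw.build_paths(self._event(44.0), self._rec())
        assert ps.direction_deg == 45.0
        complete = [p for p in ps.paths if p.complete]
        assert len(complete) == 1  # only the main diagonal reaches 10
        assert complete[0].step_um == pytest.approx(400.0 * math.sqrt(2))
        assert all(len(p.electrodes) >= 6 for p in ps.paths)

    def test_half_array_rejects_short_horizontal_paths(self):
        """A 10x5 array cannot host 10-electrode paths along x; pieces of
        length 5 fall below the degraded-quality minimum and are dropped."""
        ps = tw.build_paths(self._event(0.0), self._rec(rows=10, cols=5))
        assert ps.paths == ()

    def test_masked_channel_splits_lines(self):
        rec = self._rec()
        rec.mask[0, 3] = False
        ps = tw.build_paths(self._event(0.0), rec)
        row0 = [p for p in ps.paths if all(e[0] == 0 for e in p.electrodes)]
        assert len(row0) == 1  # the 6-electrode remainder [4..9]
        assert not row0[0].complete and len(row0[0].electrodes) == 6


class TestPathEstimates:
    @staticmethod
    def _recording_with_onsets(onsets_ms, fs=5000.0, dur_ms=600.0, bump_ms=60.0):
        """Row-0 electrodes carry a transient bump starting at given times."""
        n = int(dur_ms * fs / 1000)
        rng = np.random.default_rng(0)
        v = 0.01 * rng.standard_normal((n, 10, 10))
        t = np.arange(n) * 1000.0 / fs
        for c, onset in enumerate(onsets_ms):
            with np.errstate(over="ignore"):
                rise = 1.0 / (1.0 + np.exp(-(t - onset) / 0.5))
                fall = 1.0 / (1.0 + np.exp(-(t - onset - bump_ms) / 0.5))
            v[:, 0, c] += 5.0 * (rise - fall)
        return tw.ArrayRecording(voltage=v, sampling_rate=fs)

    def _path(self):
        return Path(electrodes=tuple((0, c) for c in range(10)),
                    step_um=400.0, complete=True)

    def _event(self):
        return tw.WaveEvent(t0=150.0, theta0=0.0, theta1=180.0,
                            t_initial=100.0, t_final=250.0)

    def test_linear_onsets_recover_speed_exactly(self):
        c_true = 200.0  # um/ms -> 2 ms per electrode
        onsets = [120.0 + i * 400.0 / c_true for i in range(10)]
        rec = self._recording_with_onsets(onsets)
        v = tw.path_speed(self._path(), rec, self._event(), smooth_ms=0.0)
        assert v == pytest.approx(c_true, rel=0.02)

    def test_median_robust_to_one_corrupted_onset(self):
        c_true = 200.0
        onsets = [120.0 + i * 400.0 / c_true for i in range(10)]
        onsets[4] += 30.0  # one electrode fires grossly late
        rec = self._recording_with_onsets(onsets)
        v = tw.path_speed(self._path(), rec, self._event(), smooth_ms=0.0)
        assert v == pytest.approx(c_true, rel=0.10)

    def test_too_few_onsets_rejects_path(self):
        onsets = [120.0, 122.0, 124.0] + [450.0] * 7  # only 3 fire in-window
        rec = self._recording_with_onsets(onsets)
        assert tw.path_speed(self._path(), rec, self._event(), smooth_ms=0.0) is None

    def test_width_recovered_within_one_pitch(self):
        spec = tw.SynthSpec(speed=200.0, width=2000.0, direction=0.0, tau=None, seed=5)
        rec = tw.synth_plane_wave_recording(spec)
        ev = tw.detect_wave_events(rec)[0]
        path = tw.build_paths(ev, rec).paths[4]
        w, lb = tw.path_width(path, rec, ev)
        assert not lb
        assert w == pytest.approx(2000.0, abs=400.0)

    def test_wave_wider_than_path_is_lower_bound(self):
        spec = tw.SynthSpec(speed=200.0, width=6000.0, direction=0.0, tau=None, seed=6)
        rec = tw.synth_plane_wave_recording(spec)
        ev = tw.detect_wave_events(rec)[0]
        path = tw.build_paths(ev, rec).paths[4]
        w, lb = tw.path_width(path, rec, ev)
        assert lb and w == pytest.approx(3600.0)

    def test_flat_recording_rejected_for_width(self):
        rng = np.random.default_rng(8)
        rec = tw.ArrayRecording(
            voltage=0.1 * rng.standard_normal((2000, 10, 10)), sampling_rate=5000.0)
        ev = self._event()
        assert tw.path_width(self._path(), rec, ev) is None

    def test_reverberation_recovered_within_20_percent(self):
        spec = tw.SynthSpec(speed=180.0, width=3000.0, direction=0.0, tau=60.0, seed=7)
        rec = tw.synth_plane_wave_recording(spec)
        ev = tw.detect_wave_events(rec)[0]
        path = tw.build_paths(ev, rec).paths[4]
        tau = tw.path_reverberation(path, rec, ev)
        assert tau == pytest.approx(60.0, rel=0.20)

    def test_no_reverberation_gives_none(self):
        spec = tw.SynthSpec(speed=180.0, width=3000.0, direction=0.0, tau=None, seed=7)
        rec = tw.synth_plane_wave_recording(spec)
        ev = tw.detect_wave_events(rec)[0]
        path = tw.build_paths(ev, rec).paths[4]
        assert tw.path_reverberation(path, rec, ev) is None

    def test_reverberation_invariant_to_gain(self):
        spec = tw.SynthSpec(speed=180.0, width=3000.0, direction=0.0, tau=60.0, seed=9)
        rec = tw.synth_plane_wave_recording(spec)
        scaled = tw.ArrayRecording(voltage=rec.voltage * 37.5,
                                   sampling_rate=rec.sampling_rate)
        ev = tw.detect_wave_events(rec)[0]
        path = tw.build_paths(ev, rec).paths[4]
        t1 = tw.path_reverberation(path, rec, ev)
        t2 = tw.path_reverberation(path, scaled, ev)
        assert t1 == pytest.approx(t2, rel=1e-12)


class TestSummarizeWave:
    def test_textbook_two_sample_confidence_interval(self):
        """n=2, speeds {100, 120}: CI half-width = t_{0.95,1} * s / sqrt(2)."""
        s = tw.summarize_wave([100.0, 120.0], [], [])
        assert s.mean_speed == pytest.approx(110.0)
        half = stats.t.ppf(0.95, 1) * np.std([100, 120], ddof=1) / math.sqrt(2)
        assert half == pytest.approx(63.138, abs=1e-2)
        assert s.speed_ci[0] == pytest.approx(110 - half, abs=1e-9)
        assert s.speed_ci[1] == pytest.approx(110 + half, abs=1e-9)

    def test_identical_values_give_zero_width_interval(self):
        s = tw.summarize_wave([150.0, 150.0, 150.0], [], [])
        assert s.speed_ci[0] == pytest.approx(150.0)
        assert s.speed_ci[1] == pytest.approx(150.0)

    def test_single_path_has_undefined_interval(self):
        s = tw.summarize_wave([150.0], [2000.0], [50.0])
        assert s.mean_speed == 150.0
        assert s.speed_ci is None and s.width_ci is None


class TestPipelineInvariances:
    def test_rotation_equivariance(self):
        """Rotating the recording by 90 deg rotates the direction estimate
        and leaves speed/width essentially unchanged."""
        base = dict(speed=200.0, width=2800.0, tau=None, seed=13)
        df0 = tw.analyze_recording(
            tw.synth_plane_wave_recording(tw.SynthSpec(direction=0.0, **base)))
        df90 = tw.analyze_recording(
            tw.synth_plane_wave_recording(tw.SynthSpec(direction=90.0, **base)))
        assert len(df0) == len(df90) == 1
        dtheta = (df90.direction_deg[0] - df0.direction_deg[0]) % 360
        assert abs(dtheta - 90.0) <= 10.0
        assert df90.speed_um_per_ms[0] == pytest.approx(df0.speed_um_per_ms[0], rel=0.02)
        assert df90.width_um[0] == pytest.approx(df0.width_um[0], rel=0.02)

    def test_amplitude_invariance_of_all_outputs(self):
        spec = tw.SynthSpec(speed=220.0, width=2500.0, direction=0.0, tau=80.0, seed=14)
        rec = tw.synth_plane_wave_recording(spec)
        scaled = tw.ArrayRecording(voltage=rec.voltage * 0.002,
                                   sampling_rate=rec.sampling_rate)
        df1, df2 = tw.analyze_recording(rec), tw.analyze_recording(scaled)
        for col in ("speed_um_per_ms", "width_um", "tau_ms", "direction_deg"):
            assert df1[col][0] == pytest.approx(df2[col][0], rel=1e-9)
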