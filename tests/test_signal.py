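"""Signal chain: axis transforms, tilt correction, filtering, turn
splitting and wavelet gait-event detection."""

import numpy as np
import pytest
from scipy.signal import correlate

from stablegait.signal import AccelerationRecording, GaitEvents, \
    InsufficientStridesError, detect_gait_events, lowpass_filter, \
    split_segments, tilt_correct, transform_axes
from stablegait.synth import GaitProfile, generate_acceleration
from stablegait.synth.gait import _direction_segment

from conftest import match_events

FS = 100.0


def _recording(samples, fs=FS, **kw):
    t = np.arange(len(samples)) / fs
    return AccelerationRecording(t=t, samples=samples, sampling_rate=fs,
                                 **kw)


def _level_walk(n=800, fs=FS, amp=0.2):
    t = np.arange(n) / fs
    v = amp * np.sin(2 * np.pi * 2.0 * t) + 1.0
    s = np.stack([0.05 * np.sin(2 * np.pi * 2 * t),
                  np.zeros(n), v], axis=1)
    return _recording(s, fs)


class TestTransformAxes:
    def test_identity_mapping_is_noop(self):
        rec = _level_walk()
        out = transform_axes(rec, np.eye(3))
        np.testing.assert_array_equal(out.samples, rec.samples)

    def test_signed_swap_is_involution(self):
        rec = _level_walk()
        M = np.array([[0, 0, -1], [0, 1, 0], [-1, 0, 0]], dtype=float)
        out = transform_axes(transform_axes(rec, M), M)
        np.testing.assert_allclose(out.samples, rec.samples)

    def test_device_z_to_vertical_moves_gravity(self):
        rec = _level_walk()
        # device carried gravity on its x axis
        device = transform_axes(rec, np.array([[0., 0., 1.],
                                               [0., 1., 0.],
                                               [1., 0., 0.]]))
        back = transform_axes(device, np.array([[0., 0., 1.],
                                                [0., 1., 0.],
                                                [1., 0., 0.]]))
        assert abs(back.vertical.mean() - 1.0) < 0.01

    def test_rejects_non_permutation(self):
        with pytest.raises(ValueError):
            transform_axes(_level_walk(), np.ones((3, 3)))


class TestTiltCorrect:
    def test_level_recording_only_loses_gravity(self):
        rec = _level_walk()
        out = tilt_correct(rec)
        np.testing.assert_allclose(out.vertical, rec.vertical - 1.0,
                                   atol=1e-9)

    def test_known_static_tilt_is_removed(self):
        rec = _level_walk()
        a = np.deg2rad(5.0)
        R = np.array([[np.cos(a), 0, np.sin(a)], [0, 1, 0],
                      [-np.sin(a), 0, np.cos(a)]])
        tilted = rec.copy_with(samples=rec.samples @ R.T)
        out = tilt_correct(tilted)
        assert np.abs(out.samples[:, :2].mean(axis=0)).max() < 1e-6

    def test_idempotent(self):
        rec = _level_walk()
        once = tilt_correct(rec)
        twice = tilt_correct(once)
        np.testing.assert_allclose(twice.samples, once.samples, atol=1e-12)

    def test_free_fall_rejected(self):
        n = 400
        rec = _recording(np.random.default_rng(0).normal(0, 1e-4, (n, 3)))
        with pytest.raises(ValueError, match="free fall|near zero"):
            tilt_correct(rec)


class TestLowpass:
    def test_dc_passes_unchanged(self):
        x = np.full(500, 0.7)
        np.testing.assert_allclose(lowpass_filter(x, FS), x, atol=1e-9)

    def test_10hz_tone_strongly_attenuated(self):
        t = np.arange(1000) / FS
        x = np.sin(2 * np.pi * 10 * t)
        y = lowpass_filter(x, FS)
        assert np.abs(y[200:-200]).max() < 0.01

    def test_zero_phase_in_passband(self):
        t = np.arange(4000) / FS
        x = np.sin(2 * np.pi * 0.5 * t)
        y = lowpass_filter(x, FS)
        xc = correlate(y[500:-500], x[500:-500], mode="full")
        lag = np.argmax(xc) - (len(x) - 1000 - 1)
        assert lag == 0

    def test_rejects_cutoff_above_nyquist(self):
        with pytest.raises(ValueError):
            lowpass_filter(np.zeros(100), 10.0, cutoff=6.0)


class TestSplitSegments:
    def test_split_point_falls_in_turn_gap(self):
        prof = GaitProfile(0.55, 2.0, 0.18, 0.62)
        rec, gt = generate_acceleration(prof, seed=0, turn_duration=3.0)
        rec = lowpass_filter(tilt_correct(rec))
        seg1, seg2 = split_segments(rec)
        gap_start = gt[0].ic_times[-1]
        gap_end = gt[1].ic_times[0]
        assert gap_start < seg2.t[0] - 3.0 + 1e-9 < gap_end + 1e-9

    def test_trim_arithmetic(self):
        prof = GaitProfile(0.5, 1.0, 0.18, 0.62)
        rec, _ = generate_acceleration(prof, distance=10.0, seed=1)
        rec = lowpass_filter(tilt_correct(rec))
        seg1, _ = split_segments(rec, trim=3.0)
        raw1 = rec.t[rec.t <= seg1.t[-1] + 3.0 + 1e-9]
        assert seg1.duration == pytest.approx(
            (raw1[-1] - rec.t[0]) - 6.0, abs=0.1)

    def test_no_gap_raises_named_error(self):
        t = np.arange(3000) / FS
        v = 0.2 * np.sin(2 * np.pi * 2 * t)
        rec = _recording(np.stack([0 * v, 0 * v, v], axis=1))
        with pytest.raises(ValueError, match="turn"):
            split_segments(rec)

    def test_short_segment_rejected(self):
        t = np.arange(1200) / FS
        v = 0.2 * np.sin(2 * np.pi * 2 * t)
        v[500:700] = 0.0   # 2 s turn between two 5 s walks
        rec = _recording(np.stack([0 * v, 0 * v, v], axis=1))
        with pytest.raises(ValueError, match="trim"):
            split_segments(rec, trim=3.0)


class TestDetectGaitEvents:
    def test_regular_steps_recovered_exactly(self):
        """Noise-free 0.5 s steps: IC count matches ground truth and the
        mean absolute timing error stays below 30 ms at 100 Hz."""
        prof = GaitProfile(0.5, 0.0, 0.18, 0.62)
        rng = np.random.default_rng(0)
        t, x, onsets, _ = _direction_segment(prof, 40, FS, rng)
        events = detect_gait_events(lowpass_filter(x - x.mean(), FS), FS)
        n_truth, n_det, err = match_events(events.ic_times, onsets, t[-1])
        assert n_det == n_truth
        assert err.mean() < 0.03
        inner = events.ic_times[(events.ic_times > 2)
                                & (events.ic_times < t[-1] - 2)]
        np.testing.assert_allclose(np.diff(inner), 0.5, atol=0.02)

    @pytest.mark.parametrize("period", [0.4, 0.6, 0.8])
    def test_cov_recovered_across_step_periods(self, period):
        """Planted step-time CoV is recovered within one percentage
        point over long noise-free walks."""
        prof = GaitProfile(period, 3.0, 0.18, 0.62)
        rng = np.random.default_rng(3)
        t, x, onsets, _ = _direction_segment(prof, 500, FS, rng)
        events = detect_gait_events(lowpass_filter(x - x.mean(), FS), FS)
        inner = events.ic_times[(events.ic_times > 2)
                                & (events.ic_times < t[-1] - 2)]
        steps = np.diff(inner)
        cov = 100 * steps.std(ddof=1) / steps.mean()
        assert abs(cov - 3.0) < 1.0

    def test_flat_signal_raises_insufficient_strides(self):
        with pytest.raises(InsufficientStridesError):
            detect_gait_events(np.zeros(2000), FS)

    def test_time_reversal_mirrors_events(self):
        prof = GaitProfile(0.6, 0.0, 0.18, 0.62)
        rng = np.random.default_rng(1)
        t, x, onsets, _ = _direction_segment(prof, 30, FS, rng)
        xf = lowpass_filter(x - x.mean(), FS)
        fwd = detect_gait_events(xf, FS)
        rev = detect_gait_events(xf[::-1], FS)
        T = (len(x) - 1) / FS
        mirrored = np.sort(T - rev.ic_times)
        inner_f = fwd.ic_times[(fwd.ic_times > 2) & (fwd.ic_times < T - 2)]
        errs = [np.min(np.abs(mirrored - s)) for s in inner_f]
        assert np.mean(errs) < 0.03

    def test_output_satisfies_event_invariants(self):
        """Ordering, alternation and IC/FC interleaving hold on random
        gait profiles (enforced by GaitEvents.validate)."""
        for seed in range(5):
            rng = np.random.default_rng(seed)
            prof = GaitProfile(0.45 + 0.07 * seed, 1.0 + seed, 0.18, 0.6)
            t, x, _, _ = _direction_segment(prof, 60, FS, rng)
            ev = detect_gait_events(lowpass_filter(x - x.mean(), FS), FS)
            ev.validate()
            assert len(ev.fc_times) == len(ev.ic_times) - 1

    def test_chain_is_deterministic(self):
        prof = GaitProfile(0.55, 2.5, 0.18, 0.62)
        rec, _ = generate_acceleration(prof, seed=5)
        out = []
        for _ in range(2):
            r = lowpass_filter(tilt_correct(rec))
            seg1, _ = split_segments(r)
            out.append(detect_gait_events(seg1).ic_times)
        np.testing.assert_array_equal(out[0], out[1])


class TestGaitEventsContainer:
    def test_round_trips_through_csv_frame(self):
        ev = GaitEvents(ic_times=[0.0, 0.5, 1.0, 1.5],
                        fc_times=[0.15, 0.65, 1.15])
        back = GaitEvents.from_frame(ev.to_frame())
        np.testing.assert_allclose(back.ic_times, ev.ic_times)
        np.testing.assert_allclose(back.fc_times, ev.fc_times)
        assert back.foot_labels == ev.foot_labels

    def test_invariant_violations_rejected(self):
        with pytest.raises(ValueError):
            GaitEvents(ic_times=[0.0, 0.5, 0.4], fc_times=[0.1, 0.45])
        with pytest.raises(ValueError):
            GaitEvents(ic_times=[0.0, 0.5, 1.0], fc_times=[0.6, 1.2])
        with pytest.raises(ValueError):
            GaitEvents(ic_times=[0.0, 0.5, 1.0], fc_times=[0.2, 0.7],
                       foot_labels=("F1", "F1", "F2"))
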