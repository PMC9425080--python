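"""Gait features: interval decomposition, the 16 STGF, dual-task costs,
table assembly and the eleven feature-subset models."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from stablegait.features import MODEL_TASKS, STGF_NAMES, \
    assemble_feature_table, compute_dtc, compute_stgf, \
    compute_stride_params, enumerate_models, model_columns, \
    select_model_columns
from stablegait.signal import GaitEvents, detect_gait_events, \
    lowpass_filter, split_segments, tilt_correct
from stablegait.synth import GaitProfile, generate_acceleration

FS = 100.0


def _regular_events(step=0.5, n=8, ds=0.15):
    ic = np.arange(n) * step
    fc = ic[:-1] + ds
    return GaitEvents(ic_times=ic, fc_times=fc)


class TestStrideParams:
    def test_regular_sequence_interval_arithmetic(self):
        p = compute_stride_params(_regular_events(step=0.5))
        np.testing.assert_allclose(p.step_times, 0.5)
        np.testing.assert_allclose(p.stride_times["F1"], 1.0)
        np.testing.assert_allclose(p.stride_times["F2"], 1.0)
        np.testing.assert_allclose(p.double_support, 0.15)
        np.testing.assert_allclose(p.single_support, 0.35)

    def test_stance_and_swing_decomposition(self):
        """Stance runs from a foot's IC to its next FC; swing from that
        FC to its next IC; together they tile the stride."""
        ev = GaitEvents(ic_times=[0.0, 0.5, 1.0, 1.5],
                        fc_times=[0.15, 0.65, 1.15])
        p = compute_stride_params(ev)
        # foot striking at 0.5 (F2) lifted off at 1.15, struck again at 1.5
        np.testing.assert_allclose(p.stance["F2"], [0.65])
        np.testing.assert_allclose(p.swing["F2"], [0.35, 0.35])
        np.testing.assert_allclose(p.stance["F1"], [0.65])
        # swing + stance = stride for every complete cycle
        assert p.stance["F2"][0] + p.swing["F2"][1] == pytest.approx(1.0)

    def test_planted_asymmetry_recovered(self):
        steps = np.tile([0.45, 0.55], 6)
        ic = np.concatenate(([0.0], np.cumsum(steps)))
        fc = ic[:-1] + 0.12
        p = compute_stride_params(GaitEvents(ic_times=ic, fc_times=fc))
        by_foot = {f: p.step_times[np.array(p.step_feet) == f].mean()
                   for f in ("F1", "F2")}
        assert sorted(by_foot.values()) == pytest.approx([0.45, 0.55])

    def test_rejects_broken_alternation(self):
        with pytest.raises(ValueError):
            GaitEvents(ic_times=[0, 0.5, 1.0, 1.5],
                       fc_times=[0.1, 0.6, 1.1],
                       foot_labels=("F1", "F2", "F2", "F1"))


class TestStgf:
    def _vector(self, events, signal=None, fs=FS, height=170.0):
        if signal is None:
            t = np.arange(int(events.ic_times[-1] * fs) + 1) / fs
            signal = 0.2 * np.sin(2 * np.pi * 2 * t)
        p = compute_stride_params(events)
        return compute_stgf(p, signal, height=height, sampling_rate=fs,
                            events=events)

    def test_constant_steps_give_exact_cadence_and_zero_cov(self):
        v = self._vector(_regular_events(step=0.5, n=10))
        assert v.StpT == pytest.approx(0.5)
        assert v.Cd == pytest.approx(120.0)
        assert v.StpTCoV == pytest.approx(0.0, abs=1e-10)
        assert v.Cd * v.StpT == pytest.approx(60.0)
        assert v.StrT == pytest.approx(v.StepDurF1 + v.StepDurF2, rel=1e-9)

    def test_two_point_cov_arithmetic(self):
        steps = np.tile([0.4, 0.6], 5)
        ic = np.concatenate(([0.0], np.cumsum(steps)))
        ev = GaitEvents(ic_times=ic, fc_times=ic[:-1] + 0.1)
        v = self._vector(ev)
        assert v.StpT == pytest.approx(0.5)
        # sample (n-1) standard deviation of the alternating series
        sd = np.std(np.tile([0.4, 0.6], 5), ddof=1)
        assert v.StpTCoV == pytest.approx(100 * sd / 0.5, rel=1e-6)

    def test_sinusoid_rms_closed_form(self):
        t = np.arange(2000) / FS
        a = 0.37
        sig = a * np.sin(2 * np.pi * 2 * t)
        v = self._vector(_regular_events(step=0.5, n=20), signal=sig)
        assert v.RMS == pytest.approx(a / np.sqrt(2), rel=1e-3)

    def test_too_few_steps_rejected(self):
        ev = GaitEvents(ic_times=[0.0, 0.5, 1.0], fc_times=[0.1, 0.6])
        with pytest.raises(ValueError):
            self._vector(ev)

    def test_speed_is_step_length_over_step_time(self):
        v = self._vector(_regular_events(step=0.5, n=10))
        assert v.GS == pytest.approx(v.StepLg / v.StpT)
        assert v.StepLg > 0


class TestDtc:
    @pytest.mark.parametrize("single,dual,expected", [
        (1.0, 1.0, 0.0),
        (1.2, 0.9, 25.0),
        (2.0, 3.0, -50.0),
    ])
    def test_cost_formula(self, single, dual, expected):
        assert compute_dtc(single, dual) == pytest.approx(expected)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            compute_dtc(0.0, 1.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(0.1, 10), st.floats(-5, 5), st.floats(-5, 5),
           st.floats(0.1, 3))
    def test_identity_and_linearity_in_dual_value(self, s, d1, d2, w):
        assert compute_dtc(s, s) == pytest.approx(0.0, abs=1e-9)
        lhs = compute_dtc(s, d1 + w * d2)
        rhs = compute_dtc(s, d1) + w * (compute_dtc(s, d2)
                                        - compute_dtc(s, 0.0))
        assert lhs == pytest.approx(rhs, rel=1e-9, abs=1e-9)


def _fake_vector(value: float):
    from stablegait.features import StgfVector

    return StgfVector(**{n: value for n in STGF_NAMES})


class TestAssembly:
    def test_full_four_task_input_yields_96_columns(self):
        tasks = {t: {"dir1": _fake_vector(1.0), "dir2": _fake_vector(2.0)}
                 for t in ("NormalW", "EasyD", "HardD", "FastW")}
        table = assemble_feature_table({"s1": tasks})
        assert table.shape == (1, 96)
        assert table.loc["s1", "NormalW::StpT"] == pytest.approx(1.5)

    def test_single_tasks_only_gives_32_columns_no_dtc(self):
        tasks = {t: {"dir1": _fake_vector(1.0), "dir2": _fake_vector(1.0)}
                 for t in ("NormalW", "FastW")}
        table = assemble_feature_table({"s1": tasks})
        assert table.shape == (1, 32)
        assert not any(c.startswith("dtc::") for c in table.columns)

    def test_dtc_computed_per_direction_before_averaging(self):
        tasks = {
            "NormalW": {"dir1": _fake_vector(1.0),
                        "dir2": _fake_vector(2.0)},
            "EasyD": {"dir1": _fake_vector(0.5),
                      "dir2": _fake_vector(3.0)},
        }
        table = assemble_feature_table({"s1": tasks})
        # dir1: (1-0.5)/1*100 = 50; dir2: (2-3)/2*100 = -50 -> mean 0
        assert table.loc["s1", "dtc::EasyD::StpT"] == pytest.approx(0.0)

    def test_incomplete_subject_dropped_with_labels_kept(self, caplog):
        good = {t: {"dir1": _fake_vector(1.0), "dir2": _fake_vector(1.0)}
                for t in ("NormalW", "FastW")}
        bad = {"NormalW": {"dir1": _fake_vector(1.0)}}
        with caplog.at_level("WARNING"):
            table = assemble_feature_table(
                {"ok": good, "broken": bad},
                labels={"ok": "HE", "broken": "MCI-E"})
        assert list(table.index) == ["ok"]
        assert "broken" in caplog.text
        assert table.loc["ok", "label"] == "HE"


class TestModelSelection:
    def test_enumerates_the_eleven_models(self):
        models = enumerate_models()
        assert len(models) == 11
        assert "All-tasks" in models and "EasyD+FastW" in models

    @pytest.mark.parametrize("model,n_cols", [
        ("NormalW", 16),
        ("FastW", 16),
        ("EasyD", 32),          # 16 STGF + 16 dual-task costs
        ("NormalW+FastW", 32),
        ("EasyD+FastW", 48),    # 2 x 16 STGF + 16 EasyD costs
        ("EasyD+HardD", 64),
        ("All-tasks", 96),
    ])
    def test_column_counts_per_model(self, model, n_cols):
        assert len(model_columns(model)) == n_cols

    def test_select_keeps_label_and_rejects_unknown(self):
        tasks = {t: {"dir1": _fake_vector(1.0), "dir2": _fake_vector(1.0)}
                 for t in ("NormalW", "EasyD", "HardD", "FastW")}
        table = assemble_feature_table({"s1": tasks},
                                       labels={"s1": "HE"})
        sub = select_model_columns(table, "NormalW")
        assert sub.shape == (1, 17) and "label" in sub.columns
        with pytest.raises(KeyError):
            select_model_columns(table, "NormalX")


class TestEndToEndRecovery:
    def test_planted_profile_recovered_through_full_chain(self):
        """Signal -> events -> features recovers the planted step time
        (within 10 ms), CoV (within 1 pp) and RMS (within 5 %)."""
        prof = GaitProfile(0.55, 3.0, 0.18, 0.62)
        rec, _ = generate_acceleration(prof, seed=12, distance=30.0,
                                       noise_sd=0.005)
        r = lowpass_filter(tilt_correct(rec))
        for seg in split_segments(r):
            ev = detect_gait_events(seg)
            p = compute_stride_params(ev)
            v = compute_stgf(p, seg, height=165.0, events=ev)
            assert v.StpT == pytest.approx(0.55, abs=0.010)
            assert v.StpTCoV == pytest.approx(3.0, abs=1.0)
            assert v.RMS == pytest.approx(0.18, rel=0.05)
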