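"""Electrophysiology summaries: instantaneous frequency, FI/rheobase,
adaptation, recruitment thresholds, latency windows, hysteresis metric."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neuromotor import ephys_analysis as ea
from neuromotor.cell_models import StimulusSpec, builtin_template
from neuromotor.model_def import ModelError


class TestInstantaneousFrequency:
    def test_regular_train(self):
        out = ea.instantaneous_frequency([100.0, 150.0, 200.0])
        np.testing.assert_allclose(out, [[150.0, 20.0], [200.0, 20.0]])

    def test_fewer_than_two_spikes_empty(self):
        assert ea.instantaneous_frequency([]).size == 0
        assert ea.instantaneous_frequency([5.0]).size == 0

    @given(st.lists(st.floats(0.1, 1000.0), min_size=2, max_size=40))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_pairwise_difference_oracle(self, isis):
        spikes = np.cumsum(np.asarray(isis))
        out = ea.instantaneous_frequency(spikes)
        for k, (t, f) in enumerate(out):
            assert t == spikes[k + 1]
            assert f == pytest.approx(1000.0 / (spikes[k + 1] - spikes[k]))


class TestFICurve:
    def test_subthreshold_ramp_gives_empty_curve(self, slow_template):
        ramp = StimulusSpec.iclamp([(0.0, 0.0), (1000.0, 1.0)])
        pairs, rheobase = ea.fi_curve(slow_template, ramp, duration=500.0,
                                      dt=0.05)
        assert pairs.size == 0 and rheobase is None

    def test_integrate_fire_rheobase_matches_closed_form(self, if_template):
        p = if_template.params
        theory = (p["v_thresh"] - p["v_rest"]) / p["r_in"]
        ramp = StimulusSpec.iclamp([(0.0, 0.0), (2000.0, 0.5)])
        _, rheobase = ea.fi_curve(if_template, ramp, duration=2000.0, dt=0.05)
        assert rheobase == pytest.approx(theory, rel=0.05)


class TestSRA:
    def test_perfectly_periodic_train_basal_is_exact(self):
        spikes = np.arange(0.0, 1000.0, 40.0)  # 25 Hz
        assert ea.basal_rate_from_spikes(spikes, 500.0) == pytest.approx(25.0)

    def test_insufficient_firing_raises(self, slow_template):
        sub = StimulusSpec.iclamp([(0.0, 0.5), (300.0, 0.5)])
        with pytest.raises(ModelError, match="insufficient"):
            ea.sra_curve(slow_template, sub, duration=300.0, dt=0.05)

    def test_adaptation_reaches_basal_within_a_few_isis(self, slow_template):
        step = ea.step_stimulus(12.0, onset=100.0, end=1000.0)
        series, basal = ea.sra_curve(slow_template, step, duration=1000.0)
        # by the 5th interval the rate is within 20% of the basal rate
        assert series[4, 1] == pytest.approx(basal, rel=0.2)
        # and early intervals fire faster than the adapted rate
        assert series[0, 1] > basal


class TestRecruitmentThresholds:
    def test_subthreshold_grid_all_none(self, if_template):
        out = ea.recruitment_thresholds([if_template], [0.01, 0.02],
                                        duration=200.0)
        assert out["interneuron_if"] is None

    def test_threshold_is_rheobase_rounded_up_to_grid(self, if_template):
        p = if_template.params
        rheo = (p["v_thresh"] - p["v_rest"]) / p["r_in"]  # closed form
        grid = [0.04 * k for k in range(1, 11)]  # grid points avoid the
        out = ea.recruitment_thresholds([if_template], grid, duration=500.0,
                                        dt=0.05)  # exact asymptotic rheobase
        expected = min(a for a in grid if a > rheo * 1.001)
        assert out["interneuron_if"] == pytest.approx(expected)

    def test_unsorted_grid_rejected(self, if_template):
        with pytest.raises(ModelError):
            ea.recruitment_thresholds([if_template], [3.0, 1.0])


class TestLatencyWindows:
    def test_deflection_at_4p7ms_is_medium_and_medium_late_not_early(self):
        w = ea.LatencyWindows()
        classes = w.classify(4.7)
        assert "medium" in classes and "medium_late" in classes
        assert "early" not in classes

    def test_window_membership_of_synthetic_trace(self):
        t = np.arange(0.0, 30.0, 0.1)
        trace = np.full_like(t, -65.0)
        pulse = 10.0
        trace[(t >= pulse + 4.6) & (t <= pulse + 4.9)] = -55.0  # one bump
        w = ea.LatencyWindows()
        early = ea.window_response(t, trace, [pulse], w.early)
        medium = ea.window_response(t, trace, [pulse], w.medium)
        ml = ea.window_response(t, trace, [pulse], w.medium_late)
        assert early == 0.0
        assert medium > 0 and ml > 0

    def test_no_pulse_raises(self):
        t = np.arange(0.0, 10.0, 0.1)
        with pytest.raises(ModelError):
            ea.window_response(t, np.zeros_like(t), [], (0, 3))

    def test_subfloor_deflections_count_as_zero(self):
        t = np.arange(0.0, 30.0, 0.1)
        trace = np.full_like(t, -65.0)
        trace[100] = -65.0 + ea.RESPONSE_FLOOR_MV / 10
        assert ea.window_response(t, trace, [5.0], (3, 12)) == 0.0


class TestReflexCurveConstruction:
    def _trace(self, amp_early, amp_ml, t, pulse=135.0):
        trace = np.full_like(t, -65.0)
        trace[(t > pulse + 1.0) & (t < pulse + 2.0)] += amp_early
        trace[(t > pulse + 6.0) & (t < pulse + 8.0)] += amp_ml
        return trace

    def test_motor_threshold_and_normalization(self):
        t = np.arange(0.0, 160.0, 0.1)
        data = [(7.0, self._trace(0, 0, t)),
                (9.0, self._trace(0, 0, t)),
                (11.0, self._trace(1.0, 8.0, t)),
                (13.0, self._trace(4.0, 2.0, t)),
                (15.0, self._trace(8.0, 0.5, t))]
        curve = ea.reflex_recruitment_curve(
            [(a, t, tr) for a, tr in data], [135.0])
        assert curve.motor_threshold == 11.0
        assert curve.early.max() == pytest.approx(1.0)
        assert curve.medium_late.max() == pytest.approx(1.0)
        assert curve.early[0] == 0.0 and curve.medium_late[0] == 0.0
        np.testing.assert_allclose(curve.amplitudes,
                                   np.array([7, 9, 11, 13, 15]) / 11.0)

    def test_no_early_response_anywhere_raises(self):
        t = np.arange(0.0, 160.0, 0.1)
        flat = np.full_like(t, -65.0)
        with pytest.raises(ModelError, match="motor threshold"):
            ea.reflex_recruitment_curve([(7.0, t, flat)], [135.0])


class TestHysteresisMetric:
    def test_identical_curves_no_hysteresis(self):
        pairs = np.column_stack([np.linspace(2, 10, 20),
                                 np.linspace(10, 40, 20)])
        _, delta, direction = ea.hysteresis_metric(pairs, pairs.copy())
        assert delta == pytest.approx(0.0)
        assert direction == "clockwise"

    def test_constant_shift_recovered_exactly(self):
        current = np.linspace(2, 10, 20)
        asc = np.column_stack([current, np.linspace(10, 40, 20)])
        dsc = asc.copy()
        dsc[:, 1] += 5.0
        _, delta, direction = ea.hysteresis_metric(asc, dsc)
        assert delta == pytest.approx(5.0)
        assert direction == "counterclockwise"

    def test_disjoint_supports_raise(self):
        asc = np.array([[1.0, 10.0], [2.0, 12.0]])
        dsc = np.array([[5.0, 10.0], [6.0, 12.0]])
        with pytest.raises(ModelError):
            ea.hysteresis_metric(asc, dsc)

    def test_empty_branch_raises(self):
        with pytest.raises(ModelError):
            ea.hysteresis_metric(np.empty((0, 2)), np.array([[1.0, 2.0]]))
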