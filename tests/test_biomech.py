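"""Twitch force, activation glue, ankle dynamics, and afferent feedback."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from neuromotor import biomech as bm
from neuromotor.model_def import ModelError


class TestTwitchForce:
    def test_single_spike_peaks_at_P_after_T(self):
        params = bm.TwitchParams(P=1.0, T=10.0)
        t = np.arange(0.0, 100.0, 0.1)
        f = bm.twitch_force([[20.0]], params, t)
        i = np.argmax(f)
        assert f[i] == pytest.approx(1.0, abs=1e-4)
        assert t[i] == pytest.approx(30.0, abs=0.1)  # spike + T

    def test_no_spikes_zero_trace(self):
        t = np.arange(0.0, 50.0, 0.5)
        assert not bm.twitch_force([[]], bm.TwitchParams(), t).any()

    def test_two_identical_trains_double_the_force(self):
        t = np.arange(0.0, 200.0, 0.5)
        train = [10.0, 40.0, 90.0]
        one = bm.twitch_force([train], bm.TwitchParams(), t)
        two = bm.twitch_force([train, train], bm.TwitchParams(), t)
        np.testing.assert_allclose(two, 2 * one)

    def test_time_invariance_shift(self):
        params = bm.TwitchParams(P=2.0, T=15.0)
        t = np.arange(0.0, 300.0, 0.5)
        base = bm.twitch_force([[50.0]], params, t)
        shifted = bm.twitch_force([[80.0]], params, t + 30.0)
        np.testing.assert_allclose(shifted, base, atol=1e-12)


class TestActivation:
    def test_no_spikes_zero(self):
        assert bm.activation_from_spikes([[], []], 100.0) == 0.0

    def test_saturation_clamps_to_one(self):
        spikes = [list(np.arange(0, 100, 5.0))]  # 200 Hz
        assert bm.activation_from_spikes(spikes, 100.0) == 1.0

    def test_half_saturation_rate_gives_half(self):
        spikes = [list(np.arange(0, 200, 40.0))]  # 5 spikes / 200 ms = 25 Hz
        assert bm.activation_from_spikes(spikes, 200.0,
                                         saturation_rate=50.0) == 0.5

    def test_nonpositive_window_rejected(self):
        with pytest.raises(ModelError):
            bm.activation_from_spikes([[1.0]], 0.0)


class TestAnkle:
    def test_balanced_moments_keep_angle_constant(self):
        model = bm.AnkleModel()
        tau_ta = bm._muscle_torque(model, model.toe_pos, 1.0)
        tau_gas = bm._muscle_torque(model, model.heel_pos, 1.0)
        f_gas = 1.0
        f_ta = -tau_gas / tau_ta * f_gas  # scaled to cancel exactly
        assert f_ta > 0
        m = model
        for _ in range(200):
            m = bm.ankle_step(m, f_ta, f_gas, 0.1)
        assert m.theta == pytest.approx(model.theta, abs=1e-9)

    def test_matches_independent_ode_solution(self):
        """Semi-implicit Euler vs scipy's adaptive integrator on the same
        nonlinear dynamics."""
        model = bm.AnkleModel(joint_limits=(-2.0, 2.0))
        f_ta = 3.0

        def rhs(t, y):
            m = bm.AnkleModel(theta=y[0], omega=y[1],
                              joint_limits=(-2.0, 2.0))
            tau = bm._muscle_torque(m, m.toe_pos, f_ta)
            return [y[1], tau / m.inertia]

        t_end = 30.0  # within the first swing, before phase sensitivity
        sol = solve_ivp(rhs, (0.0, t_end), [0.0, 0.0], rtol=1e-9, atol=1e-12)
        m = model
        dt = 0.005
        for _ in range(int(t_end / dt)):
            m = bm.ankle_step(m, f_ta, 0.0, dt)
        assert m.theta == pytest.approx(sol.y[0, -1], rel=2e-3)

    def test_constant_moment_quadratic_kinematics_short_time(self):
        model = bm.AnkleModel(joint_limits=(-2.0, 2.0))
        f_ta = 2.0
        tau0 = bm._muscle_torque(model, model.toe_pos, f_ta)
        m = model
        dt, t_end = 0.005, 5.0
        for _ in range(int(t_end / dt)):
            m = bm.ankle_step(m, f_ta, 0.0, dt)
        # short-time: geometry barely rotates, so the moment is ~constant
        assert m.theta == pytest.approx(0.5 * tau0 / model.inertia * t_end**2,
                                        rel=0.02)

    def test_gastrocnemius_alone_shortens_monotonically(self):
        """Plantar-flexion: the extensor contracts toward its insertion."""
        m = bm.AnkleModel()
        lengths = [m.muscle_lengths()[1]]
        for _ in range(400):
            m = bm.ankle_step(m, 0.0, 5.0, 0.1)
            lengths.append(m.muscle_lengths()[1])
        diffs = np.diff(lengths)
        assert (diffs <= 1e-12).all() and lengths[-1] < lengths[0]

    def test_joint_limit_clamps_with_flag(self):
        m = bm.AnkleModel(joint_limits=(-0.05, 0.05))
        for _ in range(2000):
            m = bm.ankle_step(m, 10.0, 0.0, 0.1)
        assert m.limit_hit
        assert m.theta == pytest.approx(0.05)

    def test_negative_force_rejected(self):
        with pytest.raises(ModelError):
            bm.ankle_step(bm.AnkleModel(), -1.0, 0.0, 0.1)


class TestAfferentRates:
    def test_quiescent_muscle_fires_at_base(self):
        ms = bm.MuscleState(length=1.0, resting_length=1.0)
        ia, ii = bm.afferent_rates(ms)
        assert ia == pytest.approx(bm.AFFERENT_DEFAULTS["base"])
        assert ii == pytest.approx(bm.AFFERENT_DEFAULTS["base"])

    def test_direct_evaluation_of_rate_equation(self):
        params = bm.AfferentParams(alpha1=1.0, gamma1=0.5, beta1=1.0,
                                   eta1=0.0, beta2=1.0, eta2=0.0, base=10.0)
        # v = 4 rest-lengths/s, disp = 3 rest-lengths
        ms = bm.MuscleState(length=4.0, resting_length=1.0, velocity=4e-3)
        assert ms.v == pytest.approx(4.0)
        assert ms.disp == pytest.approx(3.0)
        ia, _ = bm.afferent_rates(ms, params)
        assert ia == pytest.approx(1.0 * 4.0**0.5 + 1.0 * 3.0 + 10.0)  # = 15

    def test_power_law_velocity_scaling(self):
        params = bm.AfferentParams(alpha1=2.0, gamma1=0.6, beta1=0.0,
                                   eta1=0.0, base=0.0)
        v1 = bm.afferent_rates(
            bm.MuscleState(1.0, 1.0, velocity=1e-3), params)[0]
        v2 = bm.afferent_rates(
            bm.MuscleState(1.0, 1.0, velocity=2e-3), params)[0]
        assert v2 / v1 == pytest.approx(2 ** 0.6)

    def test_ia_strictly_increasing_in_v_and_disp(self):
        base = bm.MuscleState(1.05, 1.0, velocity=1e-3)
        more_v = bm.MuscleState(1.05, 1.0, velocity=2e-3)
        more_d = bm.MuscleState(1.10, 1.0, velocity=1e-3)
        assert bm.afferent_rates(more_v)[0] > bm.afferent_rates(base)[0]
        assert bm.afferent_rates(more_d)[0] > bm.afferent_rates(base)[0]

    def test_negative_rates_clamp_to_zero(self):
        params = bm.AfferentParams(base=0.0)
        shortened = bm.MuscleState(0.5, 1.0)  # disp < 0, v = 0
        ia, ii = bm.afferent_rates(shortened, params)
        assert ia == 0.0 and ii == 0.0

    def test_gamma_bounds_enforced(self):
        with pytest.raises(ModelError):
            bm.AfferentParams(gamma1=1.5)


class TestClosedLoop:
    def _glue(self, **kw):
        return bm.GlueConfig(
            muscles={
                "Gas": {"mn_group": "Human_L5_CEx9_L_AlphaMoto_Gas",
                        "ia_group": "Human_L5_DRG_L_IaAfferent_Gas",
                        "ii_group": "Human_L5_DRG_L_IIAfferent_Gas"},
                "TA": {"mn_group": "Human_L4_CFl9_L_AlphaMoto_Tib",
                       "ia_group": "Human_L4_DRG_L_IaAfferent_Tib",
                       "ii_group": "Human_L4_DRG_L_IIAfferent_Tib"},
            }, **kw)

    def test_missing_muscle_mapping_rejected(self):
        with pytest.raises(ModelError):
            bm.GlueConfig(muscles={"Gas": {"mn_group": "x"}})

    def test_zero_activation_keeps_rest_angle(self, small_model):
        from neuromotor.fixtures import reflex_sim_definition
        from neuromotor.simulator import build_network

        sim = reflex_sim_definition([7.0])  # below every threshold
        net = build_network(small_model, sim, seed=1)
        glue = self._glue(afferent=bm.AfferentParams(base=0.0))
        rec, traj, rates = bm.closed_loop_run(
            net, bm.AnkleModel(), glue, duration=80.0, seed=1,
            run_overrides={"ees_amplitude": 7.0})
        assert np.allclose(traj["theta"], 0.0)

    def test_feedback_ablation_equals_open_loop(self, small_model):
        from neuromotor.fixtures import reflex_sim_definition
        from neuromotor.simulator import build_network

        sim = reflex_sim_definition([13.0])
        trajs = []
        for gain in (0.0, 0.0):
            net = build_network(small_model, sim, seed=1)
            glue = self._glue(afferent_gain=gain,
                              afferent=bm.AfferentParams(base=0.0))
            _, traj, _ = bm.closed_loop_run(
                net, bm.AnkleModel(), glue, duration=80.0, seed=1,
                run_overrides={"ees_amplitude": 13.0})
            trajs.append(traj["theta"].to_numpy())
        np.testing.assert_allclose(trajs[0], trajs[1])

    def test_extensor_recruitment_drives_plantar_flexion(self, small_model):
        """EES above motor threshold recruits the extensor pool; with the
        glue mapping Gas to the extensor, the ankle plantar-flexes
        (theta decreases under the dorsi-positive convention)."""
        from neuromotor.cell_models import StimulusSpec
        from neuromotor.simulator import SimulationDefinition, build_network

        ees = StimulusSpec.ees(rate=8.0, onset_delay=10.0, amplitude=21.0)
        sim = SimulationDefinition(
            inputs=[{"stimulus": ees.to_dict(),
                     "target": ["Human_L5_DRG_L_IaAfferent_Gas",
                                "Human_L5_DRG_L_IIAfferent_Gas",
                                "Human_L5_CEx9_L_AlphaMoto_Gas"]}],
            responses=[{"variable": "v",
                        "target": {"neuron_type": "AlphaMoto"}}],
            runs=[{"duration": 160.0, "dt": 0.025}])
        net = build_network(small_model, sim, seed=1)
        glue = self._glue(afferent=bm.AfferentParams(base=0.0),
                          force_gain=5.0)
        rec, traj, _ = bm.closed_loop_run(
            net, bm.AnkleModel(), glue, duration=160.0, seed=1,
            run_overrides={"ees_amplitude": 21.0})
        assert traj["theta"].iloc[-1] < 0.0
        assert rec.metadata["angle_convention"].startswith("dorsi")
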