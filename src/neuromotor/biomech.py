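"""Native ankle biomechanics: rigid-foot model, twitch-convolution muscle
force, motoneuron-activation glue, and spindle afferent feedback.

The foot is a rigid body hinged at the ankle ``O`` with toe ``Q`` and heel
``R``; the tibialis anterior (dorsi-flexor) runs from a fixed shank
insertion ``P`` to the toe, the gastrocnemius (plantar-flexor) from ``P``
to the heel.  The joint obeys ``M = I·θ̈`` where ``M`` is the net muscle
moment about ``O`` and ``θ`` the angle of the foot with the positive x
axis (dorsi-flexion = θ increasing; recorded in output metadata).

Motor-unit force is the output of a linear time-invariant system whose
impulse response is the twitch ``P·(t/T)·exp(1 − t/T)`` (peak ``P`` at
``t = T``).  Muscle activation — a value in [0, 1] derived from the
motoneuron pool's pooled firing rate — scales the twitch sum and feeds the
spindle model's activity term.

Spindle afferent rates follow the normalized power-law form

    Ia = α₁·v^γ₁ + β₁·disp + η₁·act + base
    II =            β₂·disp + η₂·act + base

with muscle velocity ``v`` (rest-lengths/s, rectified stretch-positive)
and displacement ``disp`` (fractional stretch), both normalized by the
muscle's resting length.  The default constants are adapted from the
classic normalized muscle-spindle regression models and live in
:data:`AFFERENT_DEFAULTS` (data, not code).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Any, Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from neuromotor.model_def import ModelError

logger = logging.getLogger(__name__)

#: Default spindle constants (normalized units; rates in Hz).  Provenance:
#: adapted from the normalized forms of the classic cat-hindlimb spindle
#: regression models ("power-law velocity, linear displacement").
AFFERENT_DEFAULTS: dict[str, float] = {
    "alpha1": 4.3,   # Ia velocity gain, Hz per (rest-length/s)^gamma1
    "gamma1": 0.6,   # Ia velocity exponent
    "beta1": 200.0,  # Ia displacement gain, Hz per rest-length
    "eta1": 50.0,    # Ia activity gain, Hz per unit activation
    "beta2": 135.0,  # II displacement gain, Hz per rest-length
    "eta2": 20.0,    # II activity gain
    "base": 10.0,    # background rate, Hz
}


@dataclass(frozen=True)
class TwitchParams:
    """Twitch impulse response: peak force P (model units) at time T (ms)."""

    P: float = 1.0
    T: float = 30.0

    def __post_init__(self) -> None:
        if self.P <= 0 or self.T <= 0:
            raise ModelError("twitch P and T must be > 0")


def twitch_kernel(t: np.ndarray, params: TwitchParams) -> np.ndarray:
    """P·(t/T)·exp(1 − t/T) for t ≥ 0, zero before."""
    t = np.asarray(t, dtype=float)
    out = np.where(t >= 0, params.P * (t / params.T) * np.exp(1 - t / params.T),
                   0.0)
    return out


def twitch_force(spike_trains: Sequence[Sequence[float]],
                 params: TwitchParams, t_grid: np.ndarray) -> np.ndarray:
    """LTI motor-unit force: twitch kernel summed over all spikes and units."""
    t_grid = np.asarray(t_grid, dtype=float)
    force = np.zeros_like(t_grid)
    for train in spike_trains:
        for ts in train:
            force += twitch_kernel(t_grid - ts, params)
    return force


def activation_from_spikes(spike_trains: Sequence[Sequence[float]],
                           window: float,
                           saturation_rate: float = 50.0) -> float:
    """Pool activation in [0, 1] from motoneuron spikes in a window (ms).

    activation = min(1, per-cell mean firing rate / saturation_rate).
    """
    if window <= 0:
        raise ModelError("window must be > 0")
    n_cells = max(1, len(spike_trains))
    n_spikes = sum(len(tr) for tr in spike_trains)
    rate = n_spikes / n_cells / (window / 1000.0)
    return min(1.0, rate / saturation_rate)


# ---------------------------------------------------------------------------
# Ankle rigid-body model
# ---------------------------------------------------------------------------


@dataclass
class AnkleModel:
    """Planar rigid-foot ankle.

    Points are 2D in dimensionless model length units; ``toe``/``heel`` are
    given in the foot frame at the rest angle, ``insertion`` is fixed in the
    world (shank) frame.  ``inertia`` is in mass·length² and times in ms.
    """

    toe: tuple[float, float] = (1.2, 0.0)
    heel: tuple[float, float] = (-0.5, 0.0)
    insertion: tuple[float, float] = (0.0, 1.0)
    inertia: float = 2.0e3          # mass·length² (ms time base)
    rest_angle: float = 0.0
    theta: float = 0.0              # rad, angle of the foot with +x axis
    omega: float = 0.0              # rad/ms
    damping: float = 0.0            # torque per (rad/ms)
    joint_limits: tuple[float, float] = (-0.8, 0.8)
    limit_hit: bool = False

    def __post_init__(self) -> None:
        if np.hypot(*self.toe) <= 0 or np.hypot(*self.heel) <= 0:
            raise ModelError("toe and heel must be away from the hinge")

    def _foot_point(self, p0: tuple[float, float]) -> np.ndarray:
        phi = self.theta - self.rest_angle
        c, s = math.cos(phi), math.sin(phi)
        x, y = p0
        return np.array([c * x - s * y, s * x + c * y])

    @property
    def toe_pos(self) -> np.ndarray:
        return self._foot_point(self.toe)

    @property
    def heel_pos(self) -> np.ndarray:
        return self._foot_point(self.heel)

    def muscle_lengths(self) -> tuple[float, float]:
        """(|P−Q|, |P−R|): tibialis anterior and gastrocnemius lengths."""
        p = np.asarray(self.insertion, dtype=float)
        return (float(np.linalg.norm(p - self.toe_pos)),
                float(np.linalg.norm(p - self.heel_pos)))


def _muscle_torque(model: AnkleModel, attach_foot: np.ndarray,
                   force: float) -> float:
    """Torque about O of a muscle pulling the foot point toward P."""
    p = np.asarray(model.insertion, dtype=float)
    u = p - attach_foot
    norm = np.linalg.norm(u)
    if norm < 1e-12:
        return 0.0
    u = u / norm
    # z-component of r × F
    return float(force * (attach_foot[0] * u[1] - attach_foot[1] * u[0]))


def ankle_step(model: AnkleModel, f_ta: float, f_gas: float,
               dt: float) -> AnkleModel:
    """Advance the joint one step (semi-implicit Euler).

    Returns the updated model; ``limit_hit`` flags a clamped joint-limit
    violation.  Forces must be ≥ 0 (muscles only pull).
    """
    if f_ta < 0 or f_gas < 0:
        raise ModelError("muscle forces must be >= 0")
    torque = (_muscle_torque(model, model.toe_pos, f_ta)
              + _muscle_torque(model, model.heel_pos, f_gas)
              - model.damping * model.omega)
    alpha = torque / model.inertia
    omega = model.omega + alpha * dt
    theta = model.theta + omega * dt
    limit_hit = False
    lo, hi = model.joint_limits
    if theta < lo or theta > hi:
        theta = min(max(theta, lo), hi)
        omega = 0.0
        limit_hit = True
        logger.warning("ankle joint limit reached at theta=%.3f rad", theta)
    return replace(model, theta=theta, omega=omega, limit_hit=limit_hit)


# ---------------------------------------------------------------------------
# Afferent feedback
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AfferentParams:
    alpha1: float = AFFERENT_DEFAULTS["alpha1"]
    gamma1: float = AFFERENT_DEFAULTS["gamma1"]
    beta1: float = AFFERENT_DEFAULTS["beta1"]
    eta1: float = AFFERENT_DEFAULTS["eta1"]
    beta2: float = AFFERENT_DEFAULTS["beta2"]
    eta2: float = AFFERENT_DEFAULTS["eta2"]
    base: float = AFFERENT_DEFAULTS["base"]

    def __post_init__(self) -> None:
        if not 0 < self.gamma1 <= 1:
            raise ModelError("gamma1 must be in (0, 1]")
        if self.base < 0:
            raise ModelError("base rate must be >= 0")


@dataclass
class MuscleState:
    """Kinematic state of one muscle, normalized by resting length."""

    length: float
    resting_length: float
    velocity: float = 0.0     # length units per ms
    activation: float = 0.0
    force: float = 0.0

    def __post_init__(self) -> None:
        if self.resting_length <= 0:
            raise ModelError("resting_length must be > 0")

    @property
    def disp(self) -> float:
        """Fractional stretch (length − rest)/rest."""
        return (self.length - self.resting_length) / self.resting_length

    @property
    def v(self) -> float:
        """Stretch velocity in rest-lengths per second, rectified ≥ 0."""
        return max(0.0, self.velocity / self.resting_length * 1000.0)


def afferent_rates(muscle: MuscleState,
                   params: AfferentParams | None = None) -> tuple[float, float]:
    """(Ia Hz, II Hz) from the muscle state; negative rates clamp to 0."""
    p = params or AfferentParams()
    ia = (p.alpha1 * muscle.v ** p.gamma1 + p.beta1 * muscle.disp
          + p.eta1 * muscle.activation + p.base)
    ii = p.beta2 * muscle.disp + p.eta2 * muscle.activation + p.base
    return max(0.0, ia), max(0.0, ii)


# ---------------------------------------------------------------------------
# Closed loop
# ---------------------------------------------------------------------------


@dataclass
class GlueConfig:
    """Mapping between network cell groups and the two ankle muscles.

    ``muscles`` maps muscle key ("TA" or "Gas") to
    ``{"mn_group": ..., "ia_group": ..., "ii_group": ...}``.
    """

    muscles: dict[str, dict[str, str]]
    twitch: TwitchParams = field(default_factory=TwitchParams)
    activation_window: float = 50.0      # ms of spike history for activation
    saturation_rate: float = 50.0        # Hz per cell
    afferent: AfferentParams = field(default_factory=AfferentParams)
    afferent_generator: str = "poisson"  # or "deterministic"
    force_gain: float = 1.0
    afferent_gain: float = 1.0           # 0 ⇒ open loop (feedback ablated)

    def __post_init__(self) -> None:
        for key in ("TA", "Gas"):
            if key not in self.muscles:
                raise ModelError(f"glue config missing muscle {key!r}")
            for field_name in ("mn_group",):
                if field_name not in self.muscles[key]:
                    raise ModelError(
                        f"glue config muscle {key!r} missing {field_name!r}")


def closed_loop_run(network, ankle: AnkleModel, glue: GlueConfig,
                    duration: float, dt: float = 0.025,
                    control_interval: float = 1.0,
                    run_overrides: Mapping[str, Any] | None = None,
                    seed: int = 0):
    """Run the network with the ankle in the loop.

    Every control step: motoneuron spikes → activation → twitch-convolved,
    activation-scaled muscle force → joint update → muscle
    lengths/velocities → spindle afferent rates → afferent spike generation
    driving the network's afferent source groups.

    Returns ``(Recordings, trajectory DataFrame, afferent rate DataFrame)``.
    The trajectory frame has one row per control step with the joint angle,
    muscle lengths/velocities, activations, forces and afferent rates.
    """
    rng = np.random.default_rng(seed)
    state = {"ankle": ankle, "rows": [], "spike_hist": {"TA": [], "Gas": []},
             "prev_lengths": None, "poisson_accum": {}}
    l_ta0, l_gas0 = ankle.muscle_lengths()
    rest_lengths = {"TA": l_ta0, "Gas": l_gas0}

    def controller(t: float, window_spikes, net) -> None:
        a = state["ankle"]
        row: dict[str, float] = {"t": t}
        forces = {}
        activations = {}
        for key in ("TA", "Gas"):
            cfg = glue.muscles[key]
            mn = cfg["mn_group"]
            trains = window_spikes.get(mn, [])
            pooled = [ts for tr in trains for ts in tr]
            hist = state["spike_hist"][key]
            hist.extend(pooled)
            # keep twitch-relevant history (5 time constants)
            cutoff = t - 5 * glue.twitch.T
            state["spike_hist"][key] = [ts for ts in hist if ts >= cutoff]
            recent = [ts for ts in state["spike_hist"][key]
                      if ts >= t - glue.activation_window]
            n_cells = max(1, len(trains))
            act = min(1.0, (len(recent) / n_cells
                            / (glue.activation_window / 1000.0))
                      / glue.saturation_rate)
            f = act * glue.force_gain * float(
                twitch_force([state["spike_hist"][key]], glue.twitch,
                             np.array([t]))[0])
            activations[key] = act
            forces[key] = f
        # integrate the joint across the control interval
        n_sub = max(1, int(round(control_interval / 0.1)))
        sub_dt = control_interval / n_sub
        for _ in range(n_sub):
            a = ankle_step(a, forces["TA"], forces["Gas"], sub_dt)
        l_ta, l_gas = a.muscle_lengths()
        prev = state["prev_lengths"] or (l_ta, l_gas)
        vel = {"TA": (l_ta - prev[0]) / control_interval,
               "Gas": (l_gas - prev[1]) / control_interval}
        state["prev_lengths"] = (l_ta, l_gas)
        state["ankle"] = a
        lengths = {"TA": l_ta, "Gas": l_gas}
        for key in ("TA", "Gas"):
            ms = MuscleState(length=lengths[key],
                             resting_length=rest_lengths[key],
                             velocity=vel[key], activation=activations[key],
                             force=forces[key])
            ia, ii = afferent_rates(ms, glue.afferent)
            ia *= glue.afferent_gain
            ii *= glue.afferent_gain
            row.update({f"ia_{key}": ia, f"ii_{key}": ii,
                        f"len_{key}": lengths[key], f"vel_{key}": vel[key],
                        f"act_{key}": activations[key],
                        f"force_{key}": forces[key]})
            # drive the afferent source groups for the next interval
            cfg = glue.muscles[key]
            for rate, group_key in ((ia, "ia_group"), (ii, "ii_group")):
                gname = cfg.get(group_key)
                if not gname or gname not in net.batches:
                    continue
                batch = net.batches[gname]
                _generate_afferent_spikes(
                    batch, rate, t, control_interval, glue.afferent_generator,
                    rng, state["poisson_accum"].setdefault(gname,
                                                           np.zeros(batch.n)))
        row.update({"theta": a.theta, "omega": a.omega})
        state["rows"].append(row)

    rec = network.run(
        {"duration": duration, "dt": dt, "seed": seed,
         "overrides": dict(run_overrides or {})},
        controller=controller, control_interval=control_interval)
    traj = pd.DataFrame(state["rows"])
    rate_cols = ["t"] + [c for c in traj.columns if c.startswith(("ia_", "ii_"))]
    rec.metadata["angle_convention"] = "dorsi-flexion = theta increasing"
    return rec, traj, traj[rate_cols] if len(traj) else traj


def _generate_afferent_spikes(batch, rate_hz: float, t: float,
                              interval: float, kind: str,
                              rng: np.random.Generator,
                              accum: np.ndarray) -> None:
    """Schedule afferent spikes in (t, t+interval] at ``rate_hz`` per cell."""
    if rate_hz <= 0:
        return
    expected = rate_hz * interval / 1000.0
    if kind == "poisson":
        counts = rng.poisson(expected, size=batch.n)
        for i, c in enumerate(counts):
            if c:
                batch.add_events(i, t + np.sort(rng.uniform(0, interval, size=c)))
    else:
        # deterministic integrate-to-threshold: accumulate expected counts
        accum += expected
        for i in range(batch.n):
            n_fire = int(accum[i])
            if n_fire:
                accum[i] -= n_fire
                batch.add_events(
                    i, t + (np.arange(n_fire) + 0.5) * interval / n_fire)
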