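"""Network instantiation and fixed-step simulation with virtual recordings.

A :class:`Network` is built from a realized
:class:`~neuromotor.model_def.ModelDefinition`: each cell group becomes a
vectorized batch of cells (conductance motoneurons, integrate-and-fire
interneurons, or afferent spike sources), and each net connection becomes a
sparse fan-in wiring with a single-exponential conductance channel per
(tau, reversal) pair.  Synaptic events travel through a step-indexed delay
queue; integration is fixed-step (exponential midpoint for conductance
cells, exact integration for integrate-and-fire), with automatic
substepping during action potentials.

Epidural electrical stimulation (EES) is modeled as amplitude-dependent
fiber recruitment: a pulse train of amplitude ``A`` recruits a fraction
``f_aff(A)`` of afferent fibers (which then fire at each pulse, driving the
reflex circuit synaptically) and a fraction ``f_mn(A)`` of motoneuron axons
directly.  Directly recruited motoneurons fire at the pulse (the *early*
response) and their somata are synaptically refractory through the
medium-late window, which is what makes the medium-late (reflex) response
rise and then fall with stimulation amplitude.  The motor threshold is the
lowest amplitude with a nonzero early response (``A > t_mn``).
"""

from __future__ import annotations

import json
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from neuromotor.cell_models import (
    CellTemplate,
    IntegrateFireBatch,
    MotoneuronBatch,
    SpikeSourceBatch,
    StimulusSpec,
    make_batch,
    make_stimulus,
    iclamp_value,
)
from neuromotor.model_def import ModelDefinition, ModelError

logger = logging.getLogger(__name__)

_SIM_KEYS = ("inputs", "responses", "setup", "runs", "plots")


@dataclass
class EESRecruitment:
    """Monotone saturating recruitment of afferents and motoneuron axons.

    Fractions are piecewise linear in amplitude: 0 below the threshold,
    1 above saturation.  ``t_aff < t_mn``: afferent fibers have the lower
    electrical threshold, but both thresholds sit between adjacent points of
    the conventional stimulation grid, so below the motor threshold neither
    response is visible.  Amplitudes are dimensionless stimulation units.
    """

    t_aff: float = 9.5
    sat_aff: float = 15.0
    t_mn: float = 10.5
    sat_mn: float = 20.0

    def f_aff(self, amplitude: float) -> float:
        return _ramp01(amplitude, self.t_aff, self.sat_aff)

    def f_mn(self, amplitude: float) -> float:
        return _ramp01(amplitude, self.t_mn, self.sat_mn)

    def to_dict(self) -> dict[str, float]:
        return {"t_aff": self.t_aff, "sat_aff": self.sat_aff,
                "t_mn": self.t_mn, "sat_mn": self.sat_mn}


def _ramp01(x: float, lo: float, hi: float) -> float:
    if x <= lo:
        return 0.0
    if x >= hi:
        return 1.0
    return (x - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# Simulation definition
# ---------------------------------------------------------------------------


@dataclass
class SimulationDefinition:
    """The five-section experiment description.

    ``inputs``: list of ``{"stimulus": <StimulusSpec dict>, "target":
    <selector>}``; ``responses``: list of ``{"variable": "v"|"spike"|"i_na",
    "target": <selector>}``; ``setup``: wiring overrides and the EES
    recruitment model; ``runs``: list of ``{"duration", "dt", "seed",
    "overrides"}``; ``plots``: analysis specs passed through to
    :mod:`neuromotor.ephys_analysis`.

    A selector is a group name, a ``{"neuron_type": ...}`` match, or a list
    of either.
    """

    inputs: list[dict[str, Any]] = field(default_factory=list)
    responses: list[dict[str, Any]] = field(default_factory=list)
    setup: dict[str, Any] = field(default_factory=dict)
    runs: list[dict[str, Any]] = field(default_factory=list)
    plots: list[dict[str, Any]] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({k: getattr(self, k) for k in _SIM_KEYS}, indent=2)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "SimulationDefinition":
        unknown = set(d) - set(_SIM_KEYS)
        if unknown:
            raise ModelError(f"unknown simulation-definition sections {sorted(unknown)}")
        return cls(**{k: list(d[k]) if k != "setup" else dict(d[k])
                      for k in _SIM_KEYS if k in d})

    @classmethod
    def load(cls, path: str | Path) -> "SimulationDefinition":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def resolve_selector(model: ModelDefinition, selector: Any) -> list[str]:
    """Resolve a selector to a sorted list of cell-group names."""
    groups = model.cell_groups
    if isinstance(selector, str):
        hits = [g.name for g in groups if g.name == selector]
        if not hits and selector == "*":
            hits = [g.name for g in groups]
    elif isinstance(selector, Mapping):
        hits = [g.name for g in groups
                if all(getattr(g, key) == val for key, val in selector.items())]
    elif isinstance(selector, (list, tuple)):
        hits = []
        for s in selector:
            hits.extend(resolve_selector(model, s))
    else:
        raise ModelError(f"bad selector {selector!r}")
    hits = sorted(set(hits))
    if not hits:
        raise ModelError(
            f"selector {selector!r} matched no cell groups; available: "
            f"{sorted(g.name for g in groups)}")
    return hits


# ---------------------------------------------------------------------------
# Recordings
# ---------------------------------------------------------------------------


@dataclass
class Recordings:
    """Simulation output: time base, voltage traces, spikes, metadata.

    ``traces`` maps (group, variable) → array of shape (n_samples, n_cells);
    ``spikes`` maps group → list per cell of sorted spike times (ms).
    """

    time: np.ndarray
    traces: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    spikes: dict[str, list[list[float]]] = field(default_factory=dict)
    metadata: dict[str, Any] = field(default_factory=dict)

    def group_mean(self, group: str, variable: str = "v") -> np.ndarray:
        return self.traces[(group, variable)].mean(axis=1)

    def all_spikes(self, group: str) -> np.ndarray:
        return np.sort(np.concatenate(
            [np.asarray(s) for s in self.spikes.get(group, [])] or [np.empty(0)]))

    def to_frame(self) -> pd.DataFrame:
        """Long-format trace table (t, group, variable, cell, value)."""
        parts = []
        for (group, var), arr in self.traces.items():
            for cell in range(arr.shape[1]):
                parts.append(pd.DataFrame({
                    "t": self.time, "group": group, "variable": var,
                    "cell": cell, "value": arr[:, cell]}))
        return pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(
            columns=["t", "group", "variable", "cell", "value"])

    def save_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def save_hdf5(self, path: str | Path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("time", data=self.time)
            for (group, var), arr in self.traces.items():
                f.create_dataset(f"traces/{group}/{var}", data=arr)
            for group, per_cell in self.spikes.items():
                for i, sp in enumerate(per_cell):
                    f.create_dataset(f"spikes/{group}/{i}", data=np.asarray(sp))
            f.attrs["metadata"] = json.dumps(self.metadata)


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------


@dataclass
class _Wiring:
    """Realized fan-in for one net connection."""

    source: str
    dest: str
    weight: float
    delay: float
    tau: float
    e_rev: float
    pairs: np.ndarray          # (k, 2) array of (src_local, dst_local)


class Network:
    """Instantiated cells + synapses, ready to integrate."""

    def __init__(self, model: ModelDefinition, sim: SimulationDefinition,
                 seed: int):
        self.model = model
        self.sim = sim
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)

        templates = {name: CellTemplate.from_dict(d)
                     for name, d in model.aux.get("templates", {}).items()}
        self.batches: dict[str, Any] = {}
        self.positions: dict[str, np.ndarray] = {}
        for g in sorted(model.cell_groups, key=lambda g: g.name):
            n = g.realized_count if g.realized_count is not None else int(g.count.mean)
            if n == 0:
                continue
            tpl = templates.get(g.template)
            if tpl is None:
                from neuromotor.cell_models import builtin_template
                tpl = builtin_template(g.template)
            self.batches[g.name] = make_batch(tpl, n)
            pts = model.aux.get("positions", {}).get(g.name)
            self.positions[g.name] = (np.asarray(pts, dtype=float)
                                      if pts else np.zeros((n, 3)))

        # synaptic suppression mask (per group), used for the axonal
        # refractory window of directly recruited motoneurons under EES
        self._syn_mask: dict[str, np.ndarray] = {
            name: np.ones(b.n) for name, b in self.batches.items()}

        self.wirings: list[_Wiring] = []
        for c in sorted(model.net_connections, key=lambda c: (c.rule, c.source, c.dest)):
            if c.source not in self.batches or c.dest not in self.batches:
                continue
            n_src = self.batches[c.source].n
            n_dst = self.batches[c.dest].n
            conv = c.realized_convergence
            if conv is None:
                conv = max(1, int(round(c.convergence.mean)))
            conv = min(conv, n_src)
            weight = (c.realized_weight if c.realized_weight is not None
                      else float(c.weight.mean))
            pairs = []
            for dst in range(n_dst):
                srcs = rng.choice(n_src, size=conv, replace=False)
                pairs.extend((s, dst) for s in srcs)
            self.wirings.append(_Wiring(
                source=c.source, dest=c.dest, weight=weight, delay=c.delay,
                tau=c.tau, e_rev=c.e_rev, pairs=np.asarray(pairs, dtype=int)))

        ees_cfg = sim.setup.get("ees_recruitment", {})
        self.ees = EESRecruitment(**ees_cfg) if isinstance(ees_cfg, Mapping) \
            else ees_cfg

    # -- helpers ------------------------------------------------------------

    def group_names(self) -> list[str]:
        return sorted(self.batches)

    def _resolve(self, selector: Any) -> list[str]:
        names = resolve_selector(self.model, selector)
        return [n for n in names if n in self.batches]

    # -- main loop ----------------------------------------------------------

    def run(self, run_spec: Mapping[str, Any] | None = None,
            controller: Callable | None = None,
            control_interval: float = 1.0) -> Recordings:
        """Integrate the network for one run.

        ``run_spec``: ``{"duration" ms, "dt" ms, "seed", "overrides": {...}}``.
        Supported overrides: ``ees_amplitude`` (applied to every periodic
        EES input).  ``controller``, if given, is called every
        ``control_interval`` ms as ``controller(t, spikes_in_window,
        network)`` where ``spikes_in_window`` maps group → list per cell of
        spike times in the window; it may push events into spike-source
        groups (closed-loop biomechanics).
        """
        spec = dict(run_spec or {})
        duration = float(spec.get("duration", 160.0))
        dt = float(spec.get("dt", 0.025))
        if duration <= 0 or dt <= 0:
            raise ModelError("duration and dt must be > 0")
        overrides = dict(spec.get("overrides", {}))

        n_steps = int(round(duration / dt))
        time = np.arange(n_steps + 1) * dt

        # reset all state
        for b in self.batches.values():
            b.reset_state()
            if isinstance(b, MotoneuronBatch):
                b.settle()
        for m in self._syn_mask.values():
            m[:] = 1.0

        # --- wire stimuli
        iclamp_by_group: dict[str, list[tuple[StimulusSpec, float]]] = defaultdict(list)
        direct_mn_events: dict[str, list[float]] = {}
        suppression: dict[str, tuple[np.ndarray, list[float]]] = {}
        for inp in self.sim.inputs:
            stim = StimulusSpec.from_dict(inp["stimulus"])
            targets = self._resolve(inp["target"])
            if stim.kind == "iclamp_piecewise":
                scale = float(overrides.get("iclamp_scale", 1.0))
                for name in targets:
                    iclamp_by_group[name].append((stim, scale))
            else:
                amplitude = float(overrides.get("ees_amplitude", stim.amplitude))
                pulses = make_stimulus(stim, duration=duration)
                self._apply_ees(targets, amplitude, pulses,
                                direct_mn_events, suppression)

        # --- recording setup
        record_v: set[str] = set()
        record_ina: set[str] = set()
        for resp in self.sim.responses:
            targets = self._resolve(resp["target"])
            var = resp.get("variable", "v")
            if var == "v":
                record_v.update(targets)
            elif var in ("i_na", "ina"):
                record_ina.update(targets)
        traces: dict[tuple[str, str], np.ndarray] = {}
        for name in record_v:
            traces[(name, "v")] = np.empty((n_steps + 1, self.batches[name].n),
                                           dtype=np.float32)
        for name in record_ina:
            traces[(name, "i_na")] = np.zeros(
                (n_steps + 1, self.batches[name].n), dtype=np.float32)

        spikes: dict[str, list[list[float]]] = {
            name: [[] for _ in range(b.n)] for name, b in self.batches.items()}

        # --- synaptic channels: per (dest, tau, e_rev) conductance state
        channels: dict[tuple[str, float, float], np.ndarray] = {}
        chan_decay: dict[tuple[str, float, float], float] = {}
        for w in self.wirings:
            key = (w.dest, w.tau, w.e_rev)
            if key not in channels:
                channels[key] = np.zeros(self.batches[w.dest].n)
                chan_decay[key] = float(np.exp(-dt / w.tau))
        by_dest: dict[str, list[tuple[float, float]]] = defaultdict(list)
        for key in channels:
            by_dest[key[0]].append((key[1], key[2]))
        # step-indexed event queue: step -> list of (channel key, dst, weight)
        queue: dict[int, list[tuple[tuple, int, float]]] = defaultdict(list)
        # wiring lookup by source group for spike propagation
        by_source: dict[str, list[_Wiring]] = defaultdict(list)
        for w in self.wirings:
            by_source[w.source].append(w)

        def deliver(src_group: str, src_local: int, t_spike: float) -> None:
            for w in by_source[src_group]:
                step_idx = int(np.ceil((t_spike + w.delay) / dt - 1e-9))
                mask = w.pairs[:, 0] == src_local
                for dst in w.pairs[mask, 1]:
                    queue[step_idx].append(((w.dest, w.tau, w.e_rev), int(dst),
                                            w.weight))

        # initial samples
        for name in record_v:
            traces[(name, "v")][0] = _voltage_of(self.batches[name])

        window_spikes: dict[str, list[list[float]]] = {
            name: [[] for _ in range(b.n)] for name, b in self.batches.items()}
        next_control = control_interval

        for i in range(n_steps):
            t = i * dt
            # deliver queued synaptic events for this step
            for key, dst, weight in queue.pop(i, ()):  # type: ignore[arg-type]
                channels[key][dst] += weight
            # build per-group synaptic conductance lists
            for name, b in self.batches.items():
                syn = []
                mask = self._syn_mask[name]
                for tau, e_rev in by_dest.get(name, ()):
                    syn.append((channels[(name, tau, e_rev)] * mask, e_rev))
                i_inj = np.zeros(b.n)
                for stim, scale in iclamp_by_group.get(name, ()):  # type: ignore[call-overload]
                    i_inj += scale * float(iclamp_value(stim, t))
                st = b.step(t, dt, i_inj, syn,
                            record_i_na=(name in record_ina))
                fired = np.flatnonzero(~np.isnan(st))
                for j in fired:
                    ts = float(st[j])
                    spikes[name][j].append(ts)
                    window_spikes[name][j].append(ts)
                    deliver(name, j, ts)
                if name in record_v:
                    traces[(name, "v")][i + 1] = _voltage_of(b)
                if name in record_ina and isinstance(b, MotoneuronBatch) \
                        and b.i_na_trace is not None:
                    traces[(name, "i_na")][i + 1] = b.i_na_trace
            # decay conductances
            for key, g in channels.items():
                g *= chan_decay[key]
            # EES direct motoneuron recruitment: forced spikes + suppression
            self._update_ees_state(t, dt, direct_mn_events, suppression,
                                   spikes, window_spikes, deliver)
            # closed-loop controller
            if controller is not None and t + dt >= next_control - 1e-9:
                controller(t + dt, window_spikes, self)
                window_spikes = {name: [[] for _ in range(b.n)]
                                 for name, b in self.batches.items()}
                next_control += control_interval

        return Recordings(
            time=time,
            traces=traces,
            spikes=spikes,
            metadata={"duration": duration, "dt": dt, "seed": self.seed,
                      "overrides": overrides},
        )

    # -- EES ----------------------------------------------------------------

    def _apply_ees(self, targets: Sequence[str], amplitude: float,
                   pulses: np.ndarray,
                   direct_mn_events: dict[str, list[float]],
                   suppression: dict[str, tuple]) -> None:
        """Recruit afferents (pulse-locked events) and motoneuron axons."""
        for name in targets:
            b = self.batches[name]
            g = self.model.group(name)
            if isinstance(b, SpikeSourceBatch):
                frac = self.ees.f_aff(amplitude)
                k = int(round(frac * b.n))
                events = [list(pulses) if idx < k else [] for idx in range(b.n)]
                b.set_events(events)
            elif g.neuron_type == "AlphaMoto":
                frac = self.ees.f_mn(amplitude)
                k = int(round(frac * b.n))
                if k > 0:
                    direct_mn_events[name] = list(pulses)
                    suppression[name] = (np.arange(k), list(pulses))

    #: antidromic invasion latency (ms) and somatic refractory window (ms)
    #: for directly recruited motoneuron axons
    EES_ANTIDROMIC_LATENCY = 0.6
    EES_AXON_REFRACTORY = 12.0

    def _update_ees_state(self, t: float, dt: float,
                          direct_mn_events: dict[str, list[float]],
                          suppression: dict[str, tuple],
                          spikes, window_spikes, deliver) -> None:
        for name, pulses in direct_mn_events.items():
            b = self.batches[name]
            recruited, _ = suppression[name]
            for p in pulses:
                t_spike = p + self.EES_ANTIDROMIC_LATENCY
                if t <= t_spike < t + dt:
                    # antidromic invasion: force a somatic spike in the
                    # recruited cells by clamping them above threshold
                    b.v_s[recruited] = 30.0
                    b.last_spike[recruited] = t_spike
                    for j in recruited:
                        spikes[name][j].append(t_spike)
                        window_spikes[name][j].append(t_spike)
                        deliver(name, int(j), t_spike)
                # synaptic suppression through the medium-late window
                if p <= t < p + self.EES_AXON_REFRACTORY:
                    self._syn_mask[name][recruited] = 0.0
                    break
            else:
                self._syn_mask[name][:] = 1.0


def _voltage_of(batch: Any) -> np.ndarray:
    if isinstance(batch, MotoneuronBatch):
        return batch.v_s
    if isinstance(batch, IntegrateFireBatch):
        return batch.v
    return np.zeros(batch.n)


# ---------------------------------------------------------------------------
# API entry points
# ---------------------------------------------------------------------------


def build_network(model: ModelDefinition, sim: SimulationDefinition,
                  seed: int) -> Network:
    """Instantiate a network; deterministic for a fixed seed."""
    return Network(model, sim, seed)


def run(network: Network, run_spec: Mapping[str, Any] | None = None,
        **kwargs) -> Recordings:
    return network.run(run_spec, **kwargs)


def run_all(model: ModelDefinition, sim: SimulationDefinition,
            seed: int | None = None) -> list[Recordings]:
    """Execute every entry in the simulation definition's ``runs`` section."""
    if not sim.runs:
        raise ModelError("nothing to run: empty `runs` section")
    out = []
    for spec in sim.runs:
        run_seed = int(spec.get("seed", seed if seed is not None else 0))
        net = build_network(model, sim, run_seed)
        out.append(net.run(spec))
    return out
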