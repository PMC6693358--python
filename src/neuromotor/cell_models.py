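"""Cell dynamics: conductance-based motoneurons, integrate-and-fire
interneurons, spike sources, synapses, and stimulus generators.

Motoneurons (classes ``hh_motoneuron`` and ``bistable_2c``) are
two-compartment (soma + lumped dendrite) conductance models in the style of
the classic reduced vertebrate motoneuron: fast sodium and delayed-rectifier
potassium on the soma, N-type calcium on both compartments, an L-type
("persistent inward") calcium current on the dendrite, and
calcium-dependent potassium (K(Ca)) driven by per-compartment calcium pools.
The K(Ca)/calcium-pool pair produces spike-rate adaptation and the
post-spike AHP that sets the steady firing rate; the dendritic L-type
current produces plateau potentials and counterclockwise FI hysteresis when
its K(Ca) brake is reduced (the serotonergic "5-HT" condition, modeled as a
40% reduction of ``gkcabar_KCa``).

The three motoneuron size classes S / FR / FF share kinetics and differ in
electrotonic size (membrane area, leak) and adaptation strength; their
maximal conductances are calibrated so that rheobase and steady-state firing
rates fall in the physiological ranges for each class (S lowest rheobase,
FF highest; steady rates in the low tens of Hz).

Interneurons are leaky integrate-and-fire cells; afferents are spike
sources driven by explicit event times or time-varying rates.

All voltages are mV, times ms, currents nA, conductances μS (densities in
mS/cm², areas in cm²), capacitances nF, calcium in arbitrary pool units
(μM-like).
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

import numpy as np

from neuromotor.model_def import ModelError, RandomScalar

MODEL_CLASSES = ("hh_motoneuron", "bistable_2c", "integrate_fire", "spike_source")

#: Spike detection threshold (mV) for conductance models: upward crossing.
SPIKE_THRESHOLD = -10.0

#: Absolute refractory periods (ms) by motoneuron class, used by spike
#: detection; interneurons carry theirs in the template.
DEFAULT_REFRACTORY = {"S": 5.0, "FR": 2.5, "FF": 2.5}


# ---------------------------------------------------------------------------
# Templates
# ---------------------------------------------------------------------------


@dataclass
class CellTemplate:
    """Parameterized cell model: sections, mechanisms, passive properties.

    ``sections`` is a list of dicts ``{name, length, diameter,
    n_compartments, parent}`` (μm; diameter may be a RandomScalar dict).
    ``mechanisms`` maps section name → mechanism name → parameter map; the
    conventional NEURON-style density names (``gnabar``, ``gkdrbar``,
    ``gcanbar``, ``gcalbar``, ``gkcabar``, mS/cm²) are used throughout so
    templates are diffable against published parameter sets.  ``range`` is
    the number of perisomatic dendritic compartments carrying the CaL / CaN
    / K(Ca) mechanisms (sections are ordered by path distance from the
    soma); with a lumped dendrite it scales the effective dendritic density
    by ``range / n_compartments``.
    """

    name: str
    model_class: str
    sections: list[dict[str, Any]] = field(default_factory=list)
    mechanisms: dict[str, dict[str, dict[str, float]]] = field(default_factory=dict)
    passive: dict[str, float] = field(default_factory=dict)
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model_class not in MODEL_CLASSES:
            raise ModelError(f"template {self.name}: unknown class {self.model_class!r}")
        if self.model_class in ("hh_motoneuron", "bistable_2c"):
            names = [s["name"] for s in self.sections]
            if "soma" not in names:
                raise ModelError(f"template {self.name}: soma section required")

    # -- parameter paths ----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return {
            "name": self.name,
            "model_class": self.model_class,
            "sections": copy.deepcopy(self.sections),
            "mechanisms": copy.deepcopy(self.mechanisms),
            "passive": dict(self.passive),
            "params": copy.deepcopy(self.params),
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "CellTemplate":
        return cls(
            name=d["name"],
            model_class=d["model_class"],
            sections=copy.deepcopy(list(d.get("sections", []))),
            mechanisms=copy.deepcopy(dict(d.get("mechanisms", {}))),
            passive=dict(d.get("passive", {})),
            params=copy.deepcopy(dict(d.get("params", {}))),
        )

    def copy(self, name: str | None = None) -> "CellTemplate":
        t = CellTemplate.from_dict(self.to_dict())
        if name:
            t.name = name
        return t

    def flatten(self) -> dict[str, Any]:
        """All scalar parameters as dotted paths (used by compare/tuning)."""
        flat: dict[str, Any] = {}

        def walk(prefix: str, obj: Any) -> None:
            if isinstance(obj, Mapping):
                for k, v in obj.items():
                    walk(f"{prefix}.{k}" if prefix else str(k), v)
            elif isinstance(obj, list):
                for item in obj:
                    if isinstance(item, Mapping) and "name" in item:
                        walk(f"{prefix}.{item['name']}", {k: v for k, v in item.items() if k != "name"})
                    else:
                        return  # non-named lists are structural, not parameters
            else:
                flat[prefix] = obj

        walk("", {
            "model_class": self.model_class,
            "sections": self.sections,
            "mechanisms": self.mechanisms,
            "passive": self.passive,
            "params": self.params,
        })
        return flat

    def get_param(self, path: str) -> Any:
        obj: Any = self._root()
        for key in path.split("."):
            if isinstance(obj, list):
                obj = next(s for s in obj if s.get("name") == key)
            else:
                obj = obj[key]
        return obj

    def set_param(self, path: str, value: Any) -> None:
        keys = path.split(".")
        obj: Any = self._root()
        for key in keys[:-1]:
            if isinstance(obj, list):
                obj = next(s for s in obj if s.get("name") == key)
            else:
                obj = obj.setdefault(key, {}) if isinstance(obj, dict) else obj[key]
        if isinstance(obj, list):
            raise KeyError(path)
        obj[keys[-1]] = value

    def _root(self) -> dict[str, Any]:
        return {
            "sections": self.sections,
            "mechanisms": self.mechanisms,
            "passive": self.passive,
            "params": self.params,
        }

    # -- convenience --------------------------------------------------------

    def section(self, name: str) -> dict[str, Any]:
        for s in self.sections:
            if s["name"] == name:
                return s
        raise KeyError(name)

    def with_serotonin(self) -> "CellTemplate":
        """5-HT condition: reduce every ``gkcabar`` by 40% (×0.6)."""
        t = self.copy()
        for mechs in t.mechanisms.values():
            for mech in mechs.values():
                if "gkcabar" in mech:
                    mech["gkcabar"] *= 0.6
        t.params["serotonin"] = True
        return t


def _section_area_cm2(section: Mapping[str, Any]) -> float:
    """Membrane area: sphere for soma, cylinder otherwise (μm → cm²)."""
    diam = section["diameter"]
    if isinstance(diam, Mapping):
        diam = diam["mean"]
    if section["name"] == "soma":
        area_um2 = math.pi * float(diam) ** 2
    else:
        area_um2 = math.pi * float(diam) * float(section["length"])
    return area_um2 * 1e-8


# ---------------------------------------------------------------------------
# Built-in calibrated templates
# ---------------------------------------------------------------------------

# Shared gating kinetics (mV, ms) for the reduced motoneuron.
MOTO_KINETICS = {
    "ena": 55.0,
    "ek": -80.0,
    "eca": 80.0,
    # Na activation (instantaneous) / inactivation
    "m_half": -35.0, "m_slope": 7.8,
    "h_half": -55.0, "h_slope": 7.0,
    # delayed rectifier
    "n_half": -28.0, "n_slope": 15.0,
    # N-type Ca
    "mn_half": -30.0, "mn_slope": 5.0, "mn_tau": 4.0,
    "hn_half": -45.0, "hn_slope": 5.0, "hn_tau": 40.0,
    # L-type Ca (persistent inward current)
    "ml_half": -40.0, "ml_slope": 7.0, "ml_tau": 40.0,
    # calcium pool
    "ca_f": 0.01, "ca_alpha": 0.009, "ca_kca": 2.0, "ca_kd": 0.2,
}


def _motoneuron_template(
    name: str,
    model_class: str,
    soma_diam: float,
    dend_diam: float,
    dend_len: float,
    gna: float,
    gkdr: float,
    gcan_s: float,
    gkca_s: float,
    gcan_d: float,
    gcal_d: float,
    gkca_d: float,
    gl: float,
    el: float,
    gc_us: float,
    refractory: float,
    rng_sections: int = 4,
) -> CellTemplate:
    return CellTemplate(
        name=name,
        model_class=model_class,
        sections=[
            {"name": "soma", "length": soma_diam, "diameter": soma_diam,
             "n_compartments": 1, "parent": None},
            {"name": "dendrite", "length": dend_len, "diameter": dend_diam,
             "n_compartments": 4, "parent": "soma"},
        ],
        mechanisms={
            "soma": {
                "Na": {"gnabar": gna},
                "Kdr": {"gkdrbar": gkdr},
                "CaN": {"gcanbar": gcan_s},
                "KCa": {"gkcabar": gkca_s},
            },
            "dendrite": {
                "CaN": {"gcanbar": gcan_d},
                "CaL": {"gcalbar": gcal_d},
                "KCa": {"gkcabar": gkca_d},
            },
        },
        passive={"cm": 1.0, "g_leak": gl, "e_leak": el},
        params={
            "coupling_us": gc_us,
            "refractory": refractory,
            "range": rng_sections,
            **MOTO_KINETICS,
        },
    )


def _builtin_templates() -> dict[str, CellTemplate]:
    # Maximal conductances (mS/cm²) and calcium-pool constants calibrated so
    # that rheobase and steady-rate targets for the three size classes hold
    # (S: rheobase ~2.4 nA, 22 Hz at 12 nA; FR: ~13.3 nA, 32 Hz at 18 nA;
    # FF: ~24.2 nA, 32.5 Hz at 25 nA); see docs/methods.md.
    slow = _motoneuron_template(
        "M_cell_Slow", "hh_motoneuron",
        soma_diam=82.0, dend_diam=10.0, dend_len=2500.0,
        gna=120.0, gkdr=100.0, gcan_s=4.0, gkca_s=17.9,
        gcan_d=0.3, gcal_d=0.0, gkca_d=1.1,
        gl=0.4482, el=-65.0, gc_us=0.1, refractory=DEFAULT_REFRACTORY["S"],
    )
    slow.params["ca_alpha"] = 0.1
    fr = _motoneuron_template(
        "M_cell_FR", "hh_motoneuron",
        soma_diam=90.0, dend_diam=12.0, dend_len=4000.0,
        gna=120.0, gkdr=100.0, gcan_s=4.0, gkca_s=7.05,
        gcan_d=0.3, gcal_d=0.0, gkca_d=1.1,
        gl=2.6592, el=-65.0, gc_us=0.15, refractory=DEFAULT_REFRACTORY["FR"],
    )
    fr.params["ca_alpha"] = 0.05
    ff = _motoneuron_template(
        "M_cell_FF", "hh_motoneuron",
        soma_diam=100.0, dend_diam=14.0, dend_len=5000.0,
        gna=120.0, gkdr=100.0, gcan_s=4.0, gkca_s=1.3,
        gcan_d=0.3, gcal_d=0.0, gkca_d=1.1,
        gl=4.0962, el=-65.0, gc_us=0.2, refractory=DEFAULT_REFRACTORY["FF"],
    )
    ff.params["ca_alpha"] = 0.05
    ff.params["ca_kca"] = 16.0
    # The bistable cell keeps the S-type soma but a tighter electrotonic
    # dendrite whose L-type Ca current has a reachable activation fold
    # (half −52 mV): with 5-HT (gkcabar ×0.6) the dendritic plateau persists
    # on the descending limb of a triangular ramp, giving counterclockwise
    # FI hysteresis; without 5-HT the K(Ca) brake suppresses it.
    bistable = _motoneuron_template(
        "M_cell_bistable", "bistable_2c",
        soma_diam=82.0, dend_diam=10.0, dend_len=2500.0,
        gna=120.0, gkdr=100.0, gcan_s=4.0, gkca_s=5.0,
        gcan_d=0.3, gcal_d=0.2, gkca_d=1.0,
        gl=0.4482, el=-65.0, gc_us=0.35, refractory=DEFAULT_REFRACTORY["S"],
    )
    bistable.passive["g_leak_dend"] = 0.1
    bistable.params.update(
        ca_alpha=0.1, ml_half=-52.0, ml_slope=5.0, ml_tau=60.0)
    # The reflex-network motoneuron is its own cell model: moderate
    # adaptation and a ramp rheobase of ~3 nA (type-2 FI onset near 27 Hz),
    # with the fuller section list used in network models.
    srr = _motoneuron_template(
        "M_cell_srr", "hh_motoneuron",
        soma_diam=82.0, dend_diam=10.0, dend_len=2500.0,
        gna=120.0, gkdr=100.0, gcan_s=4.0, gkca_s=5.0,
        gcan_d=0.3, gcal_d=0.0, gkca_d=1.1,
        gl=0.99, el=-65.0, gc_us=0.1, refractory=DEFAULT_REFRACTORY["S"],
    )
    srr.params["ca_alpha"] = 0.1
    srr.sections.append(
        {"name": "inseg", "length": 30.0, "diameter": 10.0,
         "n_compartments": 1, "parent": "soma"}
    )
    interneuron = CellTemplate(
        name="interneuron_if",
        model_class="integrate_fire",
        sections=[{"name": "soma", "length": 20.0, "diameter": 20.0,
                   "n_compartments": 1, "parent": None}],
        passive={"cm": 1.0},
        params={
            "tau_m": 10.0,      # membrane time constant, ms
            "r_in": 100.0,      # input resistance, MΩ (mV per nA)
            "v_rest": -65.0,
            "v_thresh": -50.0,
            "v_reset": -65.0,
            "refractory": 1.0,
        },
    )
    source = CellTemplate(
        name="afferent_source",
        model_class="spike_source",
        params={"refractory": 1.0},
    )
    out = {t.name: t for t in (slow, fr, ff, bistable, srr, interneuron, source)}
    return out


_BUILTINS: dict[str, CellTemplate] | None = None


def builtin_template(name: str) -> CellTemplate:
    global _BUILTINS
    if _BUILTINS is None:
        _BUILTINS = _builtin_templates()
    if name not in _BUILTINS:
        raise KeyError(f"no built-in template {name!r}; have {sorted(_BUILTINS)}")
    return _BUILTINS[name].copy()


def has_builtin_template(name: str) -> bool:
    global _BUILTINS
    if _BUILTINS is None:
        _BUILTINS = _builtin_templates()
    return name in _BUILTINS


# ---------------------------------------------------------------------------
# Stimuli
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StimulusSpec:
    """Either a piecewise-linear current clamp or a periodic EES pulse train.

    ``iclamp_piecewise``: ``breakpoints`` is a time-sorted list of
    ``(t_ms, I_nA)``; between breakpoints the current is linearly
    interpolated, after the last it holds the last value.

    ``periodic_ees``: pulses at ``onset_delay + k * (1000 / rate)`` for
    ``k = 1, 2, ...`` — with 8 Hz and a 10 ms delay the first pulse falls at
    135 ms.  ``amplitude`` is in recruitment-model units (see
    :class:`neuromotor.simulator.EESRecruitment`).
    """

    kind: str
    breakpoints: tuple[tuple[float, float], ...] = ()
    rate: float = 0.0
    onset_delay: float = 0.0
    amplitude: float = 0.0
    n_pulses: int | None = None
    end_time: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("iclamp_piecewise", "periodic_ees"):
            raise ModelError(f"unknown stimulus kind {self.kind!r}")
        if self.kind == "iclamp_piecewise":
            times = [t for t, _ in self.breakpoints]
            if times != sorted(times):
                raise ModelError("iclamp breakpoints must be time-sorted")
            if not self.breakpoints:
                raise ModelError("iclamp needs at least one breakpoint")
        else:
            if self.rate <= 0:
                raise ModelError("EES rate must be > 0")

    @classmethod
    def iclamp(cls, breakpoints: Iterable[tuple[float, float]]) -> "StimulusSpec":
        return cls(kind="iclamp_piecewise", breakpoints=tuple(
            (float(t), float(i)) for t, i in breakpoints))

    @classmethod
    def ees(cls, rate: float, onset_delay: float, amplitude: float = 1.0,
            n_pulses: int | None = None, end_time: float | None = None,
            ) -> "StimulusSpec":
        return cls(kind="periodic_ees", rate=rate, onset_delay=onset_delay,
                   amplitude=amplitude, n_pulses=n_pulses, end_time=end_time)

    def to_dict(self) -> dict[str, Any]:
        if self.kind == "iclamp_piecewise":
            return {"kind": self.kind, "breakpoints": [list(b) for b in self.breakpoints]}
        d: dict[str, Any] = {"kind": self.kind, "rate": self.rate,
                             "onset_delay": self.onset_delay, "amplitude": self.amplitude}
        if self.n_pulses is not None:
            d["n_pulses"] = self.n_pulses
        if self.end_time is not None:
            d["end_time"] = self.end_time
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "StimulusSpec":
        if d["kind"] == "iclamp_piecewise":
            return cls.iclamp(d["breakpoints"])
        return cls.ees(d["rate"], d.get("onset_delay", 0.0), d.get("amplitude", 1.0),
                       d.get("n_pulses"), d.get("end_time"))


def make_stimulus(spec: StimulusSpec, duration: float | None = None,
                  dt: float | None = None) -> np.ndarray:
    """Materialize a stimulus.

    For ``periodic_ees`` returns the pulse (event) times in ms.  For
    ``iclamp_piecewise`` returns the current waveform sampled on
    ``arange(0, duration + dt, dt)`` (requires ``duration`` and ``dt``).
    """
    if spec.kind == "periodic_ees":
        period = 1000.0 / spec.rate
        end = spec.end_time if spec.end_time is not None else (
            duration if duration is not None else spec.onset_delay + 10 * period)
        times = []
        k = 1
        while True:
            t = spec.onset_delay + k * period
            if t > end or (spec.n_pulses is not None and k > spec.n_pulses):
                break
            times.append(t)
            k += 1
        return np.asarray(times, dtype=float)
    if duration is None or dt is None:
        raise ModelError("iclamp waveform needs duration and dt")
    t = np.arange(0.0, duration + dt / 2, dt)
    return iclamp_value(spec, t)


def iclamp_value(spec: StimulusSpec, t: np.ndarray | float) -> np.ndarray:
    """Piecewise-linear interpolation with constant extrapolation."""
    times = np.array([b[0] for b in spec.breakpoints])
    amps = np.array([b[1] for b in spec.breakpoints])
    return np.interp(np.asarray(t, dtype=float), times, amps)


# ---------------------------------------------------------------------------
# Synapses
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SynapseSpec:
    """Single-exponential conductance synapse."""

    sign: str
    weight: float   # μS
    delay: float    # ms
    tau: float      # ms
    e_rev: float    # mV

    def __post_init__(self) -> None:
        if self.delay <= 0 or self.tau <= 0:
            raise ModelError("synapse delay and tau must be > 0")


def synapse_conductance(spec: SynapseSpec, presyn_spike_times: Sequence[float],
                        t: float) -> float:
    """g(t) = weight · Σ exp(−(t − t_spike − delay)/tau) over delivered spikes."""
    g = 0.0
    for ts in presyn_spike_times:
        dt = t - ts - spec.delay
        if dt >= 0:
            g += math.exp(-dt / spec.tau)
    return spec.weight * g


def synapse_update(spec: SynapseSpec, presyn_spike_times: Sequence[float],
                   t: float, v_post: float) -> float:
    """Synaptic current (nA, outward-positive): g(t) · (v_post − e_rev)."""
    return synapse_conductance(spec, presyn_spike_times, t) * (v_post - spec.e_rev)


# ---------------------------------------------------------------------------
# Batched cell dynamics
# ---------------------------------------------------------------------------


def _sigmoid(v: np.ndarray, half: float, slope: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(v - half) / slope))


class MotoneuronBatch:
    """Vectorized two-compartment conductance motoneurons.

    One batch holds ``n`` cells sharing kinetics but with per-cell maximal
    conductances/areas (so amplitude sweeps and heterogeneous pools run in a
    single vectorized integration).  Exponential-Euler update per
    compartment; gating variables use the exact exponential update for
    frozen voltage.  Spike times are the linearly interpolated upward
    crossings of −10 mV, subject to the absolute refractory period.
    """

    model_kind = "conductance"

    def __init__(self, templates: Sequence[CellTemplate] | CellTemplate,
                 n: int | None = None):
        if isinstance(templates, CellTemplate):
            templates = [templates] * (n or 1)
        self.templates = list(templates)
        self.n = len(self.templates)
        k = MOTO_KINETICS

        def arr(fn) -> np.ndarray:
            return np.array([fn(t) for t in self.templates], dtype=float)

        self.area_s = arr(lambda t: _section_area_cm2(t.section("soma")))
        self.area_d = arr(lambda t: _section_area_cm2(t.section("dendrite")))
        # perisomatic placement: fraction of dendritic compartments carrying
        # the Ca/K(Ca) mechanisms
        self.range_frac = arr(
            lambda t: min(1.0, float(t.params.get("range", 4))
                          / float(t.section("dendrite")["n_compartments"])))
        cm = arr(lambda t: t.passive.get("cm", 1.0))
        self.c_s = cm * self.area_s * 1e3          # nF
        self.c_d = cm * self.area_d * 1e3

        def gbar(section: str, mech: str, pname: str) -> np.ndarray:
            return arr(lambda t: t.mechanisms.get(section, {}).get(mech, {}).get(pname, 0.0))

        to_us_s = self.area_s * 1e3                 # mS/cm² → μS
        to_us_d = self.area_d * 1e3
        self.g_na = gbar("soma", "Na", "gnabar") * to_us_s
        self.g_kdr = gbar("soma", "Kdr", "gkdrbar") * to_us_s
        self.g_can_s = gbar("soma", "CaN", "gcanbar") * to_us_s
        self.g_kca_s = gbar("soma", "KCa", "gkcabar") * to_us_s
        self.g_can_d = gbar("dendrite", "CaN", "gcanbar") * to_us_d * self.range_frac
        self.g_cal_d = gbar("dendrite", "CaL", "gcalbar") * to_us_d * self.range_frac
        self.g_kca_d = gbar("dendrite", "KCa", "gkcabar") * to_us_d * self.range_frac
        self.g_l_s = arr(lambda t: t.passive["g_leak"]) * to_us_s
        self.g_l_d = arr(
            lambda t: t.passive.get("g_leak_dend", t.passive["g_leak"])) * to_us_d
        self.e_l = arr(lambda t: t.passive["e_leak"])
        self.g_c = arr(lambda t: t.params["coupling_us"])
        self.refractory = arr(lambda t: t.params.get("refractory", 2.5))
        # voltage kinetics are shared (first template); calcium-pool
        # parameters are per-cell so size classes can differ in adaptation
        self.k = {**k, **{key: self.templates[0].params[key]
                          for key in k if key in self.templates[0].params
                          and not key.startswith("ca_")}}
        self.ca_f = arr(lambda t: t.params.get("ca_f", k["ca_f"]))
        self.ca_alpha = arr(lambda t: t.params.get("ca_alpha", k["ca_alpha"]))
        self.ca_kca = arr(lambda t: t.params.get("ca_kca", k["ca_kca"]))
        self.ca_kd = arr(lambda t: t.params.get("ca_kd", k["ca_kd"]))
        # Na inactivation is also per-cell: accommodation strength differs
        # between templates and mixed batches must honor each template
        self.h_half = arr(lambda t: t.params.get("h_half", k["h_half"]))
        self.h_slope = arr(lambda t: t.params.get("h_slope", k["h_slope"]))

        self.reset_state()

    def reset_state(self) -> None:
        k = self.k
        v0 = self.e_l.copy()
        self.v_s = v0.copy()
        self.v_d = v0.copy()
        self.h = _sigmoid(v0, self.h_half, -self.h_slope)
        self.nK = _sigmoid(v0, k["n_half"], k["n_slope"])
        self.mn_s = _sigmoid(v0, k["mn_half"], k["mn_slope"])
        self.hn_s = _sigmoid(v0, k["hn_half"], -k["hn_slope"])
        self.mn_d = self.mn_s.copy()
        self.hn_d = self.hn_s.copy()
        self.ml = _sigmoid(v0, k["ml_half"], k["ml_slope"])
        self.ca_s = np.zeros(self.n)
        self.ca_d = np.zeros(self.n)
        self.last_spike = np.full(self.n, -1e9)
        self._prev_vs = self.v_s.copy()
        self.i_na_trace: float | None = None  # populated per step if requested

    _REST_CACHE: dict = {}

    def settle(self, t_ms: float = 300.0, dt: float = 0.05) -> None:
        """Relax to rest with zero input (initialization).

        The rest state only depends on the template, so it is computed once
        per distinct template (single representative cell) and broadcast.
        """
        import json as _json

        reps: dict[str, int] = {}
        keys = []
        for i, tpl in enumerate(self.templates):
            key = _json.dumps(tpl.to_dict(), sort_keys=True, default=str)
            keys.append(key)
            reps.setdefault(key, i)
        missing = [key for key in reps if (key, t_ms, dt) not in self._REST_CACHE]
        if missing:
            sub = MotoneuronBatch([self.templates[reps[key]] for key in missing])
            for _ in range(int(round(t_ms / dt))):
                sub.step(0.0, dt)
            state = sub.state_dict()
            for j, key in enumerate(missing):
                self._REST_CACHE[(key, t_ms, dt)] = {
                    name: arr[j] for name, arr in state.items()}
        for i, key in enumerate(keys):
            cached = self._REST_CACHE[(key, t_ms, dt)]
            for name, value in cached.items():
                getattr(self, name)[i] = value
        self.last_spike[:] = -1e9

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name).copy() for name in (
            "v_s", "v_d", "h", "nK", "mn_s", "hn_s", "mn_d", "hn_d", "ml",
            "ca_s", "ca_d", "last_spike")}

    def set_state(self, state: Mapping[str, np.ndarray]) -> None:
        for name, value in state.items():
            getattr(self, name)[:] = value

    @staticmethod
    def _exp_update(v: np.ndarray, A: np.ndarray, G: np.ndarray,
                    c: np.ndarray, dt: float) -> np.ndarray:
        v_inf = A / G
        return v_inf + (v - v_inf) * np.exp(-dt * G / c)

    def _advance_ca(self, ca_s: np.ndarray, ca_d: np.ndarray,
                    mn_s: np.ndarray, hn_s: np.ndarray, mn_d: np.ndarray,
                    hn_d: np.ndarray, ml: np.ndarray,
                    vs: np.ndarray, vd: np.ndarray, dt: float) -> tuple:
        """Calcium pools driven by the Ca current density (μA/cm²), exact
        exponential update for the current frozen at the supplied gates/V."""
        k = self.k
        g_can_s = self.g_can_s * mn_s**2 * hn_s
        g_can_d = self.g_can_d * mn_d**2 * hn_d
        g_cal_d = self.g_cal_d * ml
        i_ca_s = (g_can_s * (vs - k["eca"])) / (self.area_s * 1e3)
        i_ca_d = ((g_can_d + g_cal_d) * (vd - k["eca"])) / (self.area_d * 1e3)
        decay = np.exp(-self.ca_f * self.ca_kca * dt)
        ca_inf_s = -self.ca_alpha * i_ca_s / self.ca_kca
        ca_inf_d = -self.ca_alpha * i_ca_d / self.ca_kca
        new_s = np.maximum(0.0, ca_inf_s + (ca_s - ca_inf_s) * decay)
        new_d = np.maximum(0.0, ca_inf_d + (ca_d - ca_inf_d) * decay)
        return new_s, new_d

    def _advance_gates(self, gates: tuple, vs: np.ndarray, vd: np.ndarray,
                       dt: float) -> tuple:
        """Exact exponential gate/Ca update with kinetics frozen at (vs, vd)."""
        k = self.k
        h, nK, mn_s, hn_s, mn_d, hn_d, ml, ca_s, ca_d = gates
        h_inf = _sigmoid(vs, self.h_half, -self.h_slope)
        tau_h = 30.0 / (np.exp((vs + 50.0) / 15.0) + np.exp(-(vs + 50.0) / 16.0))
        n_inf = _sigmoid(vs, k["n_half"], k["n_slope"])
        tau_n = 7.0 / (np.exp((vs + 40.0) / 40.0) + np.exp(-(vs + 40.0) / 50.0))
        h = h_inf + (h - h_inf) * np.exp(-dt / tau_h)
        nK = n_inf + (nK - n_inf) * np.exp(-dt / tau_n)
        mn_decay = math.exp(-dt / k["mn_tau"])
        hn_decay = math.exp(-dt / k["hn_tau"])
        for_pairs = []
        for gate, v, half, slope, decay in (
                (mn_s, vs, k["mn_half"], k["mn_slope"], mn_decay),
                (hn_s, vs, k["hn_half"], -k["hn_slope"], hn_decay),
                (mn_d, vd, k["mn_half"], k["mn_slope"], mn_decay),
                (hn_d, vd, k["hn_half"], -k["hn_slope"], hn_decay)):
            inf = _sigmoid(v, half, slope)
            for_pairs.append(inf + (gate - inf) * decay)
        mn_s, hn_s, mn_d, hn_d = for_pairs
        ml_inf = _sigmoid(vd, k["ml_half"], k["ml_slope"])
        ml = ml_inf + (ml - ml_inf) * math.exp(-dt / k["ml_tau"])
        ca_s, ca_d = self._advance_ca(
            ca_s, ca_d, mn_s, hn_s, mn_d, hn_d, ml, vs, vd, dt)
        return (h, nK, mn_s, hn_s, mn_d, hn_d, ml, ca_s, ca_d)

    def _membrane_coeffs(self, gates: tuple, vs: np.ndarray, vd: np.ndarray,
                         g_syn_sum: np.ndarray, ge_syn_sum: np.ndarray,
                         i_inj: np.ndarray) -> tuple:
        """Linear membrane coefficients dV/dt = (A − G·V)/C for both
        compartments; coupling enters through the supplied (vs, vd)."""
        k = self.k
        h, nK, mn_s, hn_s, mn_d, hn_d, ml, ca_s, ca_d = gates
        m_inf = _sigmoid(vs, k["m_half"], k["m_slope"])
        g_na = self.g_na * m_inf**3 * h
        g_kdr = self.g_kdr * nK**4
        g_can_s = self.g_can_s * mn_s**2 * hn_s
        g_kca_s = self.g_kca_s * ca_s / (ca_s + self.ca_kd)
        g_can_d = self.g_can_d * mn_d**2 * hn_d
        g_cal_d = self.g_cal_d * ml
        g_kca_d = self.g_kca_d * ca_d / (ca_d + self.ca_kd)
        G_s = g_na + g_kdr + g_can_s + g_kca_s + self.g_l_s + self.g_c + g_syn_sum
        A_s = (g_na * k["ena"] + g_kdr * k["ek"] + g_can_s * k["eca"]
               + g_kca_s * k["ek"] + self.g_l_s * self.e_l + self.g_c * vd
               + ge_syn_sum + i_inj)
        G_d = g_can_d + g_cal_d + g_kca_d + self.g_l_d + self.g_c
        A_d = (g_can_d * k["eca"] + g_cal_d * k["eca"] + g_kca_d * k["ek"]
               + self.g_l_d * self.e_l + self.g_c * vs)
        return G_s, A_s, G_d, A_d, g_na

    #: cells whose soma is above this voltage (spiking) are advanced with
    #: subdivided steps, concentrating accuracy where the dynamics are stiff;
    #: cells in a batch are mutually independent, so the split is exact
    SUBSTEP_THRESHOLD = -50.0
    SUBSTEPS = 10

    _PARAM_ARRAYS = ("area_s", "area_d", "range_frac", "c_s", "c_d", "g_na",
                     "g_kdr", "g_can_s", "g_kca_s", "g_can_d", "g_cal_d",
                     "g_kca_d", "g_l_s", "g_l_d", "e_l", "g_c", "refractory",
                     "ca_f", "ca_alpha", "ca_kca", "ca_kd", "h_half",
                     "h_slope")
    _STATE_ARRAYS = ("v_s", "v_d", "h", "nK", "mn_s", "hn_s", "mn_d", "hn_d",
                     "ml", "ca_s", "ca_d", "last_spike", "_prev_vs")

    def _subview(self, idx: np.ndarray) -> "MotoneuronBatch":
        view = object.__new__(MotoneuronBatch)
        view.n = int(idx.size)
        view.k = self.k
        view.i_na_trace = None
        for name in self._PARAM_ARRAYS + self._STATE_ARRAYS:
            setattr(view, name, getattr(self, name)[idx])
        return view

    def _writeback(self, view: "MotoneuronBatch", idx: np.ndarray) -> None:
        for name in self._STATE_ARRAYS:
            getattr(self, name)[idx] = getattr(view, name)

    def step(self, t: float | np.ndarray, dt: float,
             i_inj: np.ndarray | float = 0.0,
             syn: Sequence[tuple[np.ndarray, float]] = (),
             record_i_na: bool = False) -> np.ndarray:
        """Advance one step; returns interpolated spike times (NaN if none).

        ``i_inj`` (nA) and synaptic conductances (μS, with reversal mV) are
        applied to the soma.  ``t`` is the time at the *start* of the step.
        """
        hot = self.v_s > self.SUBSTEP_THRESHOLD
        if self.SUBSTEPS <= 1 or not hot.any():
            return self._step_once(t, dt, i_inj, syn, record_i_na)
        i_inj = np.broadcast_to(np.asarray(i_inj, dtype=float), (self.n,))
        if record_i_na:
            self.i_na_trace = np.zeros(self.n)
        out = np.full(self.n, np.nan)
        for idx, fine in ((np.flatnonzero(~hot), False),
                          (np.flatnonzero(hot), True)):
            if idx.size == 0:
                continue
            view = self._subview(idx)
            syn_sub = [(g[idx], e) for g, e in syn]
            if fine:
                sub_dt = dt / self.SUBSTEPS
                st = np.full(idx.size, np.nan)
                for i in range(self.SUBSTEPS):
                    s = MotoneuronBatch._step_once(
                        view, np.asarray(t) + i * sub_dt, sub_dt, i_inj[idx],
                        syn_sub, record_i_na)
                    st = np.where(np.isnan(st), s, st)
            else:
                st = MotoneuronBatch._step_once(view, t, dt, i_inj[idx],
                                                syn_sub, record_i_na)
            self._writeback(view, idx)
            if record_i_na and view.i_na_trace is not None:
                self.i_na_trace[idx] = view.i_na_trace
            out[idx] = st
        return out

    def _step_once(self, t: float | np.ndarray, dt: float,
                   i_inj: np.ndarray | float = 0.0,
                   syn: Sequence[tuple[np.ndarray, float]] = (),
                   record_i_na: bool = False) -> np.ndarray:
        k = self.k
        vs, vd = self.v_s, self.v_d
        if not np.all(np.isfinite(vs)):
            bad = int(np.flatnonzero(~np.isfinite(vs))[0])
            raise FloatingPointError(
                f"non-finite membrane potential in cell {bad} at t={t} ms")

        i_inj = np.broadcast_to(np.asarray(i_inj, dtype=float), (self.n,))
        g_syn_sum = np.zeros(self.n)
        ge_syn_sum = np.zeros(self.n)
        for g_arr, e_rev in syn:
            g_syn_sum = g_syn_sum + g_arr
            ge_syn_sum = ge_syn_sum + g_arr * e_rev

        gates0 = (self.h, self.nK, self.mn_s, self.hn_s, self.mn_d,
                  self.hn_d, self.ml, self.ca_s, self.ca_d)

        # exponential midpoint (predictor–corrector): advance once with
        # kinetics frozen at V(t), then re-advance from the start using
        # coefficients evaluated at the midpoint voltage — second order in dt
        gates1 = self._advance_gates(gates0, vs, vd, dt)
        G_s, A_s, G_d, A_d, _ = self._membrane_coeffs(
            gates1, vs, vd, g_syn_sum, ge_syn_sum, i_inj)
        vs_hat = self._exp_update(vs, A_s, G_s, self.c_s, dt)
        vd_hat = self._exp_update(vd, A_d, G_d, self.c_d, dt)

        vs_mid = 0.5 * (vs + vs_hat)
        vd_mid = 0.5 * (vd + vd_hat)
        gates_new = self._advance_gates(gates0, vs_mid, vd_mid, dt)
        gates_mid = tuple(0.5 * (a + b) for a, b in zip(gates0, gates_new))
        # re-advance the calcium pools with the *midpoint* Ca-channel gating,
        # so the per-spike Ca influx (which sets the steady firing rate via
        # K(Ca)) is second-order accurate as well
        _, _, mmn_s, mhn_s, mmn_d, mhn_d, mml, _, _ = gates_mid
        ca_s_new, ca_d_new = self._advance_ca(
            gates0[7], gates0[8], mmn_s, mhn_s, mmn_d, mhn_d, mml,
            vs_mid, vd_mid, dt)
        gates_new = gates_new[:7] + (ca_s_new, ca_d_new)
        gates_mid = gates_mid[:7] + (0.5 * (gates0[7] + ca_s_new),
                                     0.5 * (gates0[8] + ca_d_new))
        G_s, A_s, G_d, A_d, g_na_mid = self._membrane_coeffs(
            gates_mid, vs_mid, vd_mid, g_syn_sum, ge_syn_sum, i_inj)
        new_vs = self._exp_update(vs, A_s, G_s, self.c_s, dt)
        new_vd = self._exp_update(vd, A_d, G_d, self.c_d, dt)

        (self.h, self.nK, self.mn_s, self.hn_s, self.mn_d, self.hn_d,
         self.ml, self.ca_s, self.ca_d) = gates_new

        if record_i_na:
            self.i_na_trace = g_na_mid * (vs_mid - k["ena"])  # nA, outward+

        t_arr = np.broadcast_to(np.asarray(t, dtype=float), (self.n,))
        crossed = (vs < SPIKE_THRESHOLD) & (new_vs >= SPIKE_THRESHOLD)
        ready = (t_arr + dt - self.last_spike) > self.refractory
        fired = crossed & ready
        spike_times = np.full(self.n, np.nan)
        if fired.any():
            frac = (SPIKE_THRESHOLD - vs[fired]) / (new_vs[fired] - vs[fired])
            spike_times[fired] = t_arr[fired] + frac * dt
            self.last_spike[fired] = spike_times[fired]

        self._prev_vs = vs
        self.v_s = new_vs
        self.v_d = new_vd
        return spike_times


class IntegrateFireBatch:
    """Leaky integrate-and-fire cells with exact exponential subthreshold
    integration.

    dV/dt = (−(V − V_rest) + R·I) / τ; spike when V ≥ V_thresh, reset to
    V_reset, absolute refractory.  For constant suprathreshold drive the ISI
    is the closed form τ·ln(RI / (RI − (V_thr − V_rest))) plus the
    refractory period.
    """

    model_kind = "integrate_fire"

    def __init__(self, templates: Sequence[CellTemplate] | CellTemplate,
                 n: int | None = None):
        if isinstance(templates, CellTemplate):
            templates = [templates] * (n or 1)
        self.templates = list(templates)
        self.n = len(self.templates)

        def arr(key: str) -> np.ndarray:
            return np.array([t.params[key] for t in self.templates], dtype=float)

        self.tau = arr("tau_m")
        self.r_in = arr("r_in")
        self.v_rest = arr("v_rest")
        self.v_thresh = arr("v_thresh")
        self.v_reset = arr("v_reset")
        self.refractory = arr("refractory")
        self.reset_state()

    def reset_state(self) -> None:
        self.v = self.v_rest.copy()
        self.last_spike = np.full(self.n, -1e9)

    def settle(self, t_ms: float = 0.0, dt: float = 0.05) -> None:
        self.reset_state()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {"v": self.v.copy(), "last_spike": self.last_spike.copy()}

    def set_state(self, state: Mapping[str, np.ndarray]) -> None:
        for name, value in state.items():
            getattr(self, name)[:] = value

    def step(self, t: float, dt: float, i_inj: np.ndarray | float = 0.0,
             syn: Sequence[tuple[np.ndarray, float]] = (),
             record_i_na: bool = False) -> np.ndarray:
        i_inj = np.broadcast_to(np.asarray(i_inj, dtype=float), (self.n,)).copy()
        g_tot = np.zeros(self.n)
        ge_tot = np.zeros(self.n)
        for g_arr, e_rev in syn:
            g_tot = g_tot + g_arr
            ge_tot = ge_tot + g_arr * e_rev
        # C dV/dt = gL(Vrest − V) + Σ gsyn(E − V) + I with gL = 1/R (μS) and
        # C = τ·gL, i.e. dV/dt = (V∞ − V)/τ_eff
        g_l = 1.0 / self.r_in
        g_sum = g_l + g_tot
        v_inf = (g_l * self.v_rest + ge_tot + i_inj) / g_sum
        tau_eff = self.tau * g_l / g_sum
        in_refr = (t + dt - self.last_spike) <= self.refractory
        new_v = v_inf + (self.v - v_inf) * np.exp(-dt / tau_eff)
        new_v[in_refr] = self.v_reset[in_refr]
        fired = (new_v >= self.v_thresh) & ~in_refr
        spike_times = np.full(self.n, np.nan)
        if fired.any():
            denom = new_v[fired] - self.v[fired]
            frac = np.where(np.abs(denom) > 1e-12,
                            (self.v_thresh[fired] - self.v[fired]) / denom, 1.0)
            spike_times[fired] = t + np.clip(frac, 0.0, 1.0) * dt
            self.last_spike[fired] = spike_times[fired]
            new_v[fired] = self.v_reset[fired]
        self.v = new_v
        return spike_times


class SpikeSourceBatch:
    """Cells that emit externally supplied spike trains (afferents, EES drive).

    Event times are set per cell before a run (``set_events``) or pushed
    incrementally during closed-loop simulation (``push_events``).
    """

    model_kind = "spike_source"

    def __init__(self, templates: Sequence[CellTemplate] | CellTemplate,
                 n: int | None = None):
        if isinstance(templates, CellTemplate):
            templates = [templates] * (n or 1)
        self.templates = list(templates)
        self.n = len(self.templates)
        self._events: list[list[float]] = [[] for _ in range(self.n)]
        self._cursor = np.zeros(self.n, dtype=int)

    def reset_state(self) -> None:
        self._cursor[:] = 0

    def settle(self, t_ms: float = 0.0, dt: float = 0.05) -> None:
        pass

    def state_dict(self) -> dict[str, np.ndarray]:
        return {"_cursor": self._cursor.copy()}

    def set_state(self, state: Mapping[str, np.ndarray]) -> None:
        self._cursor[:] = state["_cursor"]

    def set_events(self, events_per_cell: Sequence[Sequence[float]]) -> None:
        if len(events_per_cell) != self.n:
            raise ModelError("one event list per cell required")
        self._events = [sorted(float(t) for t in ev) for ev in events_per_cell]
        self._cursor[:] = 0

    def push_events(self, cell_indices: Iterable[int], time: float) -> None:
        for i in cell_indices:
            self._events[i].append(float(time))

    def add_events(self, cell: int, times: Iterable[float]) -> None:
        """Append future event times for one cell (must be ≥ current time)."""
        self._events[cell].extend(float(t) for t in times)

    def step(self, t: float, dt: float, i_inj=0.0, syn=(),
             record_i_na: bool = False) -> np.ndarray:
        spike_times = np.full(self.n, np.nan)
        t_end = t + dt
        for i in range(self.n):
            ev = self._events[i]
            c = self._cursor[i]
            while c < len(ev) and ev[c] < t_end:
                if ev[c] >= t:
                    spike_times[i] = ev[c]   # one spike per step is enough here
                c += 1
            self._cursor[i] = c
        return spike_times


_BATCH_CLASSES = {
    "hh_motoneuron": MotoneuronBatch,
    "bistable_2c": MotoneuronBatch,
    "integrate_fire": IntegrateFireBatch,
    "spike_source": SpikeSourceBatch,
}


def make_batch(templates: Sequence[CellTemplate] | CellTemplate,
               n: int | None = None):
    tpl = templates if isinstance(templates, CellTemplate) else templates[0]
    return _BATCH_CLASSES[tpl.model_class](templates, n)


def step_cell(template: CellTemplate, state: Mapping[str, np.ndarray] | None,
              input_current: float, dt: float,
              synaptic_conductances: Sequence[tuple[float, float]] = (),
              t: float = 0.0):
    """Single-cell, single-step interface over the batched integrators.

    Returns ``(state', spike_time_or_None)``.  ``state=None`` initializes at
    the class rest state.
    """
    batch = make_batch(template, 1)
    if state is None:
        batch.settle()
    else:
        batch.set_state(state)
    syn = [(np.array([g]), e) for g, e in synaptic_conductances]
    spike = batch.step(t, dt, np.array([input_current]), syn)
    s = batch.state_dict()
    return s, (None if np.isnan(spike[0]) else float(spike[0]))
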