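"""Programmatic fixtures: the L4/L5 ankle circuit, single-cell experiment
suites, and the model-integration demo.

The ankle fixture reproduces the canonical two-segment (L4/L5) spinal
circuit controlling ankle dorsi-/plantar-flexion: gastrocnemius (extensor)
motoneurons in the left crural extensor lamina-9 region of L5, tibialis
anterior (flexor) motoneurons in the crural flexor region of L4, Ia and II
afferents in the dorsal root ganglia, and Ia-inhibitory plus excitatory
interneurons in lamina 6 of both segments.  At full scale each segment
holds 169 alpha motoneurons, 60 Ia and 60 II afferents, and 400
interneurons; a ``scale`` factor shrinks every group proportionally for
desk-scale simulation while keeping the circuit motifs intact.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from neuromotor import circuit_gen
from neuromotor.cell_models import StimulusSpec, builtin_template
from neuromotor.model_def import (
    CuratedModel,
    ModelDefinition,
    ModelError,
    build_model_definition,
)
from neuromotor.simulator import SimulationDefinition

FIXTURES = ("ankle_l4l5", "single_cell_suite", "integration_demo")

#: per-segment cell counts of the full-scale circuit
FULL_COUNTS = {"moto": 169, "ia": 60, "ii": 60, "inter_each": 200}

SEGMENT_LENGTH_UM = 12_000.0


def _scaled(count: int, scale: float) -> int:
    return max(1, int(round(count * scale)))


def ankle_l4l5_tables(scale: float = 1.0) -> dict[str, pd.DataFrame]:
    """The six curated tables of the ankle circuit as DataFrames."""
    if not 0 < scale <= 1:
        raise ModelError("scale must be in (0, 1]")
    n_moto = _scaled(FULL_COUNTS["moto"], scale)
    n_ia = _scaled(FULL_COUNTS["ia"], scale)
    n_ii = _scaled(FULL_COUNTS["ii"], scale)
    n_int = _scaled(FULL_COUNTS["inter_each"], scale)
    conv_aff = min(12, n_ia)
    conv_int = min(10, n_int)

    segments = pd.DataFrame([
        # caudal → rostral order; aligned on the central canal
        {"name": "L5", "length": SEGMENT_LENGTH_UM,
         "central_canal_x": 0.0, "central_canal_y": 0.0,
         "refs": "human lumbar segment geometry"},
        {"name": "L4", "length": SEGMENT_LENGTH_UM,
         "central_canal_x": 0.0, "central_canal_y": 0.0,
         "refs": "human lumbar segment geometry"},
    ])

    def box(name, segment, lamina, side, x0, x1, y0, y1, z0, z1):
        return {"name": name, "segment": segment, "lamina": lamina,
                "side": side, "kind": "box",
                "x_min": x0, "x_max": x1, "y_min": y0, "y_max": y1,
                "z_min": z0, "z_max": z1, "refs": "lamina atlas (box proxy)"}

    l5 = (0.0, SEGMENT_LENGTH_UM)
    l4 = (SEGMENT_LENGTH_UM, 2 * SEGMENT_LENGTH_UM)
    regions = pd.DataFrame([
        box("L5_CEx9_L", "L5", "CEx9", "L", -1500, -300, -1200, 0, *l5),
        box("L4_CFl9_L", "L4", "CFl9", "L", -1500, -300, -1200, 0, *l4),
        box("L5_L6_L", "L5", "L6", "L", -1200, -200, 0, 800, *l5),
        box("L4_L6_L", "L4", "L6", "L", -1200, -200, 0, 800, *l4),
        box("L5_DRG_L", "L5", "DRG", "L", -3500, -2500, -400, 400, *l5),
        box("L4_DRG_L", "L4", "DRG", "L", -3500, -2500, -400, 400, *l4),
    ])

    def ct(segment, lamina, neuron_type, muscle, template, count):
        return {"species": "Human", "segment": segment, "lamina": lamina,
                "side": "L", "neuron_type": neuron_type,
                "target_muscle": muscle, "template": template,
                "count_mean": count, "count_sd": 0,
                "refs": "motor pool localization"}

    cell_types = pd.DataFrame([
        ct("L5", "CEx9", "AlphaMoto", "gastrocnemius", "M_cell_srr", n_moto),
        ct("L4", "CFl9", "AlphaMoto", "tibialis anterior", "M_cell_srr", n_moto),
        ct("L5", "DRG", "IaAfferent", "gastrocnemius", "afferent_source", n_ia),
        ct("L5", "DRG", "IIAfferent", "gastrocnemius", "afferent_source", n_ii),
        ct("L4", "DRG", "IaAfferent", "tibialis anterior", "afferent_source", n_ia),
        ct("L4", "DRG", "IIAfferent", "tibialis anterior", "afferent_source", n_ii),
        ct("L5", "L6", "IaInterneuron", "gastrocnemius", "interneuron_if", n_int),
        ct("L5", "L6", "ExcInterneuron", "gastrocnemius", "interneuron_if", n_int),
        ct("L4", "L6", "IaInterneuron", "tibialis anterior", "interneuron_if", n_int),
        ct("L4", "L6", "ExcInterneuron", "tibialis anterior", "interneuron_if", n_int),
    ])

    def rule(name, src, dst, relation, sign, w, delay, tau, e_rev, conv):
        return {"name": name, "source_type": src, "dest_type": dst,
                "muscle_relation": relation, "laterality": "ipsilateral",
                "sign": sign, "weight_mean": w, "weight_sd": 0,
                "delay": delay, "tau": tau, "e_rev": e_rev,
                "convergence_mean": conv, "convergence_sd": 0,
                "refs": "stereotyped spinal reflex pathways"}

    rules = pd.DataFrame([
        rule("IaExcitation", "IaAfferent", "AlphaMoto", "agonist",
             "excitatory", 0.012, 4.5, 2.0, 0.0, conv_aff),
        rule("IaToIaInterneuron", "IaAfferent", "IaInterneuron", "agonist",
             "excitatory", 0.02, 3.0, 2.0, 0.0, min(6, n_ia)),
        rule("IIToExcInterneuron", "IIAfferent", "ExcInterneuron", "agonist",
             "excitatory", 0.02, 3.0, 2.0, 0.0, min(6, n_ii)),
        rule("ExcInterneuronToMoto", "ExcInterneuron", "AlphaMoto", "agonist",
             "excitatory", 0.006, 3.0, 2.5, 0.0, conv_int),
        rule("IaInhibition", "IaInterneuron", "AlphaMoto", "antagonist",
             "inhibitory", 0.01, 3.0, 3.0, -75.0, conv_int),
    ])

    synergy = pd.DataFrame([
        {"muscle": "gastrocnemius", "movement_type": "plantar-flexion",
         "antagonist_movement_type": "", "refs": "ankle synergy"},
        {"muscle": "tibialis anterior", "movement_type": "dorsi-flexion",
         "antagonist_movement_type": "", "refs": "ankle synergy"},
        {"muscle": "", "movement_type": "plantar-flexion",
         "antagonist_movement_type": "dorsi-flexion", "refs": "ankle synergy"},
    ])

    templates = pd.DataFrame([
        {"template": "M_cell_srr", "parameter": "base",
         "value": "M_cell_srr", "refs": "calibrated S-type reflex motoneuron"},
        {"template": "afferent_source", "parameter": "base",
         "value": "afferent_source", "refs": ""},
        {"template": "interneuron_if", "parameter": "base",
         "value": "interneuron_if", "refs": "integrate-and-fire interneuron"},
    ])

    return {
        "segments": segments,
        "regions": regions,
        "neuronal_cell_types": cell_types,
        "connection_rules": rules,
        "muscle_synergy": synergy,
        "cell_templates": templates,
    }


def write_ankle_l4l5(out_dir: str | Path, scale: float = 1.0) -> Path:
    """Write the ankle circuit's curated CSV tables into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, df in ankle_l4l5_tables(scale).items():
        df.to_csv(out_dir / f"{name}.csv", index=False)
    return out_dir


def ankle_l4l5_curated(scale: float = 1.0) -> CuratedModel:
    tables = {name: df.astype(str) for name, df in ankle_l4l5_tables(scale).items()}
    extra = {}
    from neuromotor.model_def import REQUIRED_TABLES
    for name, df in tables.items():
        extras = [c for c in df.columns if c not in REQUIRED_TABLES[name]]
        if extras:
            extra[name] = extras
    return CuratedModel(tables=tables, extra_columns=extra)


def ankle_l4l5_model(seed: int = 0, scale: float = 1.0) -> ModelDefinition:
    """Build the realized ankle-circuit model definition."""
    curated = ankle_l4l5_curated(scale)
    info = {
        "name": "ankle_l4l5",
        "scale": scale,
        "seed": seed,
        "notes": ("group names follow each group's actual segment; the "
                  "canonical extensor pool sits in L5 although the "
                  "historical example name string uses L4"),
    }
    return build_model_definition(curated, seed=seed, info=info)


# ---------------------------------------------------------------------------
# Simulation definitions
# ---------------------------------------------------------------------------

EXTENSOR_MN = "Human_L5_CEx9_L_AlphaMoto_Gas"
FLEXOR_MN = "Human_L4_CFl9_L_AlphaMoto_Tib"


def reflex_sim_definition(amplitudes: list[float] | None = None,
                          duration: float = 160.0, dt: float = 0.025,
                          ees_rate: float = 8.0, ees_delay: float = 10.0,
                          ) -> SimulationDefinition:
    """EES amplitude sweep on the extensor reflex network.

    One run per amplitude (default: 12 amplitudes from 7 to 29 stimulation
    units in steps of 2); each run lasts 160 ms so exactly one 8 Hz pulse
    (at 135 ms) falls inside it.
    """
    if amplitudes is None:
        amplitudes = [7.0 + 2.0 * k for k in range(12)]
    ees = StimulusSpec.ees(rate=ees_rate, onset_delay=ees_delay, amplitude=1.0)
    return SimulationDefinition(
        inputs=[{
            "stimulus": ees.to_dict(),
            "target": [{"neuron_type": "IaAfferent"},
                       {"neuron_type": "IIAfferent"},
                       {"neuron_type": "AlphaMoto"}],
        }],
        responses=[{"variable": "v", "target": {"neuron_type": "AlphaMoto"}}],
        setup={"ees_recruitment": {}},
        runs=[{"duration": duration, "dt": dt,
               "overrides": {"ees_amplitude": a}} for a in amplitudes],
        plots=[{"kind": "reflex_recruitment_curve", "group": EXTENSOR_MN}],
    )


def fi_sim_definition(template: str = "M_cell_srr") -> SimulationDefinition:
    """Ramp-current FI protocol (0 → 50 nA over 1 s)."""
    ramp = StimulusSpec.iclamp([(0.0, 0.0), (1000.0, 50.0)])
    return SimulationDefinition(
        inputs=[{"stimulus": ramp.to_dict(), "target": {"template": template}}],
        responses=[{"variable": "v", "target": {"template": template}}],
        runs=[{"duration": 1000.0, "dt": 0.025}],
        plots=[{"kind": "fi_curve", "template": template}],
    )


def sra_sim_definition(template: str, amplitude: float) -> SimulationDefinition:
    """Step-current spike-rate adaptation protocol."""
    step = StimulusSpec.iclamp([(0.0, 0.0), (100.0 - 1e-9, 0.0),
                                (100.0, amplitude), (1000.0, amplitude)])
    return SimulationDefinition(
        inputs=[{"stimulus": step.to_dict(), "target": {"template": template}}],
        responses=[{"variable": "v", "target": {"template": template}}],
        runs=[{"duration": 1000.0, "dt": 0.025}],
        plots=[{"kind": "sra_curve", "template": template}],
    )


def write_single_cell_suite(out_dir: str | Path) -> Path:
    """Materialize the calibrated cell templates plus FI / SRA / bistable
    protocol definitions."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name in ("M_cell_srr", "M_cell_Slow", "M_cell_FR", "M_cell_FF",
                 "M_cell_bistable", "interneuron_if"):
        tpl = builtin_template(name)
        (out_dir / f"{name}.json").write_text(
            json.dumps(tpl.to_dict(), indent=2) + "\n")
    fi_sim_definition("M_cell_srr").save(out_dir / "fi_curve_setup.json")
    for name, amp in (("M_cell_Slow", 12.0), ("M_cell_FR", 18.0),
                      ("M_cell_FF", 25.0)):
        sra_sim_definition(name, amp).save(
            out_dir / f"sra_{name.split('_')[-1].lower()}_setup.json")
    ramp = StimulusSpec.iclamp([(0.0, 0.0), (2000.0, 12.0), (4000.0, 0.0)])
    SimulationDefinition(
        inputs=[{"stimulus": ramp.to_dict(),
                 "target": {"template": "M_cell_bistable"}}],
        responses=[{"variable": "v", "target": {"template": "M_cell_bistable"}}],
        runs=[{"duration": 4000.0, "dt": 0.025}],
        plots=[{"kind": "hysteresis", "template": "M_cell_bistable"}],
    ).save(out_dir / "bistable_setup.json")
    return out_dir


def integration_demo_spec() -> dict[str, Any]:
    """Problem spec for the coordinate-ascent integration demo: tune the
    four canonical parameters of the reflex motoneuron so the integrated
    cell also expresses the bistable plateau."""
    return {
        "base_template": "M_cell_srr",
        "parameters": [
            {"path": "mechanisms.soma.KCa.gkcabar", "bounds": [1.0, 25.0],
             "subspace": "kca"},
            {"path": "mechanisms.dendrite.CaN.gcanbar", "bounds": [0.0, 1.0],
             "subspace": "can"},
            {"path": "mechanisms.dendrite.CaL.gcalbar", "bounds": [0.0, 0.6],
             "subspace": "cal"},
            {"path": "params.range", "bounds": [1, 4], "subspace": "range",
             "integer": True},
        ],
        "references": [
            {"experiment": "triangular_ramp_fi", "i_peak": 12.0,
             "t_ramp": 1000.0, "template": "M_cell_bistable",
             "serotonin": True},
            {"experiment": "fi_curve", "i_max": 50.0, "t_ramp": 1000.0,
             "template": "M_cell_srr"},
        ],
    }


def write_integration_demo(out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "integration_problem.json").write_text(
        json.dumps(integration_demo_spec(), indent=2) + "\n")
    return out_dir


def run_reflex_sweep(scale: float = 0.2, seed: int = 1,
                     amplitudes: list[float] | None = None,
                     duration: float = 160.0, dt: float = 0.025):
    """Run the EES amplitude sweep on the extensor network.

    Builds the (scaled) ankle circuit, runs one 160 ms simulation per
    amplitude with a single 8 Hz / 10 ms-delay pulse at 135 ms, and returns
    the extensor group's reflex recruitment curve.
    """
    from neuromotor.cell_models import make_stimulus
    from neuromotor.ephys_analysis import reflex_recruitment_curve
    from neuromotor.simulator import build_network

    model = ankle_l4l5_model(seed=seed, scale=scale)
    sim = reflex_sim_definition(amplitudes, duration=duration, dt=dt)
    stim = StimulusSpec.from_dict(sim.inputs[0]["stimulus"])
    pulses = make_stimulus(stim, duration=duration)
    responses = []
    for spec in sim.runs:
        amp = float(spec["overrides"]["ees_amplitude"])
        net = build_network(model, sim, seed=seed)
        rec = net.run(spec)
        responses.append((amp, rec.time, rec.group_mean(EXTENSOR_MN)))
    return reflex_recruitment_curve(responses, pulses)


def write_fixture(name: str, out_dir: str | Path, scale: float = 1.0) -> Path:
    """Materialize a named fixture; unknown names raise listing the options."""
    if name == "ankle_l4l5":
        return write_ankle_l4l5(out_dir, scale)
    if name == "single_cell_suite":
        return write_single_cell_suite(out_dir)
    if name == "integration_demo":
        return write_integration_demo(out_dir)
    raise ModelError(f"unknown fixture {name!r}; available: {list(FIXTURES)}")
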