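"""Network instantiation, event delivery, determinism, and EES semantics."""

import numpy as np
import pytest

from neuromotor.cell_models import StimulusSpec
from neuromotor.model_def import (
    CellGroup,
    ModelDefinition,
    ModelError,
    NetConnection,
    RandomScalar,
    Region,
    SpinalSegment,
)
from neuromotor.simulator import (
    SimulationDefinition,
    build_network,
    resolve_selector,
)


def tiny_model(n_src=1, n_dst=1, weight=0.05, delay=2.0, convergence=1,
               dst_template="interneuron_if"):
    """Minimal two-group model: spike sources -> integrate-and-fire cells."""
    seg = SpinalSegment(name="S1", length=1000.0, rostro_caudal_offset=0.0)
    region = Region(name="R1", segment="S1", lamina="X", side="L",
                    geometry={"kind": "box", "x": [0, 100], "y": [0, 100],
                              "z": [0, 1000]})
    groups = [
        CellGroup(name="SRC", region="R1", template="afferent_source",
                  count=RandomScalar(n_src), neuron_type="IaAfferent",
                  realized_count=n_src),
        CellGroup(name="DST", region="R1", template=dst_template,
                  count=RandomScalar(n_dst), neuron_type="ExcInterneuron",
                  realized_count=n_dst),
    ]
    conns = [NetConnection(
        source="SRC", dest="DST", sign="excitatory",
        weight=RandomScalar(weight), delay=delay, tau=2.0, e_rev=0.0,
        convergence=RandomScalar(convergence, lower_clip=1.0),
        realized_weight=weight, realized_convergence=convergence)]
    model = ModelDefinition(
        info={"name": "tiny"}, segments=[seg], regions=[region],
        cell_groups=groups, net_connections=conns,
        aux={"positions": {"SRC": [[1, 1, 1]] * n_src,
                           "DST": [[2, 2, 2]] * n_dst}})
    model.validate()
    return model


def sim_recording_v(target="DST"):
    return SimulationDefinition(
        responses=[{"variable": "v", "target": target}])


class TestBuildNetwork:
    def test_cell_totals_match_realized_counts(self, small_model):
        net = build_network(small_model, sim_recording_v(
            {"neuron_type": "AlphaMoto"}), seed=1)
        for g in small_model.cell_groups:
            assert net.batches[g.name].n == g.realized_count

    def test_unit_convergence_gives_one_synapse_per_dest(self):
        model = tiny_model(n_src=5, n_dst=4, convergence=1)
        net = build_network(model, sim_recording_v(), seed=0)
        w = net.wirings[0]
        assert len(w.pairs) == 4
        assert sorted(p[1] for p in w.pairs) == [0, 1, 2, 3]

    def test_same_seed_identical_synapse_lists(self, small_model):
        sim = sim_recording_v({"neuron_type": "AlphaMoto"})
        a = build_network(small_model, sim, seed=3)
        b = build_network(small_model, sim, seed=3)
        for wa, wb in zip(a.wirings, wb_list := b.wirings):
            np.testing.assert_array_equal(wa.pairs, wb.pairs)

    def test_different_seed_resamples_wiring(self, small_model):
        sim = sim_recording_v({"neuron_type": "AlphaMoto"})
        a = build_network(small_model, sim, seed=3)
        b = build_network(small_model, sim, seed=4)
        assert any(not np.array_equal(wa.pairs, wb.pairs)
                   for wa, wb in zip(a.wirings, b.wirings))

    def test_empty_selector_error_lists_groups(self, small_model):
        with pytest.raises(ModelError, match="Human_L5_CEx9_L_AlphaMoto_Gas"):
            resolve_selector(small_model, "NoSuchGroup")


class TestEventDelivery:
    def test_epsp_onset_exactly_at_spike_plus_delay(self):
        delay = 2.0
        model = tiny_model(delay=delay)
        sim = SimulationDefinition(
            inputs=[], responses=[{"variable": "v", "target": "DST"}])
        net = build_network(model, sim, seed=0)
        t_spike = 10.0
        net.batches["SRC"].set_events([[t_spike]])
        dt = 0.025
        rec = net.run({"duration": 30.0, "dt": dt})
        v = rec.traces[("DST", "v")][:, 0]
        rest = v[0]
        moved = np.flatnonzero(np.abs(v - rest) > 1e-9)
        onset_step = moved[0]
        expected_step = int(np.ceil((t_spike + delay) / dt)) + 1
        assert onset_step == expected_step
        # causality: strictly no deflection before spike + delay
        assert np.all(np.abs(v[:expected_step - 1] - rest) < 1e-12)

    def test_suprathreshold_drive_fires_postsynaptic_cell(self):
        model = tiny_model(weight=0.2)
        net = build_network(model, sim_recording_v(), seed=0)
        net.batches["SRC"].set_events([[5.0]])
        rec = net.run({"duration": 30.0, "dt": 0.025})
        assert len(rec.spikes["DST"][0]) >= 1
        assert rec.spikes["DST"][0][0] > 5.0 + 2.0


class TestNetworkVsSingleCell:
    def test_disconnected_network_reproduces_single_cell_run(self, small_model):
        """With all synapses removed, each cell follows its single-cell
        trajectory bit-identically."""
        from neuromotor.ephys_analysis import run_cells
        from neuromotor.cell_models import builtin_template

        model = ModelDefinition.from_json(small_model.to_json())
        model.net_connections = []
        ramp = StimulusSpec.iclamp([(0.0, 0.0), (100.0, 20.0)])
        sim = SimulationDefinition(
            inputs=[{"stimulus": ramp.to_dict(),
                     "target": "Human_L5_CEx9_L_AlphaMoto_Gas"}],
            responses=[{"variable": "v",
                        "target": "Human_L5_CEx9_L_AlphaMoto_Gas"}])
        net = build_network(model, sim, seed=0)
        rec = net.run({"duration": 100.0, "dt": 0.05})
        net_spikes = rec.spikes["Human_L5_CEx9_L_AlphaMoto_Gas"][0]

        tpl = builtin_template("M_cell_srr")
        single = run_cells([tpl], [ramp], 100.0, dt=0.05)[0]
        np.testing.assert_allclose(net_spikes, single, atol=1e-12)

    def test_integrate_fire_network_matches_closed_form_count(self):
        model = tiny_model()
        step = StimulusSpec.iclamp([(0.0, 0.4), (500.0, 0.4)])
        sim = SimulationDefinition(
            inputs=[{"stimulus": step.to_dict(), "target": "DST"}],
            responses=[{"variable": "v", "target": "DST"}])
        net = build_network(model, sim, seed=0)
        rec = net.run({"duration": 500.0, "dt": 0.01})
        import math

        p = net.batches["DST"].templates[0].params
        ri = p["r_in"] * 0.4
        isi = p["refractory"] + p["tau_m"] * math.log(
            ri / (ri - (p["v_thresh"] - p["v_rest"])))
        expected = 500.0 / isi
        assert abs(len(rec.spikes["DST"][0]) - expected) <= 1


class TestEES:
    def test_first_afferent_volley_at_135ms(self, small_model):
        from neuromotor.fixtures import reflex_sim_definition
        sim = reflex_sim_definition([13.0])
        net = build_network(small_model, sim, seed=1)
        rec = net.run(sim.runs[0])
        ia = [g.name for g in small_model.cell_groups
              if g.neuron_type == "IaAfferent"]
        volley = min(min(sp) for name in ia
                     for sp in rec.spikes[name] if sp)
        assert volley == pytest.approx(135.0, abs=0.05)

    def test_subthreshold_amplitude_recruits_nothing(self, small_model):
        from neuromotor.fixtures import reflex_sim_definition
        sim = reflex_sim_definition([7.0])
        net = build_network(small_model, sim, seed=1)
        rec = net.run(sim.runs[0])
        total = sum(len(sp) for name in rec.spikes for sp in rec.spikes[name])
        assert total == 0

    def test_run_requires_positive_duration(self, small_model):
        net = build_network(small_model, sim_recording_v(
            {"neuron_type": "AlphaMoto"}), seed=1)
        with pytest.raises(ModelError):
            net.run({"duration": 0.0})

    def test_simulation_definition_rejects_unknown_sections(self):
        with pytest.raises(ModelError):
            SimulationDefinition.from_dict({"inputs": [], "extra": 1})
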