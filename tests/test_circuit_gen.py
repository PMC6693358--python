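"""Muscle-synergy rule engine and Peters'-rule connection generation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neuromotor import circuit_gen as cg
from neuromotor.model_def import CellGroup, ModelError, RandomScalar


def synergy_from(movements, antagonisms):
    return cg.MuscleSynergyTable(
        movements_by_muscle={m: set(v) for m, v in movements.items()},
        antagonist_movements=set(antagonisms))


class TestMuscleGroups:
    def test_ankle_pair_are_antagonists(self):
        syn = synergy_from(
            {"gastrocnemius": ["plantar-flexion"],
             "tibialis anterior": ["dorsi-flexion"]},
            [("plantar-flexion", "dorsi-flexion")])
        ago, anta = cg.derive_muscle_groups(syn, "gastrocnemius")
        assert ago == {"gastrocnemius"}
        assert anta == {"tibialis anterior"}

    def test_single_muscle_no_antagonists(self):
        syn = synergy_from({"soleus": ["plantar-flexion"]}, [])
        ago, anta = cg.derive_muscle_groups(syn, "soleus")
        assert ago == {"soleus"} and anta == set()

    def test_unknown_muscle_raises(self):
        syn = synergy_from({"soleus": ["plantar-flexion"]}, [])
        with pytest.raises(ModelError):
            cg.derive_muscle_groups(syn, "biceps")

    def test_antagonism_symmetric_closure(self):
        syn = synergy_from(
            {"a": ["m1"], "b": ["m2"]}, [("m1", "m2")])
        assert cg.derive_muscle_groups(syn, "b")[1] == {"a"}

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_matches_exhaustive_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        muscles = [f"m{i}" for i in range(5)]
        movements = [f"mv{i}" for i in range(4)]
        table = {m: set(rng.choice(movements,
                                   size=rng.integers(1, 3), replace=False))
                 for m in muscles}
        antagonism = {(movements[0], movements[1])}
        syn = synergy_from(table, antagonism)
        anti_closed = antagonism | {(b, a) for a, b in antagonism}
        for muscle in muscles:
            ago, anta = cg.derive_muscle_groups(syn, muscle)
            # brute force from definitions
            expect_ago = {o for o in muscles if table[o] & table[muscle]}
            anti_movs = {b for a, b in anti_closed if a in table[muscle]}
            expect_anta = {o for o in muscles if table[o] & anti_movs}
            assert ago == expect_ago
            assert anta == expect_anta


def row(segment="L4", lamina="CEx9", side="L", neuron_type="AlphaMoto",
        muscle="gastrocnemius", count=10):
    return {"species": "Human", "segment": segment, "lamina": lamina,
            "side": side, "neuron_type": neuron_type, "target_muscle": muscle,
            "template": "M_cell_srr", "count_mean": count, "count_sd": 0}


class TestCellGroupGeneration:
    def test_printed_group_name(self):
        groups = cg.generate_cell_groups(pd.DataFrame([row()]))
        assert groups[0].name == "Human_L4_CEx9_L_AlphaMoto_Gas"

    def test_empty_table_empty_list(self):
        table = pd.DataFrame(columns=list(row().keys()))
        assert cg.generate_cell_groups(table) == []

    def test_sides_generate_distinct_groups(self):
        groups = cg.generate_cell_groups(
            pd.DataFrame([row(side="L"), row(side="R")]))
        assert len({g.name for g in groups}) == 2

    def test_duplicate_combination_rejected(self):
        with pytest.raises(ModelError, match="rows"):
            cg.generate_cell_groups(pd.DataFrame([row(), row(count=99)]))


def make_group(name, neuron_type, muscle, side="L"):
    return CellGroup(name=name, region="r", template="t",
                     count=RandomScalar(1), neuron_type=neuron_type,
                     target_muscle=muscle)


ANKLE_SYNERGY = synergy_from(
    {"gastrocnemius": ["plantar-flexion"], "tibialis anterior": ["dorsi-flexion"]},
    [("plantar-flexion", "dorsi-flexion")])


def ankle_groups():
    return [
        make_group("Human_L5_CEx9_L_AlphaMoto_Gas", "AlphaMoto", "gastrocnemius"),
        make_group("Human_L4_CFl9_L_AlphaMoto_Tib", "AlphaMoto", "tibialis anterior"),
        make_group("Human_L5_DRG_L_IaAfferent_Gas", "IaAfferent", "gastrocnemius"),
        make_group("Human_L4_DRG_L_IaAfferent_Tib", "IaAfferent", "tibialis anterior"),
        make_group("Human_L5_L6_L_IaInterneuron_Gas", "IaInterneuron", "gastrocnemius"),
        make_group("Human_L4_L6_L_IaInterneuron_Tib", "IaInterneuron", "tibialis anterior"),
        make_group("Human_L5_L6_L_ExcInterneuron_Gas", "ExcInterneuron", "gastrocnemius"),
        make_group("Human_L4_L6_L_ExcInterneuron_Tib", "ExcInterneuron", "tibialis anterior"),
    ]


RULES = [
    cg.ConnectionRule(name="IaExcitation", source_type="IaAfferent",
                      dest_type="AlphaMoto", muscle_relation="agonist"),
    cg.ConnectionRule(name="IaInhibition", source_type="IaInterneuron",
                      dest_type="AlphaMoto", muscle_relation="antagonist",
                      sign="inhibitory", e_rev=-75.0),
    cg.ConnectionRule(name="ExcToMoto", source_type="ExcInterneuron",
                      dest_type="AlphaMoto", muscle_relation="agonist"),
]


class TestNetConnectionGeneration:
    def test_ia_monosynapse_onto_homonymous_motoneurons(self):
        conns = cg.generate_net_connections(RULES, ankle_groups(), ANKLE_SYNERGY)
        assert any(c.source == "Human_L5_DRG_L_IaAfferent_Gas"
                   and c.dest == "Human_L5_CEx9_L_AlphaMoto_Gas"
                   and c.sign == "excitatory" for c in conns)

    def test_ia_interneuron_inhibits_antagonist_motoneurons(self):
        conns = cg.generate_net_connections(RULES, ankle_groups(), ANKLE_SYNERGY)
        inhib = [c for c in conns if c.rule == "IaInhibition"]
        assert {(c.source, c.dest) for c in inhib} == {
            ("Human_L5_L6_L_IaInterneuron_Gas", "Human_L4_CFl9_L_AlphaMoto_Tib"),
            ("Human_L4_L6_L_IaInterneuron_Tib", "Human_L5_CEx9_L_AlphaMoto_Gas"),
        }

    def test_no_afferent_to_antagonist_monosynapse(self):
        conns = cg.generate_net_connections(RULES, ankle_groups(), ANKLE_SYNERGY)
        for c in conns:
            if "IaAfferent" in c.source and "AlphaMoto" in c.dest:
                src_muscle = "Gas" if c.source.endswith("Gas") else "Tib"
                assert c.dest.endswith(src_muscle)

    def test_zero_rules_zero_connections(self):
        assert cg.generate_net_connections([], ankle_groups(), ANKLE_SYNERGY) == []

    def test_every_connection_has_rule_provenance(self):
        conns = cg.generate_net_connections(RULES, ankle_groups(), ANKLE_SYNERGY)
        names = {r.name for r in RULES}
        assert conns and all(c.rule in names for c in conns)

    def test_antagonist_symmetry_of_connection_graph(self):
        """Swapping flexor/extensor muscle labels yields an isomorphic graph."""
        conns = cg.generate_net_connections(RULES, ankle_groups(), ANKLE_SYNERGY)
        swap = {"Gas": "Tib", "Tib": "Gas", "L4": "L5", "L5": "L4",
                "CEx9": "CFl9", "CFl9": "CEx9"}

        def rename(name):
            parts = name.split("_")
            return "_".join(swap.get(p, p) for p in parts)

        edges = {(c.source, c.dest, c.rule) for c in conns}
        swapped = {(rename(s), rename(d), r) for s, d, r in edges}
        assert swapped == edges

    def test_rule_for_absent_type_skipped_with_warning(self, caplog):
        rules = [cg.ConnectionRule(name="ghost", source_type="IIAfferent",
                                   dest_type="AlphaMoto",
                                   muscle_relation="agonist")]
        with caplog.at_level("WARNING"):
            conns = cg.generate_net_connections(rules, ankle_groups(),
                                                ANKLE_SYNERGY)
        assert conns == [] and "ghost" in caplog.text


def box(x0, x1, y0, y1, z0, z1):
    return {"x": [x0, x1], "y": [y0, y1], "z": [z0, z1]}


class TestPetersRule:
    def test_disjoint_fields_no_candidates(self):
        a = (make_group("A", "AlphaMoto", "m"), box(0, 1, 0, 1, 0, 1),
             box(0, 1, 0, 1, 0, 1))
        b = (make_group("B", "AlphaMoto", "m"), box(5, 6, 0, 1, 0, 1),
             box(5, 6, 0, 1, 0, 1))
        assert cg.peters_rule_connections([a, b]) == []

    def test_containment_is_directed(self):
        a = (make_group("A", "AlphaMoto", "m"), box(0, 10, 0, 10, 0, 10),
             box(100, 101, 0, 1, 0, 1))
        b = (make_group("B", "AlphaMoto", "m"), box(50, 51, 0, 1, 0, 1),
             box(2, 3, 2, 3, 2, 3))
        assert cg.peters_rule_connections([a, b]) == [("A", "B")]

    def test_missing_field_skipped_with_warning(self, caplog):
        a = (make_group("A", "AlphaMoto", "m"), None, box(0, 1, 0, 1, 0, 1))
        with caplog.at_level("WARNING"):
            assert cg.peters_rule_connections([a]) == []
        assert "A" in caplog.text

    def test_random_boxes_match_brute_force_oracle(self, rng):
        groups = []
        for i in range(6):
            lo = rng.uniform(0, 10, 6)
            axon = box(lo[0], lo[0] + rng.uniform(1, 5), lo[1],
                       lo[1] + rng.uniform(1, 5), lo[2], lo[2] + rng.uniform(1, 5))
            dend = box(lo[3], lo[3] + rng.uniform(1, 5), lo[4],
                       lo[4] + rng.uniform(1, 5), lo[5], lo[5] + rng.uniform(1, 5))
            groups.append((make_group(f"G{i}", "AlphaMoto", "m"), axon, dend))
        got = set(cg.peters_rule_connections(groups))

        def overlap(b1, b2):
            vol = 1.0
            for ax in ("x", "y", "z"):
                lo = max(b1[ax][0], b2[ax][0])
                hi = min(b1[ax][1], b2[ax][1])
                if hi <= lo:
                    return 0.0
                vol *= hi - lo
            return vol

        expect = {(ga.name, gb.name)
                  for (ga, axon, _), (gb, _, dend)
                  in itertools.product(groups, groups)
                  if ga.name != gb.name and overlap(axon, dend) > 0}
        assert got == expect


class TestMergePolicy:
    def test_rule_generated_synapse_wins_over_peters_duplicate(self):
        conns = cg.generate_net_connections(RULES, ankle_groups(), ANKLE_SYNERGY)
        n_before = len(conns)
        merged = cg.merge_connections(
            conns, [(conns[0].source, conns[0].dest), ("X", "Y")])
        assert len(merged) == n_before + 1
        kept = [c for c in merged if (c.source, c.dest)
                == (conns[0].source, conns[0].dest)]
        assert len(kept) == 1 and kept[0].rule != "peters_rule"

    def test_graph_export_has_all_nodes_and_edges(self):
        groups = ankle_groups()
        conns = cg.generate_net_connections(RULES, groups, ANKLE_SYNERGY)
        g = cg.connection_graph(groups, conns)
        assert g.number_of_nodes() == len(groups)
        assert g.number_of_edges() == len(conns)
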