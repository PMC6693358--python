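"""Muscle-synergy rule engine and co-location circuit generation.

Spinal sensorimotor circuits repeat stereotyped motifs per muscle: Ia
afferents monosynaptically excite motoneurons of the same (homonymous) and
agonist muscles; Ia inhibitory interneurons project to antagonist
motoneurons; excitatory interneurons relay group-II input back to agonist
motoneurons.  Rather than enumerating every connection by hand, the circuit
is generated from three curated tables:

* **neuronal cell types** — which neuron types sit where (segment, lamina,
  side) for which target muscle, yielding one cell group per unique
  combination;
* **muscle synergy** — muscle → movement-type rows plus movement-type
  antagonism rows, from which agonist/antagonist muscle sets are derived;
* **connection rules** — (source type, destination type, muscle relation,
  laterality, synaptic properties) templates expanded against the cell
  groups.

A second, anatomical generation method (Peters' rule) proposes candidate
connections wherever a source group's axonal field overlaps a destination
group's dendritic/somatic field.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from neuromotor.model_def import (
    NEURON_TYPES,
    CellGroup,
    ModelError,
    NetConnection,
    RandomScalar,
    Region,
)

logger = logging.getLogger(__name__)

#: Default muscle-name abbreviations for group naming; first-three-letters
#: title-case unless overridden here or by an ``abbrev`` table column.
_ABBREV_OVERRIDES: dict[str, str] = {}


def muscle_abbrev(muscle: str, override: str | None = None) -> str:
    if override:
        return override
    if muscle in _ABBREV_OVERRIDES:
        return _ABBREV_OVERRIDES[muscle]
    word = muscle.split()[0]
    return word[:3].title()


class SynergyError(ModelError):
    pass


@dataclass
class MuscleSynergyTable:
    """Muscle → movement types, and movement-type antagonist pairs.

    Antagonism is closed under symmetry: declaring plantar-flexion antagonist
    to dorsi-flexion implies the reverse.
    """

    movements_by_muscle: dict[str, set[str]] = field(default_factory=dict)
    antagonist_movements: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        closure = set(self.antagonist_movements)
        closure |= {(b, a) for a, b in self.antagonist_movements}
        self.antagonist_movements = closure

    @classmethod
    def from_table(cls, df: pd.DataFrame) -> "MuscleSynergyTable":
        """Parse the long-format curated table.

        Rows with a non-empty ``muscle`` map that muscle to ``movement_type``;
        rows with an empty ``muscle`` declare ``movement_type`` and
        ``antagonist_movement_type`` as an antagonist pair.
        """
        movements: dict[str, set[str]] = {}
        antagonism: set[tuple[str, str]] = set()
        for _, row in df.iterrows():
            muscle = str(row.get("muscle", "") or "")
            movement = str(row.get("movement_type", "") or "")
            anti = str(row.get("antagonist_movement_type", "") or "")
            if muscle:
                if not movement:
                    raise SynergyError(f"muscle {muscle!r} row lacks a movement_type")
                movements.setdefault(muscle, set()).add(movement)
                if anti:
                    antagonism.add((movement, anti))
            elif movement and anti:
                antagonism.add((movement, anti))
        return cls(movements_by_muscle=movements, antagonist_movements=antagonism)

    @property
    def muscles(self) -> list[str]:
        return sorted(self.movements_by_muscle)


def derive_muscle_groups(
    synergy: MuscleSynergyTable, muscle: str
) -> tuple[set[str], set[str]]:
    """Agonist and antagonist muscle sets for ``muscle``.

    Agonists share at least one movement type with ``muscle`` (a muscle is
    its own agonist); antagonists drive a movement type antagonistic to one
    of ``muscle``'s movement types.  A muscle appearing in both sets (it
    drives both movements) is logged and kept in both.
    """
    if muscle not in synergy.movements_by_muscle:
        raise SynergyError(f"unknown muscle {muscle!r}")
    own = synergy.movements_by_muscle[muscle]
    anti_movements = {
        b for (a, b) in synergy.antagonist_movements if a in own
    }
    agonists: set[str] = set()
    antagonists: set[str] = set()
    for other, movements in synergy.movements_by_muscle.items():
        if movements & own:
            agonists.add(other)
        if movements & anti_movements:
            antagonists.add(other)
    both = agonists & antagonists
    if both:
        logger.warning(
            "muscles %s drive both %s and an antagonistic movement; flagged as "
            "agonist and antagonist of %s",
            sorted(both),
            sorted(own),
            muscle,
        )
    return agonists, antagonists


# ---------------------------------------------------------------------------
# Cell group generation
# ---------------------------------------------------------------------------


def group_name(
    species: str,
    segment: str,
    lamina: str,
    side: str,
    neuron_type: str,
    target_muscle: str | None,
    abbrev: str | None = None,
) -> str:
    """Render the canonical group name, e.g. ``Human_L5_CEx9_L_AlphaMoto_Gas``."""
    parts = [species, segment, lamina, side, neuron_type]
    if target_muscle:
        parts.append(muscle_abbrev(target_muscle, abbrev))
    return "_".join(parts)


def generate_cell_groups(
    cell_type_table: pd.DataFrame, regions: Sequence[Region] | None = None
) -> list[CellGroup]:
    """One cell group per unique (segment, side, lamina, neuron type, muscle).

    The owning region is resolved by matching (segment, lamina, side) against
    ``regions`` when given; otherwise the region name is rendered as
    ``{segment}_{lamina}_{side}``.  Duplicate combinations are an error.
    """
    region_lookup: dict[tuple[str, str, str], str] = {}
    if regions is not None:
        for r in regions:
            region_lookup[(r.segment, r.lamina, r.side)] = r.name

    seen: dict[tuple, int] = {}
    out: list[CellGroup] = []
    for idx, row in cell_type_table.iterrows():
        key = (
            row["segment"],
            row["side"],
            row["lamina"],
            row["neuron_type"],
            row.get("target_muscle", "") or "",
        )
        if key in seen:
            raise ModelError(
                f"neuronal_cell_types rows {seen[key] + 2} and {idx + 2} define "
                f"the same cell group {key}"
            )
        seen[key] = idx
        muscle = row.get("target_muscle", "") or None
        name = group_name(
            row["species"],
            row["segment"],
            row["lamina"],
            row["side"],
            row["neuron_type"],
            muscle,
            abbrev=row.get("abbrev") or None,
        )
        region = region_lookup.get(
            (row["segment"], row["lamina"], row["side"]),
            f"{row['segment']}_{row['lamina']}_{row['side']}",
        )
        sd = float(row.get("count_sd", 0) or 0)
        out.append(
            CellGroup(
                name=name,
                region=region,
                template=row["template"],
                count=RandomScalar(float(row["count_mean"]), sd, lower_clip=0.0),
                neuron_type=row["neuron_type"],
                target_muscle=muscle,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Rule-based net connection generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConnectionRule:
    """A stereotyped connection motif between neuron types.

    ``muscle_relation`` selects destination groups by their target muscle
    relative to the source group's: ``homonymous`` (same muscle), ``agonist``
    (shares a movement type — includes homonymous, since a muscle is its own
    agonist) or ``antagonist``.
    """

    name: str
    source_type: str
    dest_type: str
    muscle_relation: str
    laterality: str = "ipsilateral"
    sign: str = "excitatory"
    weight: RandomScalar = RandomScalar(0.01, 0.0, lower_clip=0.0)
    delay: float = 1.0
    tau: float = 2.0
    e_rev: float = 0.0
    convergence: RandomScalar = RandomScalar(1, 0.0, lower_clip=1.0)

    def __post_init__(self) -> None:
        for t in (self.source_type, self.dest_type):
            if t not in NEURON_TYPES:
                raise ModelError(f"rule {self.name}: unknown neuron type {t!r}")
        if self.muscle_relation not in ("homonymous", "agonist", "antagonist"):
            raise ModelError(
                f"rule {self.name}: bad muscle_relation {self.muscle_relation!r}"
            )
        if self.laterality not in ("ipsilateral", "contralateral"):
            raise ModelError(f"rule {self.name}: bad laterality {self.laterality!r}")


def parse_connection_rules(df: pd.DataFrame) -> list[ConnectionRule]:
    out = []
    for _, row in df.iterrows():
        out.append(
            ConnectionRule(
                name=row["name"],
                source_type=row["source_type"],
                dest_type=row["dest_type"],
                muscle_relation=row["muscle_relation"],
                laterality=row.get("laterality", "") or "ipsilateral",
                sign=row["sign"],
                weight=RandomScalar(
                    float(row["weight_mean"]),
                    float(row.get("weight_sd", 0) or 0),
                    lower_clip=0.0,
                ),
                delay=float(row["delay"]),
                tau=float(row["tau"]),
                e_rev=float(row["e_rev"]),
                convergence=RandomScalar(
                    float(row["convergence_mean"]),
                    float(row.get("convergence_sd", 0) or 0),
                    lower_clip=1.0,
                ),
            )
        )
    return out


def _side_of(group: CellGroup) -> str:
    # group names render side as a single-letter token (L/R)
    for token in group.name.split("_"):
        if token in ("L", "R"):
            return token
    return ""


def _muscle_matches(
    relation: str, src_muscle: str | None, dest_muscle: str | None,
    synergy: MuscleSynergyTable,
) -> bool:
    if src_muscle is None or dest_muscle is None:
        return relation != "antagonist"  # untyped groups only join non-antagonist motifs
    agonists, antagonists = derive_muscle_groups(synergy, src_muscle)
    if relation == "homonymous":
        return dest_muscle == src_muscle
    if relation == "agonist":
        return dest_muscle in agonists
    return dest_muscle in antagonists


def generate_net_connections(
    rules: Sequence[ConnectionRule],
    groups: Sequence[CellGroup],
    synergy: MuscleSynergyTable,
) -> list[NetConnection]:
    """Expand connection rules against the cell groups.

    For each rule and each source group of the rule's source type, a
    connection is emitted to every destination group of the destination type
    whose target muscle satisfies the rule's muscle relation and whose side
    satisfies its laterality.  Output is sorted by (rule, source, dest) so
    generation is deterministic.  Rules whose neuron types are absent from
    the groups are skipped with a warning.
    """
    by_type: dict[str, list[CellGroup]] = {}
    for g in groups:
        by_type.setdefault(g.neuron_type, []).append(g)

    out: list[NetConnection] = []
    for rule in sorted(rules, key=lambda r: r.name):
        sources = by_type.get(rule.source_type, [])
        dests = by_type.get(rule.dest_type, [])
        if not sources or not dests:
            logger.warning(
                "rule %s: no groups of type %s; skipped",
                rule.name,
                rule.source_type if not sources else rule.dest_type,
            )
            continue
        for src in sorted(sources, key=lambda g: g.name):
            for dst in sorted(dests, key=lambda g: g.name):
                if src.name == dst.name:
                    continue
                same_side = _side_of(src) == _side_of(dst)
                if rule.laterality == "ipsilateral" and not same_side:
                    continue
                if rule.laterality == "contralateral" and same_side:
                    continue
                if not _muscle_matches(
                    rule.muscle_relation, src.target_muscle, dst.target_muscle, synergy
                ):
                    continue
                out.append(
                    NetConnection(
                        source=src.name,
                        dest=dst.name,
                        sign=rule.sign,
                        weight=rule.weight,
                        delay=rule.delay,
                        tau=rule.tau,
                        e_rev=rule.e_rev,
                        convergence=rule.convergence,
                        rule=rule.name,
                    )
                )
    return out


# ---------------------------------------------------------------------------
# Peters' rule (axon/dendrite co-location)
# ---------------------------------------------------------------------------


def _box_overlap(a: Mapping[str, Any], b: Mapping[str, Any]) -> float:
    """Overlap volume of two axis-aligned boxes {x:[x0,x1], y:..., z:...}."""
    vol = 1.0
    for axis in ("x", "y", "z"):
        lo = max(a[axis][0], b[axis][0])
        hi = min(a[axis][1], b[axis][1])
        if hi <= lo:
            return 0.0
        vol *= hi - lo
    return vol


def peters_rule_connections(
    groups_with_fields: Iterable[tuple[CellGroup, Mapping | None, Mapping | None]],
    threshold: float = 0.0,
) -> list[tuple[str, str]]:
    """Candidate (source, dest) pairs by axon–dendrite field overlap.

    Each entry is ``(group, axon_field, dendrite_field)`` with fields as
    axis-aligned boxes (μm).  A directed candidate (A, B) is proposed when
    A's axonal field overlaps B's dendritic/somatic field by more than
    ``threshold`` μm³.  Groups missing either field annotation are skipped
    with a warning.  Self-pairs are excluded.
    """
    annotated = []
    for g, axon, dend in groups_with_fields:
        if axon is None or dend is None:
            logger.warning("group %s: missing axon/dendrite field; skipped", g.name)
            continue
        annotated.append((g, axon, dend))
    out: list[tuple[str, str]] = []
    for ga, axon, _ in annotated:
        for gb, _, dend in annotated:
            if ga.name == gb.name:
                continue
            if _box_overlap(axon, dend) > threshold:
                out.append((ga.name, gb.name))
    return out


def merge_connections(
    rule_based: Sequence[NetConnection],
    peters_candidates: Sequence[tuple[str, str]],
    default_synapse: NetConnection | None = None,
) -> list[NetConnection]:
    """Merge the two generation methods; rule-based synaptic properties win
    for duplicated (source, dest) pairs."""
    out = list(rule_based)
    have = {(c.source, c.dest) for c in rule_based}
    for src, dst in peters_candidates:
        if (src, dst) in have:
            continue
        base = default_synapse or NetConnection(
            source=src,
            dest=dst,
            sign="excitatory",
            weight=RandomScalar(0.001, 0.0, lower_clip=0.0),
            delay=1.0,
            tau=2.0,
            e_rev=0.0,
            convergence=RandomScalar(1, 0.0, lower_clip=1.0),
            rule="peters_rule",
        )
        out.append(
            NetConnection(
                source=src,
                dest=dst,
                sign=base.sign,
                weight=base.weight,
                delay=base.delay,
                tau=base.tau,
                e_rev=base.e_rev,
                convergence=base.convergence,
                rule="peters_rule",
            )
        )
        have.add((src, dst))
    return out


def connection_graph(
    groups: Sequence[CellGroup], connections: Sequence[NetConnection]
) -> nx.MultiDiGraph:
    """Directed multigraph of the generated circuit, exportable to GraphML."""
    g = nx.MultiDiGraph()
    for grp in groups:
        g.add_node(
            grp.name,
            neuron_type=grp.neuron_type,
            target_muscle=grp.target_muscle or "",
            region=grp.region,
        )
    for c in connections:
        g.add_edge(
            c.source,
            c.dest,
            sign=c.sign,
            rule=c.rule,
            weight_mean=c.weight.mean,
            delay=c.delay,
        )
    return g


def export_edge_list(connections: Sequence[NetConnection]) -> list[dict[str, Any]]:
    return [c.to_dict() for c in connections]
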