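"""Structured model definition for spinal sensorimotor circuits.

A model is described at three levels:

1. **Curated tables** — CSV tables (segments, regions, neuronal cell types,
   connection rules, muscle synergy, cell templates) holding the anatomy and
   physiology a modeler collects from the literature, with citation strings.
2. **Curated model** — the validated in-memory form of those tables
   (:class:`CuratedModel`).
3. **Model definition** — the fully enumerated, simulator-agnostic structure
   (:class:`ModelDefinition`) with five core sections (``info``, ``regions``,
   ``segments``, ``cell_groups``, ``net_connections``) plus auxiliary data
   (random cell positions, instantiated cell templates, references).

Cell counts, synaptic weights and convergence ratios are normal random
variables (:class:`RandomScalar`); :func:`build_model_definition` realizes
them with a single seeded generator so a fixed seed reproduces the model
byte-for-byte, while different seeds support Monte-Carlo re-instantiation.

Coordinates are right-handed in micrometres with *z* along the neuraxis
increasing rostrally; a segment occupies ``[offset, offset + length)`` in *z*
and segments tile the neuraxis without overlap, aligned on the central canal.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely import contains_xy
from shapely.geometry import Polygon

logger = logging.getLogger(__name__)

NEURON_TYPES = (
    "AlphaMoto",
    "IaAfferent",
    "IIAfferent",
    "IaInterneuron",
    "ExcInterneuron",
)

#: Required curated tables (file stem -> required columns).
REQUIRED_TABLES: dict[str, tuple[str, ...]] = {
    "segments": ("name", "length"),
    "regions": ("name", "segment", "lamina", "side", "kind"),
    "neuronal_cell_types": (
        "species",
        "segment",
        "lamina",
        "side",
        "neuron_type",
        "target_muscle",
        "template",
        "count_mean",
    ),
    "connection_rules": (
        "name",
        "source_type",
        "dest_type",
        "muscle_relation",
        "laterality",
        "sign",
        "weight_mean",
        "delay",
        "tau",
        "e_rev",
        "convergence_mean",
    ),
    "muscle_synergy": ("muscle", "movement_type", "antagonist_movement_type"),
    "cell_templates": ("template", "parameter", "value"),
}


class ModelError(ValueError):
    """Raised for invalid curated tables or model definitions."""


class TableLoadError(ModelError):
    """Raised when curated tables are missing or malformed."""


# ---------------------------------------------------------------------------
# Random scalars
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RandomScalar:
    """Normal random variable with optional lower truncation.

    Truncation is applied by resampling (rejection), which preserves the
    distribution's shape near the mean.  ``sd=0`` makes the value
    deterministic (clipped to ``lower_clip`` if necessary).
    """

    mean: float
    sd: float = 0.0
    lower_clip: float | None = None

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ModelError(f"RandomScalar sd must be >= 0, got {self.sd}")

    def sample(self, rng: np.random.Generator) -> float:
        if self.sd == 0.0:
            value = float(self.mean)
            if self.lower_clip is not None:
                value = max(value, self.lower_clip)
            return value
        for _ in range(10_000):
            value = float(rng.normal(self.mean, self.sd))
            if self.lower_clip is None or value >= self.lower_clip:
                return value
        # Pathological (mean far below clip): fall back to the clip itself.
        logger.warning(
            "RandomScalar(mean=%s, sd=%s) rejection sampling exhausted; "
            "returning lower_clip=%s",
            self.mean,
            self.sd,
            self.lower_clip,
        )
        return float(self.lower_clip)  # type: ignore[arg-type]

    def sample_int(self, rng: np.random.Generator) -> int:
        """Realize as an integer: round, then clip."""
        value = int(round(self.sample(rng)))
        if self.lower_clip is not None:
            value = max(value, int(math.ceil(self.lower_clip)))
        return value

    def to_dict(self) -> dict[str, float]:
        d: dict[str, Any] = {"mean": self.mean, "sd": self.sd}
        if self.lower_clip is not None:
            d["lower_clip"] = self.lower_clip
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RandomScalar":
        return cls(
            mean=float(d["mean"]),
            sd=float(d.get("sd", 0.0)),
            lower_clip=d.get("lower_clip"),
        )


# ---------------------------------------------------------------------------
# Anatomy
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpinalSegment:
    """A spinal cord segment spanning ``[offset, offset + length)`` along z (μm)."""

    name: str
    length: float
    rostro_caudal_offset: float
    central_canal_xy: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ModelError(f"segment {self.name}: length must be > 0")

    @property
    def z_span(self) -> tuple[float, float]:
        return (self.rostro_caudal_offset, self.rostro_caudal_offset + self.length)

    def to_dict(self) -> dict[str, Any]:
        return {
            "name": self.name,
            "length": self.length,
            "rostro_caudal_offset": self.rostro_caudal_offset,
            "central_canal_xy": list(self.central_canal_xy),
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "SpinalSegment":
        return cls(
            name=d["name"],
            length=float(d["length"]),
            rostro_caudal_offset=float(d["rostro_caudal_offset"]),
            central_canal_xy=tuple(d.get("central_canal_xy", (0.0, 0.0))),
        )


@dataclass(frozen=True)
class Region:
    """A 3D region (lamina volume): axis-aligned box or extruded 2D polygon.

    ``geometry`` is either::

        {"kind": "box", "x": [x0, x1], "y": [y0, y1], "z": [z0, z1]}
        {"kind": "extruded_polygon", "vertices": [[x, y], ...], "z": [z0, z1]}

    All coordinates in μm.  The z-extent must lie within the owning segment's
    rostro-caudal span.
    """

    name: str
    segment: str
    lamina: str
    side: str
    geometry: Mapping[str, Any]

    def __post_init__(self) -> None:
        kind = self.geometry.get("kind")
        if kind not in ("box", "extruded_polygon"):
            raise ModelError(f"region {self.name}: unknown geometry kind {kind!r}")
        z0, z1 = self.geometry["z"]
        if not z1 > z0:
            raise ModelError(f"region {self.name}: degenerate z extent")
        if kind == "box":
            (x0, x1), (y0, y1) = self.geometry["x"], self.geometry["y"]
            if not (x1 > x0 and y1 > y0):
                raise ModelError(f"region {self.name}: degenerate box")
        else:
            poly = Polygon(self.geometry["vertices"])
            if not poly.is_valid or poly.area <= 0:
                raise ModelError(f"region {self.name}: degenerate polygon")
        if self.side not in ("L", "R", ""):
            raise ModelError(f"region {self.name}: side must be L or R")

    @property
    def z_span(self) -> tuple[float, float]:
        z0, z1 = self.geometry["z"]
        return float(z0), float(z1)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Vectorized containment test for an (n, 3) array of points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        z0, z1 = self.z_span
        inside = (pts[:, 2] >= z0) & (pts[:, 2] <= z1)
        if self.geometry["kind"] == "box":
            (x0, x1), (y0, y1) = self.geometry["x"], self.geometry["y"]
            inside &= (pts[:, 0] >= x0) & (pts[:, 0] <= x1)
            inside &= (pts[:, 1] >= y0) & (pts[:, 1] <= y1)
        else:
            poly = Polygon(self.geometry["vertices"])
            inside &= contains_xy(poly, pts[:, 0], pts[:, 1])
        return inside

    def to_dict(self) -> dict[str, Any]:
        return {
            "name": self.name,
            "segment": self.segment,
            "lamina": self.lamina,
            "side": self.side,
            "geometry": _plain(self.geometry),
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "Region":
        return cls(
            name=d["name"],
            segment=d["segment"],
            lamina=d["lamina"],
            side=d.get("side", ""),
            geometry=d["geometry"],
        )


def sample_positions(
    region: Region, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw ``n`` points uniformly inside ``region``.

    Boxes are sampled directly; extruded polygons by rejection from the
    polygon's bounding box (uniform over the prism volume).  Returns an
    (n, 3) float array in μm.
    """
    if n < 0:
        raise ModelError("n must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n == 0:
        return np.empty((0, 3), dtype=float)
    z0, z1 = region.z_span
    if region.geometry["kind"] == "box":
        (x0, x1), (y0, y1) = region.geometry["x"], region.geometry["y"]
        out = np.column_stack(
            [
                rng.uniform(x0, x1, n),
                rng.uniform(y0, y1, n),
                rng.uniform(z0, z1, n),
            ]
        )
        return out
    poly = Polygon(region.geometry["vertices"])
    minx, miny, maxx, maxy = poly.bounds
    pts: list[np.ndarray] = []
    remaining = n
    while remaining > 0:
        batch = max(remaining * 4, 64)
        x = rng.uniform(minx, maxx, batch)
        y = rng.uniform(miny, maxy, batch)
        keep = contains_xy(poly, x, y)
        accepted = np.column_stack([x[keep], y[keep]])[:remaining]
        if accepted.size:
            pts.append(accepted)
            remaining -= len(accepted)
    xy = np.vstack(pts)
    return np.column_stack([xy, rng.uniform(z0, z1, n)])


# ---------------------------------------------------------------------------
# Cell groups and net connections
# ---------------------------------------------------------------------------


@dataclass
class CellGroup:
    """A functionally homogeneous group of cells placed in one region."""

    name: str
    region: str
    template: str
    count: RandomScalar
    neuron_type: str
    target_muscle: str | None = None
    realized_count: int | None = None

    def __post_init__(self) -> None:
        if self.neuron_type not in NEURON_TYPES:
            raise ModelError(
                f"cell group {self.name}: unknown neuron_type {self.neuron_type!r}"
            )

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            "name": self.name,
            "region": self.region,
            "template": self.template,
            "count": self.count.to_dict(),
            "neuron_type": self.neuron_type,
        }
        if self.target_muscle is not None:
            d["target_muscle"] = self.target_muscle
        if self.realized_count is not None:
            d["realized_count"] = self.realized_count
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "CellGroup":
        return cls(
            name=d["name"],
            region=d["region"],
            template=d["template"],
            count=RandomScalar.from_dict(d["count"]),
            neuron_type=d["neuron_type"],
            target_muscle=d.get("target_muscle"),
            realized_count=d.get("realized_count"),
        )


@dataclass
class NetConnection:
    """Source group → destination group with synaptic properties.

    ``weight`` (μS) and ``convergence`` (presynaptic cells per destination
    cell) are random variables; ``delay`` (ms), ``tau`` (ms) and ``e_rev``
    (mV) are fixed synaptic properties.  ``rule`` records provenance (the
    connection rule or generation method that produced this connection).
    """

    source: str
    dest: str
    sign: str
    weight: RandomScalar
    delay: float
    tau: float
    e_rev: float
    convergence: RandomScalar
    rule: str = ""
    realized_weight: float | None = None
    realized_convergence: int | None = None

    def __post_init__(self) -> None:
        if self.sign not in ("excitatory", "inhibitory"):
            raise ModelError(f"connection {self.source}->{self.dest}: bad sign")
        if self.delay <= 0:
            raise ModelError(f"connection {self.source}->{self.dest}: delay must be > 0")
        if self.tau <= 0:
            raise ModelError(f"connection {self.source}->{self.dest}: tau must be > 0")
        if self.sign == "inhibitory" and self.e_rev > -55.0:
            raise ModelError(
                f"connection {self.source}->{self.dest}: inhibitory reversal "
                f"{self.e_rev} mV is above typical rest"
            )

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            "source": self.source,
            "dest": self.dest,
            "sign": self.sign,
            "weight": self.weight.to_dict(),
            "delay": self.delay,
            "tau": self.tau,
            "e_rev": self.e_rev,
            "convergence": self.convergence.to_dict(),
            "rule": self.rule,
        }
        if self.realized_weight is not None:
            d["realized_weight"] = self.realized_weight
        if self.realized_convergence is not None:
            d["realized_convergence"] = self.realized_convergence
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "NetConnection":
        return cls(
            source=d["source"],
            dest=d["dest"],
            sign=d["sign"],
            weight=RandomScalar.from_dict(d["weight"]),
            delay=float(d["delay"]),
            tau=float(d["tau"]),
            e_rev=float(d["e_rev"]),
            convergence=RandomScalar.from_dict(d["convergence"]),
            rule=d.get("rule", ""),
            realized_weight=d.get("realized_weight"),
            realized_convergence=d.get("realized_convergence"),
        )


# ---------------------------------------------------------------------------
# Model definition
# ---------------------------------------------------------------------------

_CORE_KEYS = ("info", "regions", "segments", "cell_groups", "net_connections", "aux")


@dataclass
class ModelDefinition:
    """The five-section structured model plus auxiliary data."""

    info: dict[str, Any] = field(default_factory=dict)
    segments: list[SpinalSegment] = field(default_factory=list)
    regions: list[Region] = field(default_factory=list)
    cell_groups: list[CellGroup] = field(default_factory=list)
    net_connections: list[NetConnection] = field(default_factory=list)
    aux: dict[str, Any] = field(default_factory=dict)

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        """Check referential integrity and geometric invariants."""
        seg_by_name = {s.name: s for s in self.segments}
        if len(seg_by_name) != len(self.segments):
            raise ModelError("duplicate segment names")
        # segments tile the neuraxis
        ordered = sorted(self.segments, key=lambda s: s.rostro_caudal_offset)
        for a, b in zip(ordered, ordered[1:]):
            if b.rostro_caudal_offset < a.rostro_caudal_offset + a.length - 1e-9:
                raise ModelError(f"segments {a.name} and {b.name} overlap")
        region_by_name = {r.name: r for r in self.regions}
        if len(region_by_name) != len(self.regions):
            raise ModelError("duplicate region names")
        for r in self.regions:
            seg = seg_by_name.get(r.segment)
            if seg is None:
                raise ModelError(f"region {r.name}: unknown segment {r.segment!r}")
            z0, z1 = r.z_span
            s0, s1 = seg.z_span
            if z0 < s0 - 1e-9 or z1 > s1 + 1e-9:
                raise ModelError(
                    f"region {r.name}: z extent [{z0}, {z1}] outside segment "
                    f"{seg.name} span [{s0}, {s1})"
                )
        group_by_name = {g.name: g for g in self.cell_groups}
        if len(group_by_name) != len(self.cell_groups):
            raise ModelError("duplicate cell group names")
        for g in self.cell_groups:
            if g.region not in region_by_name:
                raise ModelError(f"cell group {g.name}: unknown region {g.region!r}")
        for c in self.net_connections:
            for end in (c.source, c.dest):
                if end not in group_by_name:
                    raise ModelError(
                        f"net connection {c.source}->{c.dest}: unknown group {end!r}"
                    )
        positions = self.aux.get("positions", {})
        for gname, pts in positions.items():
            g = group_by_name.get(gname)
            if g is None:
                raise ModelError(f"aux.positions: unknown group {gname!r}")
            if g.realized_count is not None and len(pts) != g.realized_count:
                raise ModelError(
                    f"aux.positions[{gname}]: {len(pts)} points for "
                    f"realized_count {g.realized_count}"
                )
            region = region_by_name[g.region]
            if len(pts) and not region.contains(np.asarray(pts)).all():
                raise ModelError(f"aux.positions[{gname}]: point outside region")

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return {
            "info": _plain(self.info),
            "regions": [r.to_dict() for r in self.regions],
            "segments": [s.to_dict() for s in self.segments],
            "cell_groups": [g.to_dict() for g in self.cell_groups],
            "net_connections": [c.to_dict() for c in self.net_connections],
            "aux": _plain(self.aux),
        }

    def to_json(self) -> str:
        """Canonical JSON: fixed top-level key order, 2-space indent."""
        d = self.to_dict()
        return json.dumps({k: d[k] for k in _CORE_KEYS}, indent=2)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ModelDefinition":
        model = cls(
            info=dict(d.get("info", {})),
            segments=[SpinalSegment.from_dict(s) for s in d.get("segments", [])],
            regions=[Region.from_dict(r) for r in d.get("regions", [])],
            cell_groups=[CellGroup.from_dict(g) for g in d.get("cell_groups", [])],
            net_connections=[
                NetConnection.from_dict(c) for c in d.get("net_connections", [])
            ],
            aux=dict(d.get("aux", {})),
        )
        return model

    @classmethod
    def from_json(cls, text: str) -> "ModelDefinition":
        return cls.from_dict(json.loads(text))

    @classmethod
    def load(cls, path: str | Path) -> "ModelDefinition":
        model = cls.from_json(Path(path).read_text())
        model.validate()
        return model

    # -- convenience --------------------------------------------------------

    def group(self, name: str) -> CellGroup:
        for g in self.cell_groups:
            if g.name == name:
                return g
        raise KeyError(name)

    def groups_of_type(self, neuron_type: str) -> list[CellGroup]:
        return [g for g in self.cell_groups if g.neuron_type == neuron_type]


def _plain(obj: Any) -> Any:
    """Recursively convert numpy scalars/arrays into JSON-safe builtins."""
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, Mapping):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


# ---------------------------------------------------------------------------
# Curated tables
# ---------------------------------------------------------------------------


@dataclass
class CuratedModel:
    """Validated in-memory curated tables.

    ``tables`` maps table name → DataFrame.  Columns beyond the required set
    are preserved in ``extra_columns`` metadata; a ``refs`` column, when
    present, carries citation strings that are copied into
    ``ModelDefinition.aux['references']``.
    """

    tables: dict[str, pd.DataFrame]
    extra_columns: dict[str, list[str]] = field(default_factory=dict)

    def __getitem__(self, name: str) -> pd.DataFrame:
        return self.tables[name]


def load_curated_model(table_dir: str | Path) -> CuratedModel:
    """Load and validate the curated CSV tables from ``table_dir``.

    Each required table may be a ``.csv`` (header row) or ``.json``
    (list-of-records) file.  Unknown columns are preserved and reported in
    ``extra_columns``.  Missing tables raise :class:`TableLoadError` naming
    every missing table; malformed rows raise with the row number.
    """
    table_dir = Path(table_dir)
    tables: dict[str, pd.DataFrame] = {}
    extra: dict[str, list[str]] = {}
    missing: list[str] = []
    for name, required_cols in REQUIRED_TABLES.items():
        csv_path = table_dir / f"{name}.csv"
        json_path = table_dir / f"{name}.json"
        if csv_path.exists():
            df = pd.read_csv(csv_path, dtype=str, keep_default_na=False)
        elif json_path.exists():
            df = pd.DataFrame(json.loads(json_path.read_text()))
        else:
            missing.append(name)
            continue
        missing_cols = [c for c in required_cols if c not in df.columns]
        if missing_cols:
            raise TableLoadError(
                f"table {name!r}: missing required columns {missing_cols}"
            )
        extras = [c for c in df.columns if c not in required_cols]
        if extras:
            extra[name] = extras
        tables[name] = df
    if missing:
        raise TableLoadError(f"missing required tables: {missing}")
    _validate_tables(tables)
    return CuratedModel(tables=tables, extra_columns=extra)


def _row_float(df_name: str, row: pd.Series, idx: int, col: str, default=None) -> float:
    raw = row.get(col, "")
    if raw in ("", None) and default is not None:
        return default
    try:
        return float(raw)
    except (TypeError, ValueError):
        raise TableLoadError(
            f"table {df_name!r} row {idx + 2}: column {col!r} has non-numeric "
            f"value {raw!r}"
        ) from None


def _validate_tables(tables: dict[str, pd.DataFrame]) -> None:
    for idx, row in tables["segments"].iterrows():
        length = _row_float("segments", row, idx, "length")
        if length <= 0:
            raise TableLoadError(f"table 'segments' row {idx + 2}: length <= 0")
    for idx, row in tables["neuronal_cell_types"].iterrows():
        if row["neuron_type"] not in NEURON_TYPES:
            raise TableLoadError(
                f"table 'neuronal_cell_types' row {idx + 2}: unknown neuron_type "
                f"{row['neuron_type']!r}"
            )
        _row_float("neuronal_cell_types", row, idx, "count_mean")
    for idx, row in tables["connection_rules"].iterrows():
        for col in ("weight_mean", "delay", "tau", "e_rev", "convergence_mean"):
            _row_float("connection_rules", row, idx, col)


def parse_segments(curated: CuratedModel) -> list[SpinalSegment]:
    """Build segments tiled caudal→rostral in table order, aligned on the
    central canal."""
    out: list[SpinalSegment] = []
    offset = 0.0
    for idx, row in curated["segments"].iterrows():
        length = _row_float("segments", row, idx, "length")
        cx = _row_float("segments", row, idx, "central_canal_x", 0.0)
        cy = _row_float("segments", row, idx, "central_canal_y", 0.0)
        out.append(
            SpinalSegment(
                name=row["name"],
                length=length,
                rostro_caudal_offset=offset,
                central_canal_xy=(cx, cy),
            )
        )
        offset += length
    return out


def parse_regions(
    curated: CuratedModel, segments: Sequence[SpinalSegment]
) -> list[Region]:
    seg_by_name = {s.name: s for s in segments}
    out: list[Region] = []
    for idx, row in curated["regions"].iterrows():
        seg = seg_by_name.get(row["segment"])
        if seg is None:
            raise ModelError(
                f"table 'regions' row {idx + 2}: unknown segment {row['segment']!r}"
            )
        z0 = _row_float("regions", row, idx, "z_min", seg.z_span[0])
        z1 = _row_float("regions", row, idx, "z_max", seg.z_span[1])
        if row["kind"] == "box":
            geometry = {
                "kind": "box",
                "x": [
                    _row_float("regions", row, idx, "x_min"),
                    _row_float("regions", row, idx, "x_max"),
                ],
                "y": [
                    _row_float("regions", row, idx, "y_min"),
                    _row_float("regions", row, idx, "y_max"),
                ],
                "z": [z0, z1],
            }
        elif row["kind"] == "extruded_polygon":
            vertices = [
                [float(v) for v in pair.split()]
                for pair in str(row["polygon"]).split(";")
            ]
            geometry = {"kind": "extruded_polygon", "vertices": vertices, "z": [z0, z1]}
        else:
            raise ModelError(
                f"table 'regions' row {idx + 2}: unknown kind {row['kind']!r}"
            )
        out.append(
            Region(
                name=row["name"],
                segment=row["segment"],
                lamina=row["lamina"],
                side=row["side"],
                geometry=geometry,
            )
        )
    return out


def collect_references(curated: CuratedModel) -> dict[str, list[str]]:
    """Gather the ``refs`` citation columns, keyed by table/row element name."""
    refs: dict[str, list[str]] = {}
    for tname, df in curated.tables.items():
        if "refs" not in df.columns:
            continue
        for _, row in df.iterrows():
            if not row["refs"]:
                continue
            key_col = "name" if "name" in df.columns else df.columns[0]
            key = f"{tname}:{row[key_col]}"
            refs.setdefault(key, []).append(str(row["refs"]))
    return refs


def build_model_definition(
    curated: CuratedModel,
    seed: int,
    cell_groups: Sequence[CellGroup] | None = None,
    net_connections: Sequence[NetConnection] | None = None,
    info: Mapping[str, Any] | None = None,
) -> ModelDefinition:
    """Enumerate curated tables into a fully realized :class:`ModelDefinition`.

    If ``cell_groups``/``net_connections`` are not supplied they are generated
    from the curated tables with the muscle-synergy rule engine
    (:mod:`neuromotor.circuit_gen`).  All random scalars (counts, weights,
    convergences) and cell positions are realized through one generator seeded
    with ``seed``, so identical inputs and seed give byte-identical JSON.
    """
    from neuromotor import circuit_gen  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    segments = parse_segments(curated)
    regions = parse_regions(curated, segments)
    region_by_name = {r.name: r for r in regions}

    if cell_groups is None:
        cell_groups = circuit_gen.generate_cell_groups(
            curated["neuronal_cell_types"], regions
        )
    if net_connections is None:
        synergy = circuit_gen.MuscleSynergyTable.from_table(curated["muscle_synergy"])
        rules = circuit_gen.parse_connection_rules(curated["connection_rules"])
        net_connections = circuit_gen.generate_net_connections(
            rules, cell_groups, synergy
        )
    cell_groups = list(cell_groups)
    net_connections = list(net_connections)

    # Realize counts and positions (deterministic iteration order).
    positions: dict[str, list[list[float]]] = {}
    for g in cell_groups:
        g.realized_count = g.count.sample_int(rng)
        region = region_by_name.get(g.region)
        if region is None:
            raise ModelError(f"cell group {g.name}: unresolved region {g.region!r}")
        pts = sample_positions(region, g.realized_count, rng)
        positions[g.name] = [[float(v) for v in p] for p in pts]

    count_by_name = {g.name: g.realized_count for g in cell_groups}
    for c in net_connections:
        c.realized_weight = round(float(c.weight.sample(rng)), 9)
        conv = c.convergence.sample_int(rng)
        src_count = count_by_name.get(c.source, 0)
        if src_count and conv > src_count:
            logger.warning(
                "connection %s->%s: realized convergence %d exceeds source "
                "count %d; clipped",
                c.source,
                c.dest,
                conv,
                src_count,
            )
            conv = src_count
        c.realized_convergence = conv

    templates = _instantiate_templates(curated, cell_groups)

    model = ModelDefinition(
        info=dict(info or {"name": "model", "seed": seed}),
        segments=segments,
        regions=regions,
        cell_groups=cell_groups,
        net_connections=net_connections,
        aux={
            "positions": positions,
            "templates": templates,
            "references": collect_references(curated),
        },
    )
    model.validate()
    return model


def _instantiate_templates(
    curated: CuratedModel, cell_groups: Sequence[CellGroup]
) -> dict[str, dict[str, Any]]:
    """Resolve each group's cell template from the cell_templates table.

    The table is long-format (template, parameter, value): ``parameter`` is a
    dotted path into the template dict, e.g. ``model_class`` or
    ``mechanisms.soma.KCa.gbar``.  Templates start from the packaged defaults
    when ``model_class`` names a built-in; table rows override.
    """
    from neuromotor.cell_models import builtin_template, has_builtin_template

    used = sorted({g.template for g in cell_groups})
    table = curated["cell_templates"]
    out: dict[str, dict[str, Any]] = {}
    for tname in used:
        rows = table[table["template"] == tname]
        params: dict[str, Any] = {}
        for _, row in rows.iterrows():
            params[row["parameter"]] = row["value"]
        base = params.pop("base", None) or (
            tname if has_builtin_template(tname) else None
        )
        if base is not None:
            tpl = builtin_template(base).to_dict()
        elif rows.empty:
            raise ModelError(f"cell template {tname!r}: not in table, not built-in")
        else:
            tpl = {"name": tname, "model_class": params.pop("model_class", None)}
        tpl["name"] = tname
        for path, raw in params.items():
            _set_path(tpl, path, _coerce(raw))
        out[tname] = tpl
    return out


def _coerce(raw: Any) -> Any:
    if isinstance(raw, str):
        try:
            f = float(raw)
            return int(f) if f.is_integer() and "." not in raw and "e" not in raw.lower() else f
        except ValueError:
            return raw
    return raw


def _set_path(d: dict[str, Any], path: str, value: Any) -> None:
    keys = path.split(".")
    cur = d
    for k in keys[:-1]:
        cur = cur.setdefault(k, {})
    cur[keys[-1]] = value
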