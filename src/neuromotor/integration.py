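"""Cell-model integration: template comparison, Pearson-sum objective, and
subspace-then-joint coordinate ascent.

An *integrated* cell model is built from one base (constituent) template
plus a handful of parameters imported from other constituents — typically
the calcium/K(Ca) conductances (``gkcabar_KCa``, ``gcanbar_CaN``,
``gcalbar_CaL``) and the perisomatic placement index ``range``.  The
search objective is the sum of Pearson correlation coefficients between
the candidate model's response series and each constituent reference
series; it is maximized by coordinate ascent, first within each parameter
subspace (yielding seed points), then jointly over all parameters from the
top-scoring seeds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from neuromotor.cell_models import CellTemplate, builtin_template
from neuromotor.model_def import ModelError

logger = logging.getLogger(__name__)

KEY_NOT_FOUND = "KeyNotFound"


# ---------------------------------------------------------------------------
# compare_cells
# ---------------------------------------------------------------------------


def compare_cells(a: CellTemplate, b: CellTemplate) -> pd.DataFrame:
    """Tabulated parameter diff of two cell templates.

    Three columns (``parameter``, value in A, value in B) over the union of
    both parameter paths, sorted by path; a parameter absent from one
    template is shown as ``KeyNotFound``.  ``equal`` flags matching rows.
    """
    fa, fb = a.flatten(), b.flatten()
    rows = []
    for path in sorted(set(fa) | set(fb)):
        va = fa.get(path, KEY_NOT_FOUND)
        vb = fb.get(path, KEY_NOT_FOUND)
        rows.append({"parameter": path, a.name: va, b.name: vb,
                     "equal": va == vb})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Objective
# ---------------------------------------------------------------------------


def _as_series(s: Any) -> np.ndarray:
    arr = np.asarray(s, dtype=float)
    if arr.ndim == 1:
        arr = np.column_stack([np.arange(arr.size), arr])
    if arr.size == 0:
        raise ModelError("empty response series")
    return arr


def pearson_on_common_support(candidate: Any, reference: Any) -> float:
    """Pearson r between two (x, y) series resampled by linear interpolation
    onto the overlap of their x supports; constant series score 0."""
    c = _as_series(candidate)
    r = _as_series(reference)
    lo = max(c[:, 0].min(), r[:, 0].min())
    hi = min(c[:, 0].max(), r[:, 0].max())
    if hi <= lo:
        return -1.0  # no overlap: maximally dissimilar
    # union of the two supports inside the overlap: identical supports are
    # compared point-for-point (textbook Pearson), differing supports are
    # linearly resampled
    grid = np.unique(np.concatenate([c[:, 0], r[:, 0]]))
    grid = grid[(grid >= lo) & (grid <= hi)]
    if grid.size < 3:
        grid = np.linspace(lo, hi, 50)
    ic, ir = np.argsort(c[:, 0]), np.argsort(r[:, 0])
    yc = np.interp(grid, c[ic, 0], c[ic, 1])
    yr = np.interp(grid, r[ir, 0], r[ir, 1])
    if np.std(yc) == 0 or np.std(yr) == 0:
        logger.warning("constant series in Pearson objective; r := 0")
        return 0.0
    return float(np.corrcoef(yc, yr)[0, 1])


@dataclass
class ObjectiveScore:
    per_reference: list[float]

    @property
    def total(self) -> float:
        return float(sum(self.per_reference))


def objective(candidate_responses: Sequence[Any],
              references: Sequence[Any]) -> ObjectiveScore:
    """Sum of Pearson r between each candidate/reference series pair."""
    if len(candidate_responses) != len(references):
        raise ModelError("one candidate series per reference required")
    return ObjectiveScore([
        pearson_on_common_support(c, r)
        for c, r in zip(candidate_responses, references)])


# ---------------------------------------------------------------------------
# Coordinate ascent
# ---------------------------------------------------------------------------


@dataclass
class ParamSpec:
    path: str
    bounds: tuple[float, float]
    subspace: str
    integer: bool = False

    def clip(self, x: float) -> float:
        x = min(max(x, self.bounds[0]), self.bounds[1])
        return float(round(x)) if self.integer else float(x)


@dataclass
class IntegrationProblem:
    """Search problem: base template, parameter specs, reference series.

    ``evaluate(template) -> list of response series`` runs the experiments
    (one series per reference).  The default evaluator is installed by
    :func:`default_evaluator`; tests may inject analytic surrogates.
    """

    base_template: CellTemplate
    params: list[ParamSpec]
    references: list[Any]
    evaluate: Callable[[CellTemplate], Sequence[Any]] | None = None
    history: list[tuple[dict[str, float], float]] = field(default_factory=list)

    def make_template(self, values: Mapping[str, float]) -> CellTemplate:
        tpl = self.base_template.copy(self.base_template.name + "_candidate")
        for spec in self.params:
            v = spec.clip(values[spec.path])
            tpl.set_param(spec.path, int(v) if spec.integer else v)
        return tpl

    def score(self, values: Mapping[str, float]) -> float:
        n = len(self.references)
        try:
            responses = self.evaluate(self.make_template(values))
            s = objective(responses, self.references).total
        except Exception as exc:  # noqa: BLE001 — search must survive bad points
            logger.warning("objective failed at %s: %s", dict(values), exc)
            s = -float(n)
        self.history.append((dict(values), s))
        return s


#: step-size schedule: grow on improvement, shrink and flip on deterioration
STEP_GROW = 1.5
STEP_SHRINK = 0.5
STEP_FLOOR_FRAC = 1e-3
TOP_K_SEEDS = 2


def _ascend(problem: IntegrationProblem, values: dict[str, float],
            specs: Sequence[ParamSpec], iterations: int,
            init_step_frac: float = 0.2) -> tuple[dict[str, float], float]:
    """Adaptive-step coordinate ascent over ``specs``, cycling parameters."""
    best = dict(values)
    best_score = problem.score(best)
    steps = {s.path: init_step_frac * (s.bounds[1] - s.bounds[0])
             for s in specs}
    direction = {s.path: +1.0 for s in specs}
    floors = {s.path: STEP_FLOOR_FRAC * (s.bounds[1] - s.bounds[0])
              for s in specs}
    for it in range(iterations):
        spec = specs[it % len(specs)]
        p = spec.path
        candidate = dict(best)
        candidate[p] = spec.clip(best[p] + direction[p] * steps[p])
        score = problem.score(candidate)
        if score > best_score:
            best, best_score = candidate, score
            steps[p] *= STEP_GROW
        else:
            direction[p] = -direction[p]
            steps[p] = max(steps[p] * STEP_SHRINK, floors[p])
    return best, best_score


def coordinate_ascent(problem: IntegrationProblem, iterations: int = 30,
                      seed: int = 0) -> tuple[dict[str, float],
                                              list[tuple[dict, float]]]:
    """Subspace-then-joint coordinate ascent.

    Phase 1 ascends each parameter subspace independently from a random
    start (other parameters at the base template's values), producing one
    seed point per subspace.  Phase 2 ascends the full parameter space from
    the top-k seeds.  Returns the best parameter values and the full
    evaluation history (non-decreasing in best-so-far score).
    """
    if iterations < 1:
        raise ModelError("iterations must be >= 1")
    rng = np.random.default_rng(seed)
    base_values = {
        s.path: s.clip(float(_get_default(problem.base_template, s)))
        for s in problem.params}

    subspaces: dict[str, list[ParamSpec]] = {}
    for s in problem.params:
        subspaces.setdefault(s.subspace, []).append(s)

    seeds: list[tuple[dict[str, float], float]] = []
    for name, specs in subspaces.items():
        start = dict(base_values)
        for s in specs:
            lo, hi = s.bounds
            start[s.path] = s.clip(lo + rng.uniform(0.25, 0.75) * (hi - lo))
        best, score = _ascend(problem, start, specs, iterations)
        seeds.append((best, score))
        logger.info("subspace %s: score %.3f at %s", name, score, best)

    seeds.sort(key=lambda t: -t[1])
    overall_best, overall_score = seeds[0]
    for start, _ in seeds[:TOP_K_SEEDS]:
        best, score = _ascend(problem, dict(start), problem.params,
                              iterations, init_step_frac=0.1)
        if score > overall_score:
            overall_best, overall_score = best, score
    return overall_best, problem.history


def _get_default(template: CellTemplate, spec: ParamSpec) -> float:
    try:
        return float(template.get_param(spec.path))
    except (KeyError, StopIteration):
        return 0.5 * (spec.bounds[0] + spec.bounds[1])


# ---------------------------------------------------------------------------
# Default (simulation-backed) evaluator
# ---------------------------------------------------------------------------


def default_evaluator(reference_specs: Sequence[Mapping[str, Any]],
                      dt: float = 0.05) -> Callable:
    """Evaluator running the referenced single-cell experiments.

    Each spec selects an experiment (``triangular_ramp_fi`` or
    ``fi_curve``); the candidate template is run through the same protocol
    and the resulting analysis-level series is returned for the Pearson
    objective.
    """
    from neuromotor import ephys_analysis as ea
    from neuromotor.cell_models import StimulusSpec

    def evaluate(template: CellTemplate) -> list[np.ndarray]:
        out = []
        for spec in reference_specs:
            kind = spec.get("experiment", "fi_curve")
            if kind == "triangular_ramp_fi":
                # frequency-vs-time over the whole triangle keeps the
                # hysteresis signature (ascending and descending limbs)
                tr = spec.get("t_ramp", 1000.0)
                ramp = StimulusSpec.iclamp([(0, 0), (tr, spec.get("i_peak", 12.0)),
                                            (2 * tr, 0)])
                sp = ea.run_single_cell(template, ramp, 2 * tr, dt)
                out.append(ea.instantaneous_frequency(sp))
            elif kind == "fi_curve":
                ramp = StimulusSpec.iclamp(
                    [(0.0, 0.0), (spec.get("t_ramp", 1000.0),
                                  spec.get("i_max", 50.0))])
                pairs, _ = ea.fi_curve(template, ramp, dt=dt)
                out.append(pairs)
            else:
                raise ModelError(f"unknown reference experiment {kind!r}")
        return out

    return evaluate


def reference_responses(reference_specs: Sequence[Mapping[str, Any]],
                        dt: float = 0.05) -> list[np.ndarray]:
    """Materialize the constituent models' reference series."""
    from neuromotor.cell_models import builtin_template

    out = []
    for spec in reference_specs:
        tpl = builtin_template(spec.get("template", "M_cell_srr"))
        if spec.get("serotonin"):
            tpl = tpl.with_serotonin()
        out.append(default_evaluator([spec], dt=dt)(tpl)[0])
    return out
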