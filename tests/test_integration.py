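"""Template comparison, Pearson-sum objective, and coordinate ascent."""

import numpy as np
import pytest

from neuromotor import integration as ig
from neuromotor.cell_models import builtin_template
from neuromotor.model_def import ModelError


class TestCompareCells:
    def test_parameter_missing_in_one_template_reads_keynotfound(self):
        a = builtin_template("M_cell_srr")
        b = builtin_template("M_cell_bistable")
        diff = ig.compare_cells(a, b)
        rows = diff[diff["parameter"] == "passive.g_leak_dend"]
        assert len(rows) == 1
        assert rows.iloc[0]["M_cell_srr"] == ig.KEY_NOT_FOUND
        assert rows.iloc[0]["M_cell_bistable"] != ig.KEY_NOT_FOUND

    def test_identical_templates_have_zero_differing_rows(self):
        a = builtin_template("M_cell_Slow")
        b = builtin_template("M_cell_Slow")
        diff = ig.compare_cells(a, b)
        assert diff["equal"].all()

    def test_single_conductance_difference_isolated(self):
        a = builtin_template("M_cell_Slow")
        b = builtin_template("M_cell_Slow")
        b.mechanisms["soma"]["KCa"]["gkcabar"] *= 2
        diff = ig.compare_cells(a, b)
        differing = diff[~diff["equal"]]
        assert list(differing["parameter"]) == ["mechanisms.soma.KCa.gkcabar"]

    def test_rows_sorted_by_parameter_path(self):
        diff = ig.compare_cells(builtin_template("M_cell_Slow"),
                                builtin_template("M_cell_FF"))
        assert list(diff["parameter"]) == sorted(diff["parameter"])


class TestObjective:
    def test_identical_series_score_n(self):
        refs = [np.column_stack([np.arange(10), np.sin(np.arange(10))]),
                np.column_stack([np.arange(10), np.arange(10) ** 2])]
        score = ig.objective(refs, [r.copy() for r in refs])
        assert score.total == pytest.approx(len(refs))

    def test_negated_series_scores_minus_one(self):
        x = np.arange(20.0)
        ref = np.column_stack([x, np.sin(x)])
        cand = np.column_stack([x, -np.sin(x)])
        score = ig.objective([cand], [ref])
        assert score.per_reference[0] == pytest.approx(-1.0)

    def test_five_point_series_matches_textbook_pearson(self):
        x = np.arange(5.0)
        ya = np.array([2.0, 4.0, 5.0, 4.0, 5.0])
        yb = np.array([1.0, 3.0, 2.0, 5.0, 6.0])
        # hand-computed product-moment formula
        expected = (np.sum((ya - ya.mean()) * (yb - yb.mean()))
                    / np.sqrt(np.sum((ya - ya.mean()) ** 2)
                              * np.sum((yb - yb.mean()) ** 2)))
        got = ig.pearson_on_common_support(np.column_stack([x, ya]),
                                           np.column_stack([x, yb]))
        assert got == pytest.approx(expected)

    def test_constant_series_scores_zero_with_warning(self, caplog):
        x = np.arange(10.0)
        with caplog.at_level("WARNING"):
            r = ig.pearson_on_common_support(
                np.column_stack([x, np.ones_like(x)]),
                np.column_stack([x, np.sin(x)]))
        assert r == 0.0

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ModelError):
            ig.objective([np.ones((3, 2))], [])


def quadratic_problem(center, bounds=(-1.0, 1.0)):
    """Analytic 2-D concave objective with a known argmax."""
    specs = [ig.ParamSpec(path=f"params.p{i}", bounds=bounds, subspace=f"s{i}")
             for i in range(2)]
    tpl = builtin_template("interneuron_if")
    tpl.params["p0"], tpl.params["p1"] = 0.0, 0.0
    x_ref = np.linspace(0, 1, 50)

    def evaluate(template):
        p = np.array([template.params["p0"], template.params["p1"]])
        # score peaks when p == center: response slope tracks the quadratic
        val = -np.sum((p - np.asarray(center)) ** 2)
        return [np.column_stack([x_ref, x_ref * np.exp(val)])]

    # reference is the response at the optimum
    ref = [np.column_stack([x_ref, x_ref])]
    # the Pearson r of x vs x*exp(val) is 1 regardless of scale, so use a
    # shape that bends away from the reference as val drops
    def evaluate_shaped(template):
        p = np.array([template.params["p0"], template.params["p1"]])
        val = float(np.sum((p - np.asarray(center)) ** 2))
        return [np.column_stack([x_ref, x_ref + val * np.sin(8 * x_ref)])]

    return ig.IntegrationProblem(base_template=tpl, params=specs,
                                 references=ref, evaluate=evaluate_shaped)


class TestCoordinateAscent:
    def test_recovers_quadratic_argmax_within_1pct_of_range(self):
        center = (0.31, -0.42)
        problem = quadratic_problem(center)
        best, history = ig.coordinate_ascent(problem, iterations=60, seed=0)
        span = 2.0
        assert abs(best["params.p0"] - center[0]) < 0.01 * span
        assert abs(best["params.p1"] - center[1]) < 0.01 * span

    def test_monotone_objective_converges_to_bound(self):
        spec = ig.ParamSpec(path="params.p0", bounds=(0.0, 1.0), subspace="s")
        tpl = builtin_template("interneuron_if")
        tpl.params["p0"] = 0.1
        x = np.linspace(0, 1, 30)

        def evaluate(template):
            gain = template.params["p0"]
            return [np.column_stack([x, x + (1 - gain) * np.cos(9 * x)])]

        problem = ig.IntegrationProblem(
            base_template=tpl, params=[spec],
            references=[np.column_stack([x, x])], evaluate=evaluate)
        best, _ = ig.coordinate_ascent(problem, iterations=40, seed=1)
        assert best["params.p0"] == pytest.approx(1.0, abs=0.02)

    def test_history_best_so_far_non_decreasing(self):
        problem = quadratic_problem((0.2, 0.6))
        _, history = ig.coordinate_ascent(problem, iterations=25, seed=2)
        best_so_far = np.maximum.accumulate([s for _, s in history])
        assert (np.diff(best_so_far) >= 0).all()

    def test_objective_failure_scored_minus_n_and_search_continues(self):
        spec = ig.ParamSpec(path="params.p0", bounds=(0.0, 1.0), subspace="s")
        tpl = builtin_template("interneuron_if")
        tpl.params["p0"] = 0.5
        calls = {"n": 0}

        def evaluate(template):
            calls["n"] += 1
            if calls["n"] == 2:
                raise RuntimeError("solver blew up")
            x = np.linspace(0, 1, 10)
            return [np.column_stack([x, x])]

        problem = ig.IntegrationProblem(
            base_template=tpl, params=[spec],
            references=[np.column_stack([np.linspace(0, 1, 10),
                                         np.linspace(0, 1, 10)])],
            evaluate=evaluate)
        _, history = ig.coordinate_ascent(problem, iterations=5, seed=0)
        scores = [s for _, s in history]
        assert -1.0 in scores          # the failed point scored -N (N = 1)
        assert calls["n"] > 2          # search continued afterwards

    def test_iterations_must_be_positive(self):
        problem = quadratic_problem((0.0, 0.0))
        with pytest.raises(ModelError):
            ig.coordinate_ascent(problem, iterations=0)
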