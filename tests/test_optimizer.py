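"""Grouped LP optimizer: worked examples, vertex-oracle equivalence, invariants."""

import numpy as np
import pytest

from teacat import (
    CATECHINS,
    FACTORS,
    TEC_GROUP,
    GeneratorConfig,
    ValidationError,
    build_problem,
    load_table1,
    optimize_group_report,
    solve_lp,
    vertex_oracle,
)
from teacat.core import SchemaError
from teacat.optimize import DEMO_FACTOR_BOX, OPTIMAL_CONDITIONS, OptimizationProblem
from teacat.regression import CoefficientTable, RegressionModel
from teacat.synth import generate_catechins, generate_meteo


def random_problem(rng, target="egcg"):
    """Random coefficient table and box for oracle-equivalence trials."""
    models = {}
    for m in CATECHINS:
        models[m] = RegressionModel(
            response=m,
            intercept=float(rng.normal()),
            coefficients=tuple(rng.normal(scale=1.0, size=8).tolist()),
        )
    lows = rng.uniform(-10, 0, size=8)
    highs = lows + rng.uniform(0, 10, size=8)
    box = {f: (float(lo), float(hi)) for f, lo, hi in zip(FACTORS, lows, highs)}
    return OptimizationProblem(target, CoefficientTable(models), box)


class TestBuildProblem:
    def test_tec_group_constrains_co_members_only(self, table1, noisy_dataset):
        problem = build_problem("egcg", noisy_dataset, table1, group="TEC",
                                thresholds_source=noisy_dataset)
        assert set(problem.thresholds) == {"ecg", "gcg", "cg"}
        for m, (lo, hi) in problem.thresholds.items():
            y = noisy_dataset.response(m)
            assert lo == pytest.approx(y.min()) and hi == pytest.approx(y.max())

    def test_explicit_box_passes_through(self, table1):
        problem = build_problem("c", dict(DEMO_FACTOR_BOX), table1)
        assert problem.box == DEMO_FACTOR_BOX

    def test_invalid_inputs_rejected(self, table1, noisy_dataset):
        with pytest.raises(SchemaError, match="tc"):
            build_problem("tc", noisy_dataset, table1)
        with pytest.raises(ValidationError):
            OptimizationProblem("egcg", table1, dict(DEMO_FACTOR_BOX),
                                thresholds={"ecg": (5.0, 1.0)})
        with pytest.raises(ValidationError, match="own threshold"):
            OptimizationProblem("egcg", table1, dict(DEMO_FACTOR_BOX),
                                thresholds={"egcg": (1.0, 5.0)})


class TestSolveBoxOnly:
    def test_reported_c_optimum_vertex(self, table1):
        problem = build_problem("c", dict(DEMO_FACTOR_BOX), table1)
        result = solve_lp(problem)
        assert result.status == "optimal"
        assert np.allclose(result.argmax, OPTIMAL_CONDITIONS["c"], atol=1e-12)
        assert round(result.objective, 2) == 4.61

    def test_sign_rule_vertex(self, table1):
        problem = build_problem("egcg", dict(DEMO_FACTOR_BOX), table1)
        result = solve_lp(problem)
        slopes = table1["egcg"].coef_array()
        for j, f in enumerate(FACTORS):
            lo, hi = DEMO_FACTOR_BOX[f]
            expected = hi if slopes[j] > 0 else lo
            assert result.argmax[j] == pytest.approx(expected, abs=1e-12)

    def test_zero_coefficient_breaks_tie_to_low(self, table1):
        models = dict(load_table1().models)
        models["egcg"] = RegressionModel("egcg", 1.0, (0.0,) * 8)
        table = CoefficientTable(models)
        result = solve_lp(build_problem("egcg", dict(DEMO_FACTOR_BOX), table))
        lows = np.array([DEMO_FACTOR_BOX[f][0] for f in FACTORS])
        assert np.allclose(result.argmax, lows, atol=1e-12)

    def test_oracle_equivalence_on_random_problems(self):
        rng = np.random.default_rng(777)
        for _ in range(200):
            problem = random_problem(rng)
            a = solve_lp(problem)
            b = vertex_oracle(problem)
            assert np.array_equal(a.argmax, b.argmax)
            assert a.objective == pytest.approx(b.objective, abs=0)

    def test_oracle_rejects_group_constraints(self, table1, noisy_dataset):
        problem = build_problem("egcg", noisy_dataset, table1, group="TEC",
                                thresholds_source=noisy_dataset)
        with pytest.raises(ValidationError, match="box-only"):
            vertex_oracle(problem)

    def test_degenerate_box_all_fixed_but_one(self, table1):
        box = {f: (v, v) for f, v in zip(FACTORS, OPTIMAL_CONDITIONS["egcg"])}
        box["rainfall"] = (1.13, 9.78)
        result = solve_lp(build_problem("egcg", box, table1))
        oracle = vertex_oracle(build_problem("egcg", box, table1))
        assert np.array_equal(result.argmax, oracle.argmax)
        assert result.argmax[0] == 9.78  # positive rainfall coefficient


class TestGroupedSolve:
    def test_constraints_satisfied_at_reported_tolerance(self, table1, noisy_dataset):
        problem = build_problem("egcg", noisy_dataset, table1, group="TEC",
                                thresholds_source=noisy_dataset)
        result = solve_lp(problem)
        assert result.status == "optimal"
        lows = {f: noisy_dataset.frame[f].min() for f in FACTORS}
        highs = {f: noisy_dataset.frame[f].max() for f in FACTORS}
        for j, f in enumerate(FACTORS):
            assert lows[f] - 1e-9 <= result.argmax[j] <= highs[f] + 1e-9
        for m, (lo, hi) in problem.thresholds.items():
            assert lo - 1e-9 <= result.co_predictions[m] <= hi + 1e-9
        assert result.objective == pytest.approx(
            float(table1["egcg"].predict(result.argmax)), abs=1e-9
        )

    def test_thresholds_never_increase_the_optimum(self, table1, noisy_dataset):
        for target in ("egcg", "ecg", "c"):
            group = "TEC" if target in TEC_GROUP else "TNEC"
            free = solve_lp(build_problem(target, noisy_dataset, table1))
            constrained = solve_lp(
                build_problem(target, noisy_dataset, table1, group=group,
                              thresholds_source=noisy_dataset)
            )
            if constrained.status == "optimal":
                assert constrained.objective <= free.objective + 1e-9

    def test_empty_threshold_interval_is_infeasible(self, table1):
        problem = OptimizationProblem(
            "egcg", table1, dict(DEMO_FACTOR_BOX),
            group="TEC", thresholds={"ecg": (100.0, 101.0)},
        )
        result = solve_lp(problem)
        assert result.status == "infeasible"
        assert "ecg" in result.message

    def test_binding_constraints_reported(self, table1):
        result = solve_lp(build_problem("c", dict(DEMO_FACTOR_BOX), table1))
        assert "temp_avg=high" in result.binding
        assert "rainfall=low" in result.binding


class TestGroupReport:
    def test_tec_report_rows_and_sums(self, table1, noisy_dataset):
        report = optimize_group_report("TEC", table1, noisy_dataset,
                                       thresholds_source=noisy_dataset)
        assert list(report["target"]) == list(TEC_GROUP)
        optimal = report[report["status"] == "optimal"]
        assert (optimal["tec_sum"] > 0).all()

    def test_reported_tec_bound_at_ecg_optimum(self, table1):
        # the two esterified-catechin optimization schemes push TEC above 19%
        x = np.array(OPTIMAL_CONDITIONS["ecg"])
        total = sum(float(table1[m].predict(x)) for m in TEC_GROUP)
        assert total >= 19.0
        assert total == pytest.approx(20.46, abs=0.01)

    def test_unknown_or_empty_group_rejected(self, table1, noisy_dataset):
        with pytest.raises(ValidationError, match="unknown group"):
            optimize_group_report("XYZ", table1, noisy_dataset)
        empty = CoefficientTable({"egc": table1["egc"]})
        with pytest.raises(ValidationError, match="no member"):
            optimize_group_report("TEC", empty, noisy_dataset,
                                  thresholds_source=noisy_dataset)
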