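"""Constrained linear optimization of meteorological conditions.

Given the per-catechin linear equations, the optimization stage asks: which
combination of the eight meteorological factors, inside the box of
conditions actually observed across the tea plantations, maximizes the
predicted concentration of a target catechin?  Because catechins of the
same chemical group (esterified TEC, non-esterified TNEC) trade off
against each other, the other members of the target's group are kept
between data-derived thresholds while the target is maximized -- a small
linear program:

    maximize    b0_t + b_t . x
    subject to  low_j <= x_j <= high_j                    (factor box)
                lo_m <= b0_m + b_m . x <= hi_m            (group co-members)

The LP is solved exactly (HiGHS); ties are broken toward the
lexicographically smallest factor vector so results are deterministic.  A
brute-force vertex oracle over the 2^8 box corners is provided for
box-only problems as an independent check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .core import FACTORS, GROUPS, Dataset, SchemaError, ValidationError
from .regression import CoefficientTable, RegressionModel

__all__ = [
    "FactorBox",
    "OptimizationProblem",
    "OptimizationResult",
    "build_problem",
    "solve_lp",
    "vertex_oracle",
    "optimize_group_report",
    "DEMO_FACTOR_BOX",
    "OPTIMAL_CONDITIONS",
]

_FEAS_TOL = 1e-9

FactorBox = dict[str, tuple[float, float]]

#: factor box spanned by the published optimal condition vectors -- the demo
#: stand-in for the observed per-site min/max (raw study data not deposited)
DEMO_FACTOR_BOX: FactorBox = {
    "rainfall": (1.13, 9.78),
    "temp_avg": (12.72, 25.53),
    "eat": (223.50, 553.74),
    "temp_max": (26.9, 35.30),
    "temp_min": (-3.60, -3.60),
    "humidity": (75.50, 96.34),
    "ground_temp": (14.36, 30.65),
    "irradiance": (1283.50, 8421.08),
}

#: published optimal meteorological conditions per optimized catechin
OPTIMAL_CONDITIONS: dict[str, tuple[float, ...]] = {
    "egcg": (9.78, 12.72, 553.74, 35.30, -3.60, 96.34, 14.36, 8421.08),
    "ecg": (9.78, 25.53, 223.50, 35.30, -3.60, 75.50, 30.65, 1283.50),
    "c": (1.13, 25.53, 223.50, 26.9, -3.6, 96.34, 14.36, 1283.50),
}


@dataclass
class OptimizationProblem:
    """Maximize one catechin's predicted concentration over the factor box."""

    target: str
    table: CoefficientTable
    box: FactorBox
    group: str | None = None                       # "TEC" | "TNEC" | None
    thresholds: dict[str, tuple[float, float]] = field(default_factory=dict)
    vip_weights: Mapping[str, float] | None = None  # optional VIP-weighted objective

    def __post_init__(self) -> None:
        if self.target not in self.table:
            raise SchemaError(f"target {self.target!r} not in coefficient table")
        missing = [f for f in FACTORS if f not in self.box]
        if missing:
            raise ValidationError(f"factor box missing {', '.join(missing)}")
        for f, (lo, hi) in self.box.items():
            if not np.isfinite([lo, hi]).all():
                raise ValidationError(f"non-finite box bound for {f!r}")
            if lo > hi:
                raise ValidationError(f"box low > high for {f!r}: ({lo}, {hi})")
        if self.target in self.thresholds:
            raise ValidationError("target must not be constrained by its own threshold")
        for m, (lo, hi) in self.thresholds.items():
            if m not in self.table:
                raise SchemaError(f"threshold on unknown response {m!r}")
            if lo > hi:
                raise ValidationError(f"threshold low > high for {m!r}: ({lo}, {hi})")

    @property
    def co_members(self) -> list[str]:
        return list(self.thresholds)

    def objective(self) -> tuple[float, np.ndarray]:
        """(intercept, slope vector) of the objective, VIP-weighted if configured."""
        m = self.table[self.target]
        b = m.coef_array()
        if self.vip_weights is not None:
            w = np.array([self.vip_weights.get(f, 1.0) for f in FACTORS])
            b = b * w
        return m.intercept, b


@dataclass
class OptimizationResult:
    status: str                       # optimal | infeasible | unbounded
    target: str
    argmax: np.ndarray | None         # ordered x1..x8
    objective: float | None
    co_predictions: dict[str, float]  # group members evaluated at argmax
    binding: list[str]                # active constraints at the optimum
    message: str = ""

    def argmax_dict(self) -> dict[str, float]:
        if self.argmax is None:
            raise ValidationError(f"no argmax: problem is {self.status}")
        return dict(zip(FACTORS, self.argmax.tolist()))

    def to_row(self) -> dict[str, object]:
        row: dict[str, object] = {"target": self.target, "status": self.status}
        if self.argmax is not None:
            row.update(self.argmax_dict())
            row["objective"] = self.objective
            for m, v in self.co_predictions.items():
                row[f"pred_{m}"] = v
            row["binding"] = ";".join(self.binding)
        return row


# ---------------------------------------------------------------------------
# problem construction
# ---------------------------------------------------------------------------


def box_from_dataset(dataset: Dataset) -> FactorBox:
    """Per-factor observed (min, max) across all site-season records."""
    X = dataset.meteo_matrix()
    return {f: (float(X[:, j].min()), float(X[:, j].max())) for j, f in enumerate(FACTORS)}


def thresholds_from_dataset(dataset: Dataset, members: Sequence[str]) -> dict[str, tuple[float, float]]:
    """Observed (min, max) concentration per group co-member."""
    out = {}
    for m in members:
        y = dataset.response(m)
        out[m] = (float(y.min()), float(y.max()))
    return out


def build_problem(
    target: str,
    bounds_source: Dataset | FactorBox,
    table: CoefficientTable,
    group: str | None = None,
    thresholds_source: Dataset | Mapping[str, tuple[float, float]] | None = None,
    vip_weights: Mapping[str, float] | None = None,
) -> OptimizationProblem:
    """Assemble the grouped LP for one target catechin.

    The box comes from per-factor observed min/max when ``bounds_source`` is
    a :class:`Dataset`, else it is taken verbatim.  When a group is named,
    the target's co-members are constrained between thresholds: explicit
    values if supplied, otherwise their observed min/max in
    ``thresholds_source``.
    """
    box = box_from_dataset(bounds_source) if isinstance(bounds_source, Dataset) else dict(bounds_source)
    thresholds: dict[str, tuple[float, float]] = {}
    if group is not None:
        if group not in GROUPS:
            raise ValidationError(f"unknown group {group!r}; expected one of {list(GROUPS)}")
        members = [m for m in GROUPS[group] if m != target]
        if target not in GROUPS[group]:
            raise ValidationError(f"target {target!r} is not a member of group {group}")
        if isinstance(thresholds_source, Dataset):
            thresholds = thresholds_from_dataset(thresholds_source, members)
        elif thresholds_source is not None:
            thresholds = {m: tuple(thresholds_source[m]) for m in members}
        else:
            raise ValidationError("grouped problem needs a thresholds_source (dataset or explicit)")
    return OptimizationProblem(target, table, box, group, thresholds, vip_weights)


# ---------------------------------------------------------------------------
# solvers
# ---------------------------------------------------------------------------


def _box_arrays(box: FactorBox) -> tuple[np.ndarray, np.ndarray]:
    lows = np.array([box[f][0] for f in FACTORS])
    highs = np.array([box[f][1] for f in FACTORS])
    return lows, highs


def _binding_constraints(problem: OptimizationProblem, x: np.ndarray) -> list[str]:
    lows, highs = _box_arrays(problem.box)
    binding = []
    for j, f in enumerate(FACTORS):
        at_low = abs(x[j] - lows[j]) <= _FEAS_TOL
        at_high = abs(x[j] - highs[j]) <= _FEAS_TOL
        if at_low and at_high:
            binding.append(f"{f}=fixed")
        elif at_low:
            binding.append(f"{f}=low")
        elif at_high:
            binding.append(f"{f}=high")
    for m, (lo, hi) in problem.thresholds.items():
        pred = float(problem.table[m].predict(x))
        if abs(pred - lo) <= 1e-7:
            binding.append(f"{m}>=low")
        elif abs(pred - hi) <= 1e-7:
            binding.append(f"{m}<=high")
    return binding


def _co_predictions(problem: OptimizationProblem, x: np.ndarray) -> dict[str, float]:
    members = GROUPS.get(problem.group, ()) if problem.group else problem.co_members
    out = {}
    for m in members:
        if m in problem.table:
            out[m] = float(problem.table[m].predict(x))
    return out


def _sign_rule_argmax(slopes: np.ndarray, lows: np.ndarray, highs: np.ndarray) -> np.ndarray:
    """Box-only LP optimum: high bound iff slope > 0, else low (ties to low,
    which is also the lexicographically smallest optimal choice)."""
    return np.where(slopes > 0, highs, lows)


def _infeasibility_certificate(problem: OptimizationProblem) -> str:
    """Name a single-constraint cause when one exists, else report joint infeasibility."""
    lows, highs = _box_arrays(problem.box)
    for m, (lo, hi) in problem.thresholds.items():
        if lo > hi:
            return f"threshold interval for {m!r} is empty: ({lo}, {hi})"
        b = problem.table[m].coef_array()
        b0 = problem.table[m].intercept
        pred_min = b0 + float(np.where(b > 0, lows, highs) @ b)
        pred_max = b0 + float(np.where(b > 0, highs, lows) @ b)
        if pred_max < lo - _FEAS_TOL or pred_min > hi + _FEAS_TOL:
            return (
                f"threshold on {m!r} unreachable over the box: attainable range "
                f"[{pred_min:.4g}, {pred_max:.4g}] vs required [{lo:.4g}, {hi:.4g}]"
            )
    return "group thresholds are jointly infeasible over the box"


def _lex_refine(
    c_obj: np.ndarray,
    opt_value: float,
    x_incumbent: np.ndarray,
    lows: np.ndarray,
    highs: np.ndarray,
    A_ub: np.ndarray,
    b_ub: np.ndarray,
) -> np.ndarray:
    """Among (near-)optimal points, find the lexicographically smallest x.

    Sequentially minimizes each coordinate subject to the original
    constraints plus near-optimality of the objective; each step's minimum
    is appended as a further constraint.  Any solver hiccup falls back to
    the incumbent optimum, so the refinement can only improve determinism,
    never correctness.
    """
    n = len(lows)
    tol = 1e-9 * max(1.0, abs(opt_value))
    rows = [A_ub, -c_obj[None, :]]          # c.x >= opt_value - tol
    rhs = [b_ub, np.array([-(opt_value - tol)])]
    bounds = list(zip(lows, highs))
    best = x_incumbent
    for j in range(n):
        c = np.zeros(n)
        c[j] = 1.0
        res = linprog(c, A_ub=np.vstack(rows), b_ub=np.concatenate(rhs),
                      bounds=bounds, method="highs")
        if not res.success:
            return best
        best = res.x
        vj = float(res.x[j])
        rows.append(c[None, :])             # x_j <= vj (+ slack)
        rhs.append(np.array([vj + 1e-9 * max(1.0, abs(vj))]))
    return best


def solve_lp(problem: OptimizationProblem) -> OptimizationResult:
    """Exact solution of the grouped LP.

    Box-only problems use the closed-form sign rule (the optimum of a linear
    function over a box is the sign-consistent vertex); problems with group
    thresholds go through the HiGHS simplex solver, followed by a
    lexicographic refinement for deterministic tie-breaking.
    """
    b0, slopes = problem.objective()
    lows, highs = _box_arrays(problem.box)

    if not problem.thresholds:
        x = _sign_rule_argmax(slopes, lows, highs)
        obj = float(problem.table[problem.target].predict(x))
        return OptimizationResult(
            "optimal", problem.target, x, obj,
            _co_predictions(problem, x), _binding_constraints(problem, x),
        )

    # inequality rows: lo_m <= b0_m + b_m.x <= hi_m  ->  two <=-rows per member
    A_rows, b_rows = [], []
    for m, (lo, hi) in problem.thresholds.items():
        bm = problem.table[m].coef_array()
        b0m = problem.table[m].intercept
        A_rows.append(bm)
        b_rows.append(hi - b0m)
        A_rows.append(-bm)
        b_rows.append(b0m - lo)
    A_ub = np.array(A_rows)
    b_ub = np.array(b_rows)

    res = linprog(-slopes, A_ub=A_ub, b_ub=b_ub, bounds=list(zip(lows, highs)), method="highs")
    if res.status == 2:
        return OptimizationResult(
            "infeasible", problem.target, None, None, {}, [],
            message=_infeasibility_certificate(problem),
        )
    if res.status == 3:
        return OptimizationResult("unbounded", problem.target, None, None, {}, [],
                                  message="objective unbounded over the stated box")
    if not res.success:
        raise ValidationError(f"LP solver failed: {res.message}")

    opt_value = float(slopes @ res.x)
    x = _lex_refine(slopes, opt_value, res.x, lows, highs, A_ub, b_ub)
    obj = float(problem.table[problem.target].predict(x))
    return OptimizationResult(
        "optimal", problem.target, x, obj,
        _co_predictions(problem, x), _binding_constraints(problem, x),
    )


def vertex_oracle(problem: OptimizationProblem) -> OptimizationResult:
    """Exhaustive 2^p vertex enumeration for box-only problems (test oracle).

    Evaluates the objective at every corner of the box and returns the exact
    argmax under the same lexicographic tie-break as :func:`solve_lp`.
    """
    if problem.thresholds:
        raise ValidationError("vertex oracle handles box-only problems")
    _, slopes = problem.objective()
    lows, highs = _box_arrays(problem.box)
    p = len(FACTORS)
    best_x, best_val = None, -np.inf
    for mask in range(2 ** p):
        x = np.where([(mask >> j) & 1 for j in range(p)], highs, lows)
        val = float(slopes @ x)
        if val > best_val + 1e-15 or (
            abs(val - best_val) <= 1e-15 and best_x is not None and tuple(x) < tuple(best_x)
        ):
            best_x, best_val = x, val
    obj = float(problem.table[problem.target].predict(best_x))
    return OptimizationResult(
        "optimal", problem.target, best_x, obj,
        _co_predictions(problem, best_x), _binding_constraints(problem, best_x),
    )


def optimize_group_report(
    group: str,
    table: CoefficientTable,
    box: FactorBox | Dataset,
    thresholds_source: Dataset | Mapping[str, tuple[float, float]] | None = None,
    constrain_group: bool = True,
    vip_weights: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Optimize every member of a catechin group; one row per target.

    Each row reports the optimal factor vector, the target's optimized
    concentration, the co-members' predicted concentrations at that optimum
    and the group sum.  ``constrain_group=False`` drops the co-member
    thresholds (box-only optimization per target).
    """
    if group not in GROUPS:
        raise ValidationError(f"unknown group {group!r}; expected one of {list(GROUPS)}")
    members = [m for m in GROUPS[group] if m in table]
    if not members:
        raise ValidationError(f"coefficient table covers no member of group {group}")
    rows = []
    for target in members:
        problem = build_problem(
            target, box, table,
            group=group if constrain_group else None,
            thresholds_source=thresholds_source if constrain_group else None,
            vip_weights=vip_weights,
        )
        result = solve_lp(problem)
        row = result.to_row()
        if result.status == "optimal":
            preds = dict(result.co_predictions)
            preds[target] = result.objective
            row[f"{group.lower()}_sum"] = float(sum(preds[m] for m in members))
        rows.append(row)
    return pd.DataFrame(rows)
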