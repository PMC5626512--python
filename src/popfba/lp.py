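"""Thin linear-programming layer with pluggable backends.

All flux computations reduce to LPs of the form

    optimize    c @ x
    subject to  A_eq @ x = b_eq,  A_ub @ x <= b_ub,  lb <= x <= ub.

The default backend is HiGHS via :func:`scipy.optimize.linprog`; a GLPK
backend (through optlang) is kept behind the same contract so solutions
can be cross-checked between two independent solvers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

__all__ = ["LPResult", "solve_lp", "BACKENDS"]

BACKENDS = ("highs", "glpk")


@dataclass
class LPResult:
    x: np.ndarray | None
    objective: float | None
    status: str  # "optimal" | "infeasible" | "unbounded" | "error"

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


def solve_lp(c, lb, ub, A_eq=None, b_eq=None, A_ub=None, b_ub=None,
             sense: str = "max", backend: str = "highs") -> LPResult:
    """Solve an LP; never raises on solver failure, reports status instead."""
    c = np.asarray(c, dtype=float)
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    if sense not in ("max", "min"):
        raise ValueError("sense must be 'max' or 'min'")
    if backend == "highs":
        return _solve_highs(c, lb, ub, A_eq, b_eq, A_ub, b_ub, sense)
    if backend == "glpk":
        return _solve_glpk(c, lb, ub, A_eq, b_eq, A_ub, b_ub, sense)
    raise ValueError(f"unknown LP backend {backend!r}; available: {BACKENDS}")


def _solve_highs(c, lb, ub, A_eq, b_eq, A_ub, b_ub, sense) -> LPResult:
    sign = -1.0 if sense == "max" else 1.0
    res = linprog(
        sign * c,
        A_eq=A_eq, b_eq=b_eq,
        A_ub=A_ub, b_ub=b_ub,
        bounds=np.column_stack([lb, ub]),
        method="highs",
    )
    if res.status == 0:
        return LPResult(res.x, float(c @ res.x), "optimal")
    status = {2: "infeasible", 3: "unbounded"}.get(res.status, "error")
    return LPResult(None, None, status)


def _solve_glpk(c, lb, ub, A_eq, b_eq, A_ub, b_ub, sense) -> LPResult:
    from optlang import glpk_interface as glpk

    n = len(c)
    xs = [glpk.Variable(f"x{i}", lb=float(lb[i]), ub=float(ub[i]))
          for i in range(n)]
    model = glpk.Model()
    constraints = []

    def add_rows(A, b, kind):
        if A is None:
            return
        A = sparse.csr_matrix(A)
        b = np.atleast_1d(np.asarray(b, dtype=float))
        for i in range(A.shape[0]):
            row = A.getrow(i)
            expr = sum(float(v) * xs[j] for j, v in zip(row.indices, row.data))
            if kind == "eq":
                constraints.append(glpk.Constraint(expr, lb=b[i], ub=b[i]))
            else:
                constraints.append(glpk.Constraint(expr, ub=b[i]))

    add_rows(A_eq, b_eq, "eq")
    add_rows(A_ub, b_ub, "ub")
    model.add(constraints)
    model.objective = glpk.Objective(
        sum(float(ci) * xi for ci, xi in zip(c, xs) if ci != 0.0),
        direction=sense,
    )
    status = model.optimize()
    if status != "optimal":
        return LPResult(None, None,
                        "infeasible" if status == "infeasible" else status)
    x = np.array([model.variables[f"x{i}"].primal for i in range(n)])
    return LPResult(x, float(c @ x), "optimal")
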