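"""Flux balance analysis for one constrained cell.

Plain FBA maximizes biomass flux subject to steady state (``S v = 0``)
and flux bounds; parsimonious FBA (pFBA) additionally minimizes the
total absolute flux while holding the objective at (a fraction of) its
optimum, modeling efficient enzyme usage; flux variability analysis
(FVA) reports the attainable range of every flux at a given optimality
fraction, optionally with the pFBA total flux pinned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from .constraints import DEFAULT_BOUND, CellConstraintSet, MetabolicModel
from .lp import solve_lp

__all__ = ["FluxSolution", "FVAResult", "fba", "pfba", "fva", "active_bounds",
           "apply_overrides"]

_GROWTH_PIN_TOL = 1e-9
_TOTAL_FLUX_SLACK = 1e-6


@dataclass
class FluxSolution:
    """One cell's flux state."""

    reaction_ids: list[str]
    fluxes: np.ndarray | None
    growth_rate: float
    status: str
    total_flux: float | None = None  # sum of |v|, set by pFBA

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def flux(self, reaction_id: str) -> float:
        return float(self.fluxes[self.reaction_ids.index(reaction_id)])

    def to_series(self) -> pd.Series:
        return pd.Series(self.fluxes, index=self.reaction_ids)


@dataclass
class FVAResult:
    """Per-reaction flux ranges at a given optimality fraction."""

    reaction_ids: list[str]
    minimum: np.ndarray
    maximum: np.ndarray
    fraction: float

    def range(self, reaction_id: str) -> tuple[float, float]:
        i = self.reaction_ids.index(reaction_id)
        return float(self.minimum[i]), float(self.maximum[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"reaction_id": self.reaction_ids,
                             "minimum": self.minimum,
                             "maximum": self.maximum}).set_index("reaction_id")


def apply_overrides(
    model: MetabolicModel,
    overrides: CellConstraintSet | None,
    symmetric: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Merge protein-derived capacities into the model's default bounds.

    A capacity tightens the upper bound (``ub = min(ub, vmax)``) and, for
    reversible reactions when ``symmetric`` (the default), the lower
    bound as well (``lb = max(lb, -vmax)``): the same enzyme pool carries
    flux in either direction.
    """
    lb, ub = model.lb.copy(), model.ub.copy()
    if overrides is not None:
        for rxn, vmax in overrides.overrides.items():
            i = model.index(rxn)
            ub[i] = min(ub[i], vmax)
            if symmetric:
                lb[i] = max(lb[i], -vmax)
            lb[i] = min(lb[i], ub[i])
    return lb, ub


def _infeasible(model: MetabolicModel, status: str) -> FluxSolution:
    return FluxSolution(list(model.reaction_ids), None, 0.0, status)


def fba(
    model: MetabolicModel,
    overrides: CellConstraintSet | None = None,
    symmetric_overrides: bool = True,
    backend: str = "highs",
) -> FluxSolution:
    """Maximize biomass flux subject to mass balance and bounds."""
    lb, ub = apply_overrides(model, overrides, symmetric_overrides)
    n = model.n_reactions
    c = np.zeros(n)
    c[model.index(model.biomass_id)] = 1.0
    res = solve_lp(c, lb, ub, A_eq=model.S, b_eq=np.zeros(model.S.shape[0]),
                   sense="max", backend=backend)
    if not res.optimal:
        return _infeasible(model, res.status)
    return FluxSolution(list(model.reaction_ids), res.x, float(res.objective),
                        "optimal", total_flux=float(np.abs(res.x).sum()))


def _split_parts(lb: np.ndarray, ub: np.ndarray):
    """Bounds for the forward/backward split ``v = f - r``, ``f, r >= 0``."""
    f_lb, f_ub = np.maximum(lb, 0.0), np.maximum(ub, 0.0)
    r_lb, r_ub = np.maximum(-ub, 0.0), np.maximum(-lb, 0.0)
    return f_lb, f_ub, r_lb, r_ub


def pfba(
    model: MetabolicModel,
    overrides: CellConstraintSet | None = None,
    optimality_fraction: float = 1.0,
    symmetric_overrides: bool = True,
    backend: str = "highs",
) -> FluxSolution:
    """Parsimonious FBA: minimal total flux at near-optimal growth.

    Stage 1 finds the optimal growth rate ``mu*``; stage 2 splits every
    reaction into non-negative forward/backward parts and minimizes their
    sum subject to ``biomass >= optimality_fraction * mu*`` (an
    inequality, with a small slack, to avoid numerical infeasibility at
    the vertex).
    """
    stage1 = fba(model, overrides, symmetric_overrides, backend)
    if not stage1.optimal:
        return stage1
    mu_star = stage1.growth_rate

    lb, ub = apply_overrides(model, overrides, symmetric_overrides)
    n = model.n_reactions
    f_lb, f_ub, r_lb, r_ub = _split_parts(lb, ub)
    A_eq = sparse.hstack([model.S, -model.S], format="csr")
    b_eq = np.zeros(model.S.shape[0])
    # growth pin: -(f_bio - r_bio) <= -(fraction * mu* - tol)
    pin = np.zeros(2 * n)
    i_bio = model.index(model.biomass_id)
    pin[i_bio], pin[n + i_bio] = -1.0, 1.0
    b_pin = -(optimality_fraction * mu_star - _GROWTH_PIN_TOL)
    res = solve_lp(
        np.ones(2 * n),
        np.concatenate([f_lb, r_lb]), np.concatenate([f_ub, r_ub]),
        A_eq=A_eq, b_eq=b_eq,
        A_ub=pin.reshape(1, -1), b_ub=[b_pin],
        sense="min", backend=backend,
    )
    if not res.optimal:
        return _infeasible(model, res.status)
    v = res.x[:n] - res.x[n:]
    return FluxSolution(list(model.reaction_ids), v, float(v[i_bio]),
                        "optimal", total_flux=float(res.objective))


def fva(
    model: MetabolicModel,
    overrides: CellConstraintSet | None = None,
    optimality_fraction: float = 1.0,
    pin_total_flux: float | None = None,
    reactions: list[str] | None = None,
    symmetric_overrides: bool = True,
    backend: str = "highs",
) -> FVAResult:
    """Per-reaction flux ranges at a growth-optimality fraction.

    With ``pin_total_flux`` the ranges are additionally restricted to
    flux states whose total absolute flux does not exceed the given pFBA
    total (plus a small slack), probing the robustness of the
    parsimonious solution itself.
    """
    stage1 = fba(model, overrides, symmetric_overrides, backend)
    if not stage1.optimal:
        raise RuntimeError(f"FVA requires a feasible model (status: {stage1.status})")
    mu_star = stage1.growth_rate
    lb, ub = apply_overrides(model, overrides, symmetric_overrides)
    n = model.n_reactions
    i_bio = model.index(model.biomass_id)
    rxns = reactions if reactions is not None else list(model.reaction_ids)

    if pin_total_flux is None:
        A_eq, b_eq = model.S, np.zeros(model.S.shape[0])
        pin = np.zeros(n)
        pin[i_bio] = -1.0
        A_ub, b_ub = pin.reshape(1, -1), [-(optimality_fraction * mu_star - _GROWTH_PIN_TOL)]
        width = n

        def objective(i):
            c = np.zeros(width)
            c[i] = 1.0
            return c
    else:
        f_lb, f_ub, r_lb, r_ub = _split_parts(lb, ub)
        lb = np.concatenate([f_lb, r_lb])
        ub = np.concatenate([f_ub, r_ub])
        A_eq = sparse.hstack([model.S, -model.S], format="csr")
        b_eq = np.zeros(model.S.shape[0])
        pin = np.zeros(2 * n)
        pin[i_bio], pin[n + i_bio] = -1.0, 1.0
        A_ub = np.vstack([pin, np.ones(2 * n)])
        b_ub = [-(optimality_fraction * mu_star - _GROWTH_PIN_TOL),
                pin_total_flux + _TOTAL_FLUX_SLACK]
        width = 2 * n

        def objective(i):
            c = np.zeros(width)
            c[i], c[n + i] = 1.0, -1.0
            return c

    lo = np.empty(len(rxns))
    hi = np.empty(len(rxns))
    for k, rxn in enumerate(rxns):
        i = model.index(rxn)
        c = objective(i)
        for sense, target in (("min", lo), ("max", hi)):
            res = solve_lp(c, lb, ub, A_eq=A_eq, b_eq=b_eq,
                           A_ub=A_ub, b_ub=b_ub, sense=sense, backend=backend)
            if not res.optimal:
                raise RuntimeError(f"FVA subproblem for {rxn!r} returned {res.status}")
            target[k] = res.objective
    # clip tiny solver noise so minimum <= maximum always holds
    swap = lo > hi
    lo[swap], hi[swap] = hi[swap], lo[swap]
    return FVAResult(list(rxns), lo, hi, optimality_fraction)


def active_bounds(
    sol: FluxSolution,
    overrides: CellConstraintSet,
    tol: float = 1e-6,
    default_bound: float = DEFAULT_BOUND,
) -> set[str]:
    """Reactions whose flux sits at their protein-derived capacity.

    Only genuinely constraining overrides count: a capacity at or above
    the default bound is a no-op and is ignored.
    """
    if not sol.optimal:
        raise ValueError("active_bounds requires an optimal solution")
    out = set()
    for rxn, vmax in overrides.overrides.items():
        if vmax >= default_bound:
            continue
        v = abs(sol.flux(rxn))
        if v >= (1.0 - tol) * vmax and vmax > 0:
            out.add(rxn)
    return out
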