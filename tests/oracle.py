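"""Brute-force LP oracles, independent of the package's solver path.

For networks with a handful of reactions the flux polytope
{v : S v = 0, lb <= v <= ub} has enumerable vertices: every vertex fixes
(n - rank(S)) fluxes at a bound and solves the balance equations for the
rest. FBA/pFBA/FVA answers can then be read off the vertex list directly
(for the irreversible fixtures used here the total flux is linear on the
optimal face, so its minimum is attained at a face vertex).
"""

import itertools

import numpy as np


def polytope_vertices(model, lb=None, ub=None, tol=1e-8):
    S = np.asarray(model.S.todense(), dtype=float)
    lb = model.lb if lb is None else lb
    ub = model.ub if ub is None else ub
    m, n = S.shape
    r = np.linalg.matrix_rank(S)
    vertices = []
    for free in itertools.combinations(range(n), n - r):
        basis = [j for j in range(n) if j not in free]
        SB = S[:, basis]
        for pattern in itertools.product(*[(lb[j], ub[j]) for j in free]):
            rhs = -S[:, list(free)] @ np.asarray(pattern)
            xB, *_ = np.linalg.lstsq(SB, rhs, rcond=None)
            x = np.zeros(n)
            x[list(free)] = pattern
            x[basis] = xB
            if np.abs(S @ x).max() > tol:
                continue
            if (x < lb - tol).any() or (x > ub + tol).any():
                continue
            if not any(np.abs(x - v).max() < 1e-6 for v in vertices):
                vertices.append(x)
    if not vertices:
        raise RuntimeError("no vertices found (infeasible or degenerate)")
    return vertices


def oracle_fba(model, lb=None, ub=None):
    """(mu*, optimal vertices) by exhaustive vertex enumeration."""
    i = model.index(model.biomass_id)
    verts = polytope_vertices(model, lb, ub)
    mu = max(v[i] for v in verts)
    best = [v for v in verts if v[i] >= mu - 1e-9]
    return mu, best

def oracle_pfba_total(model, lb=None, ub=None):
    """Minimal total absolute flux among optimal-growth vertices."""
    _, best = oracle_fba(model, lb, ub)
    return min(np.abs(v).sum() for v in best)


def oracle_fva(model, lb=None, ub=None, fraction=1.0):
    """Per-reaction flux ranges over the fraction-optimal face's vertices."""
    i = model.index(model.biomass_id)
    verts = polytope_vertices(model, lb, ub)
    mu = max(v[i] for v in verts)
    face = [v for v in verts if v[i] >= fraction * mu - 1e-9]
    V = np.array(face)
    return V.min(axis=0), V.max(axis=0)
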