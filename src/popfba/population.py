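"""Whole-population simulation and heterogeneity analytics.

Every sampled cell is an independent FBA problem: its protein counts set
enzyme-capacity bounds, and parsimonious FBA yields its growth rate and
flux vector. The resulting population is summarized by growth-rate
histograms, PCA of growth-normalized fluxes (growth-independent pathway
usage), mean-flux comparisons against reference fluxomics, and
saturation statistics of uptake bounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .constraints import (KcatTable, MediumSpec, MetabolicModel, UnitConstants,
                          apply_medium_and_knockouts, build_cell_bounds)
from .fba import active_bounds, pfba
from .sampling import CellCounts

__all__ = [
    "PopulationResult",
    "Histogram",
    "PhenotypeSummary",
    "UptakeClassification",
    "simulate_population",
    "growth_histogram",
    "flux_pca",
    "compare_fluxes",
    "bound_uptake_fraction",
]

logger = logging.getLogger(__name__)


@dataclass
class PopulationResult:
    """Per-cell growth rates and fluxes for one simulated population.

    Infeasible cells are flagged, never dropped: their rows stay aligned
    with the sampled count matrix.
    """

    reaction_ids: list[str]
    growth_rates: np.ndarray          # (n_cells,), hr^-1; 0 for infeasible
    fluxes: np.ndarray                # (n_cells, n_reactions)
    feasible: np.ndarray              # (n_cells,) bool
    counts: CellCounts | None = None
    active: list[set[str]] = field(default_factory=list)  # per-cell bound-active reactions
    seed: int | None = None

    @property
    def n_cells(self) -> int:
        return len(self.growth_rates)

    @property
    def n_feasible(self) -> int:
        return int(self.feasible.sum())

    def flux_column(self, reaction_id: str) -> np.ndarray:
        return self.fluxes[:, self.reaction_ids.index(reaction_id)]

    def growth_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"growth_rate": self.growth_rates,
                             "feasible": self.feasible})


def simulate_population(
    model: MetabolicModel,
    samples: CellCounts,
    kcats: KcatTable,
    medium: MediumSpec | None = None,
    knockouts: Iterable[str] = (),
    units: UnitConstants | None = None,
    optimality_fraction: float = 1.0,
    track_active: bool = False,
) -> PopulationResult:
    """Run pFBA for every sampled cell.

    The medium and knockouts are applied once; each cell then gets its
    own capacity overrides from its count vector. Deterministic given the
    sampled counts.
    """
    units = units or UnitConstants()
    if medium is not None or knockouts:
        model = apply_medium_and_knockouts(model, medium or MediumSpec(), knockouts)
    n = samples.n_cells
    mu = np.zeros(n)
    fluxes = np.zeros((n, model.n_reactions))
    feasible = np.zeros(n, dtype=bool)
    actives: list[set[str]] = []
    for i in range(n):
        counts = dict(zip(samples.protein_ids, samples.values[i]))
        cs = build_cell_bounds(model, counts, kcats, units)
        sol = pfba(model, cs, optimality_fraction)
        if sol.optimal:
            mu[i] = sol.growth_rate
            fluxes[i] = sol.fluxes
            feasible[i] = True
            if track_active:
                actives.append(active_bounds(sol, cs))
        elif track_active:
            actives.append(set())
    n_bad = n - int(feasible.sum())
    if n_bad:
        logger.info("simulate_population: %d of %d cells infeasible", n_bad, n)
    return PopulationResult(list(model.reaction_ids), mu, fluxes, feasible,
                            counts=samples, active=actives, seed=samples.seed)


@dataclass
class Histogram:
    """Density-normalized histogram (integrates to 1 over its range)."""

    density: np.ndarray
    edges: np.ndarray

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def probabilities(self) -> np.ndarray:
        return self.density * np.diff(self.edges)


def growth_histogram(
    result: PopulationResult,
    nbins: int = 50,
    range: tuple[float, float] = (0.0, 0.7),
    include_infeasible: bool = False,
) -> Histogram:
    """Growth-rate distribution of the population.

    Infeasible cells are excluded by default (with a logged count); with
    ``include_infeasible`` they enter at growth rate 0.
    """
    if include_infeasible:
        mu = result.growth_rates
    else:
        mu = result.growth_rates[result.feasible]
        n_bad = result.n_cells - result.n_feasible
        if n_bad:
            logger.info("growth_histogram: excluding %d infeasible cells", n_bad)
    if mu.size == 0:
        raise ValueError("no feasible cells to histogram")
    density, edges = np.histogram(mu, bins=nbins, range=range, density=True)
    return Histogram(density, edges)


@dataclass
class PhenotypeSummary:
    """PCA of growth-normalized fluxes plus population flux statistics."""

    reaction_ids: list[str]           # columns retained (non-zero variance)
    loadings: np.ndarray              # (n_components, len(reaction_ids))
    explained_variance: np.ndarray    # fractions, non-increasing
    scores: np.ndarray                # (n_cells_used, n_components)
    cell_indices: np.ndarray          # indices of the sampled cells

    def top_loadings(self, component: int, k: int = 5) -> list[tuple[str, float]]:
        w = self.loadings[component]
        order = np.argsort(-np.abs(w))[:k]
        return [(self.reaction_ids[i], float(w[i])) for i in order]


def flux_pca(
    result: PopulationResult,
    n_cells: int = 1000,
    seed: int = 0,
    n_components: int | None = None,
) -> PhenotypeSummary:
    """Principal components of growth-normalized fluxes.

    A random subset of feasible cells is drawn (seeded), each cell's flux
    vector is divided by its growth rate to remove the overall scale of
    metabolism, zero-variance reactions are dropped, and PCA runs on the
    centered (not rescaled) matrix, so components reflect absolute flux
    reallocation between pathways.
    """
    from sklearn.decomposition import PCA

    ok = np.flatnonzero(result.feasible & (result.growth_rates > 0))
    if ok.size < n_cells:
        raise ValueError(f"need at least {n_cells} feasible growing cells, "
                         f"have {ok.size}")
    rng = np.random.Generator(np.random.Philox(key=seed))
    chosen = rng.choice(ok, size=n_cells, replace=False)
    X = result.fluxes[chosen] / result.growth_rates[chosen, None]
    # constant up to solver jitter counts as zero-variance
    scale = 1.0 + np.abs(X.mean(axis=0))
    keep = np.flatnonzero(X.std(axis=0) > 1e-9 * scale)
    rxn_ids = [result.reaction_ids[i] for i in keep]
    if keep.size == 0:
        return PhenotypeSummary([], np.zeros((0, 0)), np.zeros(0),
                                np.zeros((n_cells, 0)), chosen)
    X = X[:, keep]
    k = n_components or min(10, keep.size, n_cells)
    pca = PCA(n_components=k)
    scores = pca.fit_transform(X)
    return PhenotypeSummary(rxn_ids, pca.components_,
                            pca.explained_variance_ratio_, scores, chosen)


def compare_fluxes(
    result: PopulationResult,
    reference: Mapping[str, float],
) -> tuple[dict[str, float], float]:
    """Population mean fluxes vs a reference flux map, with their RMSD.

    ``RMSD = sqrt(mean over referenced reactions of (mean flux - ref)^2)``.
    """
    missing = [r for r in reference if r not in result.reaction_ids]
    if missing:
        raise ValueError(f"reference reaction(s) not in model: {missing}")
    ok = result.feasible
    if not ok.any():
        raise ValueError("no feasible cells")
    means = {r: float(result.flux_column(r)[ok].mean()) for r in reference}
    sq = [(means[r] - reference[r]) ** 2 for r in reference]
    return means, float(np.sqrt(np.mean(sq)))


@dataclass
class UptakeClassification:
    fraction_at_max: float
    fraction_basal: float
    bimodal: bool


def bound_uptake_fraction(
    result: PopulationResult,
    exchange_id: str,
    medium: MediumSpec,
    tol: float = 1e-3,
    basal_threshold: float = 0.1,
    min_fraction: float = 0.05,
    middle_max: float = 0.05,
) -> UptakeClassification:
    """Classify cells by how hard they use one uptake bound.

    Cells at >= ``(1 - tol)`` of the medium maximum count as saturated;
    cells at <= ``basal_threshold`` of the maximum count as basal. The
    population is flagged bimodal when both groups exceed
    ``min_fraction`` and the in-between fraction stays below
    ``middle_max`` — the either/or uptake signature.
    """
    if exchange_id not in medium:
        raise ValueError(f"exchange {exchange_id!r} not part of the medium")
    cap = float(medium[exchange_id])
    if cap <= 0:
        raise ValueError(f"exchange {exchange_id!r} has zero uptake capacity")
    uptake = np.maximum(0.0, -result.flux_column(exchange_id)[result.feasible])
    if uptake.size == 0:
        raise ValueError("no feasible cells")
    at_max = float(np.mean(uptake >= (1.0 - tol) * cap))
    basal = float(np.mean(uptake <= basal_threshold * cap))
    middle = max(0.0, 1.0 - at_max - basal)
    bimodal = at_max >= min_fraction and basal >= min_fraction and middle <= middle_max
    return UptakeClassification(at_max, basal, bimodal)
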