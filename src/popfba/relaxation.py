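"""Repair of overly-constraining turnover numbers.

Literature kcat values are noisy: imposing every measured enzyme
capacity as sampled can choke growth far below what is observed in bulk
culture. Two relaxation strategies are implemented. The deterministic
*doubling procedure* repeatedly simulates a small batch of cells, finds
the reaction whose capacity binds most often, and doubles the kcat of
the responsible enzyme until the batch mean growth rate reaches the
experimental value. The *micro genetic algorithm* instead searches over
binary choices — keep a curated kcat or lift it to the maximal wild-type
yeast value of 38,000 s^-1 — scoring each choice set by how well the
resulting growth-rate distribution matches a target histogram.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .constraints import (DEFAULT_KCAT, KcatTable, MediumSpec, MetabolicModel,
                          UnitConstants)
from .gpr import And, Gene, GPRExpr
from .population import simulate_population
from .proteomics import CalibrationModel, ProteinMarginal
from .sampling import CorrelationModel, sample_population

__all__ = [
    "DoublingEvent",
    "DoublingLog",
    "GAGenome",
    "GAConfig",
    "GAResult",
    "PopulationContext",
    "harmonize_complex_kcats",
    "doubling_procedure",
    "apply_genome",
    "genome_fitness",
    "microga_select",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DoublingEvent:
    """One doubling step: all listed genes had their kcat doubled together."""

    iteration: int
    reaction_id: str
    genes: tuple[str, ...]
    old_kcats: tuple[float, ...]
    new_kcats: tuple[float, ...]
    batch_mean_growth: float

    def __post_init__(self) -> None:
        for old, new in zip(self.old_kcats, self.new_kcats):
            if abs(new - 2.0 * old) > 1e-9 * max(1.0, abs(new)):
                raise ValueError("doubling event must exactly double each kcat")


@dataclass
class DoublingLog:
    events: list[DoublingEvent] = field(default_factory=list)
    final_mean_growth: float = 0.0

    @property
    def n_doublings(self) -> int:
        return len(self.events)

    @property
    def genes_affected(self) -> set[str]:
        return {g for e in self.events for g in e.genes}

    def replay(self, initial: KcatTable) -> KcatTable:
        """Re-apply the logged doublings to a fresh copy of the initial table."""
        table = initial.copy()
        doubled: dict[str, int] = {}
        for e in self.events:
            for g in e.genes:
                doubled[g] = doubled.get(g, 0) + 1
                table.set(g, table.kcat(g) * 2.0, f"doubled x{doubled[g]}")
        return table


def _and_groups(expr: GPRExpr) -> list[list[str]]:
    """Maximal AND-connected gene groups (protein complexes) in a GPR tree."""
    if isinstance(expr, Gene):
        return []
    if isinstance(expr, And):
        # every gene below an AND node belongs to one complex
        return [expr.genes()]
    groups = []
    for child in expr.children:  # type: ignore[attr-defined]
        groups.extend(_and_groups(child))
    return groups


def harmonize_complex_kcats(kcats: KcatTable, model: MetabolicModel) -> KcatTable:
    """Raise every complex subunit's kcat to the maximum within its complex.

    A complex turns over as one unit, so a subunit with a lower reported
    kcat than its partners most likely reflects a measurement gap, not a
    slower subunit. Applied transitively until a fixpoint, so a gene
    shared by two complexes propagates the larger maximum.
    """
    table = kcats.copy()
    groups: list[list[str]] = []
    for expr in model.gpr.values():
        if expr is not None:
            groups.extend(_and_groups(expr))
    changed = True
    while changed:
        changed = False
        for group in groups:
            mx = max(table.kcat(g) for g in group)
            for g in group:
                if table.kcat(g) < mx:
                    table.set(g, mx, "complex-harmonized")
                    changed = True
    return table


@dataclass
class PopulationContext:
    """Everything needed to simulate a population for a given kcat table."""

    model: MetabolicModel
    marginals: Sequence[ProteinMarginal]
    corr: CorrelationModel | None
    cal: CalibrationModel
    kcats: KcatTable
    medium: MediumSpec | None = None
    knockouts: tuple[str, ...] = ()
    units: UnitConstants = field(default_factory=UnitConstants)

    def simulate(self, n_cells: int, seed: int, kcats: KcatTable | None = None,
                 track_active: bool = False):
        samples = sample_population(n_cells, self.marginals, self.corr,
                                    self.cal, seed)
        return simulate_population(
            self.model, samples, kcats if kcats is not None else self.kcats,
            self.medium, self.knockouts, self.units, track_active=track_active)


def _genes_to_double(expr: GPRExpr, mean_count: dict[str, float]) -> tuple[str, ...]:
    """Which gene(s) to double for a binding reaction.

    Isozymes (OR): only the isozyme with the highest mean copy number —
    it dominates the capacity sum. Complexes (AND): every subunit, since
    the complex turns over as a unit.
    """
    if isinstance(expr, Gene):
        return (expr.name,)
    if isinstance(expr, And):
        return tuple(expr.genes())
    # OR node: descend into the branch with the largest effective mean count
    def branch_count(child: GPRExpr) -> float:
        v = child.combine_counts(mean_count)
        return v if v is not None else -np.inf

    best = max(expr.children, key=branch_count)  # type: ignore[attr-defined]
    return _genes_to_double(best, mean_count)


def doubling_procedure(
    model: MetabolicModel,
    marginals: Sequence[ProteinMarginal],
    corr: CorrelationModel | None,
    cal: CalibrationModel,
    kcats: KcatTable,
    medium: MediumSpec | None,
    target_mean_growth: float,
    batch_size: int = 400,
    seed: int = 0,
    knockouts: Iterable[str] = (),
    max_iterations: int = 1000,
    units: UnitConstants | None = None,
) -> tuple[KcatTable, DoublingLog]:
    """Iteratively double the kcat behind the most-often-binding reaction.

    Each iteration simulates a fresh seeded batch (seed + iteration, so
    the stopping rule is not fit to one fixed population), tallies which
    protein-derived bounds the cells' fluxes sit on, and doubles the kcat
    of the enzyme behind the most frequently binding reaction (ties break
    to the lexicographically smallest reaction id). Stops once the batch
    mean growth rate reaches ``target_mean_growth``.
    """
    if not target_mean_growth > 0:
        raise ValueError("target_mean_growth must be positive")
    ctx = PopulationContext(model, marginals, corr, cal, kcats.copy(),
                            medium, tuple(knockouts),
                            units or UnitConstants())
    # mean copy number proxy: calibration applied to the marginal mean
    mean_count = {m.protein_id: float(cal.convert(m.mean)) for m in marginals}
    log = DoublingLog()
    table = ctx.kcats
    for it in range(max_iterations):
        result = ctx.simulate(batch_size, seed + it, kcats=table,
                              track_active=True)
        mean_mu = float(result.growth_rates[result.feasible].mean()) \
            if result.feasible.any() else 0.0
        log.final_mean_growth = mean_mu
        if mean_mu >= target_mean_growth:
            return table, log
        tally: dict[str, int] = {}
        for cell_active in result.active:
            for rxn in cell_active:
                tally[rxn] = tally.get(rxn, 0) + 1
        if not tally:
            raise RuntimeError(
                "doubling_procedure: mean growth "
                f"{mean_mu:.4f} < target {target_mean_growth:.4f} but no "
                "protein-derived bound is ever active — growth is limited "
                "by the medium, not by proteins")
        # tie-break: highest count, then lexicographically smallest id
        top = max(tally.values())
        best = min(r for r, n in tally.items() if n == top)
        genes = _genes_to_double(model.gpr[best], mean_count)
        old = tuple(table.kcat(g) for g in genes)
        for g in genes:
            table.set(g, table.kcat(g) * 2.0, "doubled")
        log.events.append(DoublingEvent(
            iteration=it, reaction_id=best, genes=genes,
            old_kcats=old, new_kcats=tuple(2.0 * v for v in old),
            batch_mean_growth=mean_mu))
    raise RuntimeError(
        f"doubling_procedure: iteration cap {max_iterations} exceeded "
        f"({log.n_doublings} doublings performed, mean growth "
        f"{log.final_mean_growth:.4f} < target {target_mean_growth:.4f})")


# ---------------------------------------------------------------------------
# Micro genetic algorithm

@dataclass
class GAGenome:
    """Binary choice per candidate gene: 0 keep curated kcat, 1 lift to 38,000 s^-1."""

    bits: tuple[int, ...]
    fitness: float | None = None

    @property
    def lifted(self) -> int:
        return int(sum(self.bits))


@dataclass
class GAConfig:
    population_size: int = 10
    cells_per_eval: int = 100
    bins: int = 50
    range: tuple[float, float] = (0.0, 0.7)
    max_generations: int = 200
    restart_similarity: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 5:
            raise ValueError("GA population size must be at least 5")
        if self.bins < 10:
            raise ValueError("GA histogram needs at least 10 bins")


@dataclass
class GAResult:
    best: GAGenome
    trace: list[float]
    population: list[GAGenome]
    hit_generation_cap: bool


def apply_genome(
    kcats: KcatTable,
    genome: GAGenome,
    candidate_genes: Sequence[str],
    lifted_kcat: float = DEFAULT_KCAT,
) -> KcatTable:
    """Materialize a genome: lift the selected genes' kcats."""
    if len(genome.bits) != len(candidate_genes):
        raise ValueError("genome length does not match candidate gene list")
    table = kcats.copy()
    for bit, gene in zip(genome.bits, candidate_genes):
        if bit:
            table.set(gene, lifted_kcat, "lifted-38000")
    return table


def growth_probabilities(mu: np.ndarray, cfg: GAConfig) -> np.ndarray:
    """Normalized bin probabilities of a growth-rate sample.

    Normalization is by the total cell count, so mass falling outside the
    histogram range is penalized rather than renormalized away.
    """
    counts, _ = np.histogram(mu, bins=cfg.bins, range=cfg.range)
    return counts / max(1, len(mu))


def genome_fitness(
    genome: GAGenome,
    context: PopulationContext,
    target_hist: np.ndarray,
    cfg: GAConfig,
    candidate_genes: Sequence[str],
) -> float:
    """Goodness-of-fit of a genome's growth-rate distribution.

    Simulates ``cfg.cells_per_eval`` cells under the genome's kcat table
    (same seed for every genome, so comparisons are paired) and returns
    the negative sum of squared bin-probability differences against the
    target histogram; higher is better, and an all-infeasible population
    scores ``-inf``.
    """
    target_hist = np.asarray(target_hist, dtype=float)
    if target_hist.shape != (cfg.bins,):
        raise ValueError("target histogram length must equal cfg.bins")
    table = apply_genome(context.kcats, genome, candidate_genes)
    result = context.simulate(cfg.cells_per_eval, cfg.seed, kcats=table)
    if not result.feasible.any():
        return -np.inf
    p = growth_probabilities(result.growth_rates[result.feasible], cfg)
    return -float(np.sum((p - target_hist) ** 2))


def microga_select(
    context: PopulationContext,
    target_hist: np.ndarray,
    cfg: GAConfig,
    candidate_genes: Sequence[str] | None = None,
) -> GAResult:
    """Micro-GA over kcat lift choices.

    Small population, elitism (the best genome survives unchanged, so the
    elite fitness trace is non-decreasing), binary tournament selection
    biased by fitness, uniform crossover, no mutation; when the
    population's mean bit-similarity to the elite reaches
    ``restart_similarity`` the non-elite genomes are re-randomized around
    the preserved elite.
    """
    if candidate_genes is None:
        candidate_genes = context.kcats.genes()
    candidate_genes = list(candidate_genes)
    n_genes = len(candidate_genes)
    if n_genes == 0:
        raise ValueError("no candidate genes for the micro-GA")
    rng = np.random.Generator(np.random.Philox(key=cfg.seed))
    cache: dict[tuple[int, ...], float] = {}

    def fitness(bits: tuple[int, ...]) -> float:
        if bits not in cache:
            cache[bits] = genome_fitness(GAGenome(bits), context, target_hist,
                                         cfg, candidate_genes)
        return cache[bits]

    def random_bits() -> tuple[int, ...]:
        return tuple(int(b) for b in rng.integers(0, 2, size=n_genes))

    population = [GAGenome(random_bits()) for _ in range(cfg.population_size)]
    for g in population:
        g.fitness = fitness(g.bits)
    trace: list[float] = []
    hit_cap = True
    for _gen in range(cfg.max_generations):
        population.sort(key=lambda g: g.fitness, reverse=True)
        elite = population[0]
        trace.append(elite.fitness)

        # convergence-triggered restart around the elite
        elite_bits = np.array(elite.bits)
        sim = np.mean([np.mean(np.array(g.bits) == elite_bits)
                       for g in population[1:]])
        if sim >= cfg.restart_similarity:
            population = [elite] + [GAGenome(random_bits())
                                    for _ in range(cfg.population_size - 1)]
            for g in population[1:]:
                g.fitness = fitness(g.bits)
            continue

        def tournament() -> GAGenome:
            i, j = rng.integers(0, cfg.population_size, size=2)
            a, b = population[i], population[j]
            return a if a.fitness >= b.fitness else b

        children = [elite]
        while len(children) < cfg.population_size:
            mother, father = tournament(), tournament()
            mask = rng.integers(0, 2, size=n_genes)
            bits = tuple(int(x) if m else int(y)
                         for m, x, y in zip(mask, mother.bits, father.bits))
            children.append(GAGenome(bits, fitness(bits)))
        population = children
    population.sort(key=lambda g: g.fitness, reverse=True)
    best = population[0]
    if trace and best.fitness < max(trace):
        # elitism guarantees this cannot happen; guard for bookkeeping
        logger.warning("micro-GA: final best below recorded elite")
    return GAResult(best, trace, population, hit_cap)
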