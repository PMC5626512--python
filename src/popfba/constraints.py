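"""Metabolic model container and per-cell enzyme-capacity constraints.

One sampled cell is a vector of protein copy numbers. Paired with
turnover numbers (kcat) and a unit conversion, every copy number becomes
an enzyme capacity ``v_max = N_copy * k_cat * c`` in flux units
(mmol gDwt^-1 hr^-1), and GPR rules combine per-gene capacities into
per-reaction flux bounds. This module holds the model data structure,
kcat selection, medium and knockout handling, and the translation of one
cell's counts into a constraint set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from .gpr import GPRExpr, parse_gpr

__all__ = [
    "UnitConstants",
    "MetabolicModel",
    "KcatRecord",
    "KcatTable",
    "MediumSpec",
    "CellConstraintSet",
    "select_kcat",
    "protein_vmax",
    "evaluate_gpr",
    "apply_medium_and_knockouts",
    "build_cell_bounds",
    "minimal_kcat",
    "DEFAULT_BOUND",
    "DEFAULT_KCAT",
]

#: Flux bound (mmol gDwt^-1 hr^-1) used for reactions without an
#: effective enzyme-capacity constraint.
DEFAULT_BOUND = 1000.0

#: Fallback turnover number (s^-1) for enzymes with no curated value:
#: the largest kcat reported for a wild-type yeast enzyme.
DEFAULT_KCAT = 38_000.0


@dataclass(frozen=True)
class UnitConstants:
    """Constants converting copies/cell * s^-1 to mmol gDwt^-1 hr^-1."""

    seconds_per_hour: float = 3600.0
    cell_dry_mass: float = 2.0e-11  # g per haploid yeast cell
    particles_per_mmol: float = 6.02e20

    @property
    def c(self) -> float:
        """Conversion factor, approximately 3.0e-7 s cell^-1 mmol gDwt^-1 hr^-1."""
        return self.seconds_per_hour / (self.cell_dry_mass * self.particles_per_mmol)


@dataclass
class MetabolicModel:
    """Stoichiometric model with bounds, GPR rules and a biomass objective.

    ``S`` is metabolites x reactions. Exchange reactions follow the SBML
    sign convention: uptake is a negative flux.
    """

    reaction_ids: list[str]
    metabolite_ids: list[str]
    S: sparse.csc_matrix
    lb: np.ndarray
    ub: np.ndarray
    gpr: dict[str, GPRExpr | None]
    gene_ids: list[str]
    biomass_id: str
    exchange_ids: set[str] = field(default_factory=set)
    name: str = "model"

    def __post_init__(self) -> None:
        self.lb = np.asarray(self.lb, dtype=float)
        self.ub = np.asarray(self.ub, dtype=float)
        n_met, n_rxn = self.S.shape
        if n_rxn != len(self.reaction_ids) or n_met != len(self.metabolite_ids):
            raise ValueError("stoichiometric matrix shape inconsistent with ids")
        if len(self.lb) != n_rxn or len(self.ub) != n_rxn:
            raise ValueError("bound vectors inconsistent with reaction count")
        if (self.lb > self.ub).any():
            bad = self.reaction_ids[int(np.argmax(self.lb > self.ub))]
            raise ValueError(f"lb > ub for reaction {bad!r}")
        if self.biomass_id not in self.reaction_ids:
            raise ValueError(f"biomass reaction {self.biomass_id!r} not in model")
        self._index = {r: i for i, r in enumerate(self.reaction_ids)}
        gene_set = set(self.gene_ids)
        for rxn, expr in self.gpr.items():
            if expr is None:
                continue
            unknown = [g for g in expr.genes() if g not in gene_set]
            if unknown:
                raise ValueError(
                    f"GPR of {rxn!r} references unknown gene(s): {unknown}")

    def index(self, reaction_id: str) -> int:
        return self._index[reaction_id]

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            reaction_ids=list(self.reaction_ids),
            metabolite_ids=list(self.metabolite_ids),
            S=self.S.copy(),
            lb=self.lb.copy(),
            ub=self.ub.copy(),
            gpr=dict(self.gpr),
            gene_ids=list(self.gene_ids),
            biomass_id=self.biomass_id,
            exchange_ids=set(self.exchange_ids),
            name=self.name,
        )

    def reactions_for_gene(self, gene: str) -> list[str]:
        return [r for r, expr in self.gpr.items()
                if expr is not None and gene in expr.genes()]


@dataclass(frozen=True)
class KcatRecord:
    """One literature turnover-number measurement for a gene product."""

    value: float
    organism: str = ""
    wild_type: bool = False

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValueError(f"kcat must be positive, got {self.value}")

    @property
    def is_wild_type_sc(self) -> bool:
        org = self.organism.lower()
        return self.wild_type and ("cerevisiae" in org or org in ("sc", "s.c."))


class KcatTable:
    """Per-gene turnover numbers (s^-1) with provenance tags.

    Genes without an entry fall back to ``default_kcat``, the least
    constraining choice for an unparameterized enzyme.
    """

    def __init__(self, values: Mapping[str, float] | None = None,
                 provenance: Mapping[str, str] | None = None,
                 default_kcat: float = DEFAULT_KCAT):
        self._values: dict[str, float] = {}
        self._prov: dict[str, str] = {}
        self.default_kcat = float(default_kcat)
        for g, v in (values or {}).items():
            self.set(g, v, (provenance or {}).get(g, "curated"))

    def set(self, gene: str, value: float, provenance: str = "curated") -> None:
        if not value > 0:
            raise ValueError(f"kcat for {gene!r} must be positive, got {value}")
        self._values[gene] = float(value)
        self._prov[gene] = provenance

    def kcat(self, gene: str) -> float:
        return self._values.get(gene, self.default_kcat)

    def provenance(self, gene: str) -> str:
        return self._prov.get(gene, "default")

    def __contains__(self, gene: str) -> bool:
        return gene in self._values

    def genes(self) -> list[str]:
        return list(self._values)

    def copy(self) -> "KcatTable":
        return KcatTable(dict(self._values), dict(self._prov), self.default_kcat)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(g, self._values[g], self._prov[g]) for g in sorted(self._values)],
            columns=["gene", "kcat", "provenance"],
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_records(cls, path) -> "KcatTable":
        """Build a table from a TSV of candidate measurements.

        Expects columns ``gene, kcat, organism, wild_type``; applies the
        wild-type-S. cerevisiae-first selection rule of :func:`select_kcat`.
        """
        df = pd.read_csv(path, sep="\t")
        recs: dict[str, list[KcatRecord]] = {}
        for r in df.itertuples(index=False):
            recs.setdefault(str(r.gene), []).append(
                KcatRecord(float(r.kcat), str(r.organism), bool(r.wild_type)))
        return select_kcat(recs)


def select_kcat(
    records: Mapping[str, Sequence[KcatRecord]],
    genes: Iterable[str] | None = None,
    default_kcat: float = DEFAULT_KCAT,
) -> KcatTable:
    """Choose one turnover number per gene from candidate measurements.

    Preference order: the largest value measured for a wild-type
    S. cerevisiae enzyme; failing that, the largest value from any mutant
    or other species; failing that, ``default_kcat``. The selection
    deliberately errs toward large values so enzyme-capacity constraints
    are minimally restrictive.
    """
    table = KcatTable(default_kcat=default_kcat)
    for gene, recs in records.items():
        if not recs:
            continue
        wt_sc = [r.value for r in recs if r.is_wild_type_sc]
        if wt_sc:
            table.set(gene, max(wt_sc), "wild-type-Sc")
        else:
            table.set(gene, max(r.value for r in recs), "other")
    if genes is not None:
        for g in genes:
            if g not in table:
                table.set(g, default_kcat, "default")
    return table


def protein_vmax(count: float, kcat: float, units: UnitConstants | None = None) -> float:
    """Enzyme capacity in flux units: ``count * kcat * c``."""
    if count < 0:
        raise ValueError("protein count must be non-negative")
    if not kcat > 0:
        raise ValueError("kcat must be positive")
    units = units or UnitConstants()
    return count * kcat * units.c


def evaluate_gpr(
    expr: GPRExpr | str,
    vmax_by_gene: Mapping[str, float],
    default_bound: float = DEFAULT_BOUND,
) -> float:
    """Effective reaction capacity from per-gene capacities.

    AND takes the minimum over measured subunits; OR sums isozymes unless
    any isozyme is unmeasured, in which case the reaction stays at
    ``default_bound``; a rule with no measured gene also returns
    ``default_bound``.
    """
    if isinstance(expr, str):
        expr = parse_gpr(expr)
    v = expr.evaluate_vmax(vmax_by_gene, default_bound)
    return default_bound if v is None else v


class MediumSpec(dict):
    """Maximum uptake magnitudes per exchange reaction (mmol gDwt^-1 hr^-1).

    Exchanges not listed are closed for uptake; secretion is left
    unconstrained.
    """

    def __init__(self, uptakes: Mapping[str, float] | None = None):
        super().__init__(uptakes or {})
        for rxn, mag in self.items():
            if mag < 0:
                raise ValueError(f"uptake magnitude for {rxn!r} must be >= 0")

    @classmethod
    def from_tsv(cls, path) -> "MediumSpec":
        df = pd.read_csv(path, sep="\t")
        return cls(dict(zip(df["exchange_id"].astype(str), df["max_uptake"].astype(float))))

    def to_tsv(self, path) -> None:
        pd.DataFrame(sorted(self.items()), columns=["exchange_id", "max_uptake"]
                     ).to_csv(path, sep="\t", index=False)


def apply_medium_and_knockouts(
    model: MetabolicModel,
    medium: MediumSpec,
    knockouts: Iterable[str] = (),
) -> MetabolicModel:
    """Impose a growth medium and gene deletions on a model copy.

    Uptake lower bounds of listed exchanges become ``-magnitude``; all
    other exchanges are closed for uptake (secretion untouched).
    Reactions whose GPR evaluates to false with the knocked-out genes
    absent are fixed to zero flux.
    """
    knockouts = set(knockouts)
    unknown_genes = knockouts - set(model.gene_ids)
    if unknown_genes:
        raise ValueError(f"knockout gene(s) not in model: {sorted(unknown_genes)}")
    unknown_ex = set(medium) - set(model.exchange_ids)
    if unknown_ex:
        raise ValueError(f"medium lists unknown exchange reaction(s): {sorted(unknown_ex)}")

    out = model.copy()
    for rxn in out.exchange_ids:
        i = out.index(rxn)
        if rxn in medium:
            out.lb[i] = -float(medium[rxn])
        else:
            out.lb[i] = max(out.lb[i], 0.0)
    for rxn, expr in out.gpr.items():
        if expr is None or not knockouts & set(expr.genes()):
            continue
        if not expr.evaluate_bool(lambda g: g not in knockouts):
            i = out.index(rxn)
            out.lb[i] = 0.0
            out.ub[i] = 0.0
    return out


@dataclass
class CellConstraintSet:
    """One cell's protein-derived reaction capacities with provenance.

    ``overrides`` maps reaction id to ``v_max``; ``provenance`` records
    which measured genes produced each bound.
    """

    overrides: dict[str, float] = field(default_factory=dict)
    provenance: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rxn, v in self.overrides.items():
            if v < 0:
                raise ValueError(f"negative v_max override for {rxn!r}")

    def __len__(self) -> int:
        return len(self.overrides)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r, self.overrides[r], ";".join(self.provenance.get(r, ())))
             for r in sorted(self.overrides)],
            columns=["reaction_id", "vmax", "genes"],
        )


def build_cell_bounds(
    model: MetabolicModel,
    counts: Mapping[str, float],
    kcats: KcatTable,
    units: UnitConstants | None = None,
    default_bound: float = DEFAULT_BOUND,
) -> CellConstraintSet:
    """Translate one cell's protein counts into reaction capacity overrides.

    Every reaction whose GPR references at least one measured gene gets an
    override from :func:`evaluate_gpr`. An enzyme catalyzing several
    reactions contributes its full copy number to each of them — copies
    are not partitioned across reactions or compartments.
    """
    units = units or UnitConstants()
    vmax_by_gene = {g: protein_vmax(n, kcats.kcat(g), units)
                    for g, n in counts.items()}
    cs = CellConstraintSet()
    for rxn, expr in model.gpr.items():
        if expr is None:
            continue
        measured = [g for g in expr.genes() if g in vmax_by_gene]
        if not measured:
            continue
        cs.overrides[rxn] = evaluate_gpr(expr, vmax_by_gene, default_bound)
        cs.provenance[rxn] = tuple(measured)
    return cs


def minimal_kcat(
    flux: float,
    counts: Mapping[str, float],
    expr: GPRExpr | str,
    units: UnitConstants | None = None,
) -> float:
    """Smallest turnover number consistent with a measured flux.

    Divides the flux by the GPR-effective copy number (sum over isozymes,
    minimum over complex subunits) times the unit conversion: the kcat an
    enzyme would need for its mean abundance to sustain the flux.
    """
    if isinstance(expr, str):
        expr = parse_gpr(expr)
    units = units or UnitConstants()
    eff = expr.combine_counts(counts)
    if eff is None or eff <= 0:
        raise ValueError("no measured counts for the GPR expression")
    return flux / (eff * units.c)
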