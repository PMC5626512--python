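"""Synthetic fixtures: a toy Crabtree-style network and matching omics.

The toy model distills the mechanism behind overflow metabolism in
budding yeast into ~20 reactions: lumped glycolysis feeds a branch point
where pyruvate is either fermented to ethanol (fast, low ATP yield) or
respired through a lumped TCA/electron-transport chain (high ATP yield)
whose capacity is set by a complex containing one very low-abundance
subunit (~100 copies per cell, echoing QCR8). Unconstrained FBA
therefore respires; once sampled enzyme capacities are imposed, most
cells overflow to ethanol. An amino-acid uptake with a small cap feeds a
catabolic shortcut whose use toggles with which enzyme bound limits
glycolytic flux, reproducing bimodal uptake.

Explicit ATP/ADP and NADH/NAD currency metabolites make the
fermentation/respiration yield gap and redox-balance effects mechanistic
rather than cosmetic; full elemental balancing is out of scope for a
fixture. All fixtures regenerate bit-identically from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .constraints import KcatTable, MediumSpec, MetabolicModel
from .gpr import parse_gpr
from .proteomics import CalibrationModel, ProteinMarginal
from .sampling import CorrelationModel

__all__ = [
    "ToyModelConfig",
    "ToyProteomics",
    "ChainFixture",
    "make_toy_model",
    "make_toy_medium",
    "make_toy_proteomics",
    "make_planted_chain",
    "make_planted_ga_fixture",
    "sample_with_marginal_family",
]

IDENTITY_CAL = CalibrationModel(a=1.0, b=1.0)


@dataclass(frozen=True)
class ToyModelConfig:
    """Parameters of the toy Crabtree network.

    ATP yields are per glucose for fermentation (glycolysis only) versus
    full respiration; the respiratory yield must exceed the fermentative
    one for the Crabtree mechanism to be non-trivial.
    """

    glucose_max_uptake: float = 10.0       # mmol gDwt^-1 hr^-1
    amino_acid_max_uptake: float = 0.78    # mmol gDwt^-1 hr^-1
    glycolysis_atp: float = 2.0            # ATP per glucose
    tca_nadh: float = 4.0                  # NADH per pyruvate
    etc_atp_per_nadh: float = 2.0
    biomass_pyr: float = 5.0
    biomass_atp: float = 40.0
    biomass_nadh: float = 5.0
    respiration_mean_copies: float = 97.0  # low-abundance ETC subunit
    n_decoys: int = 4
    seed: int = 0

    @property
    def fermentation_atp_per_glucose(self) -> float:
        return self.glycolysis_atp

    @property
    def respiration_atp_per_glucose(self) -> float:
        # glycolysis + 2 TCA turns + ETC on all NADH produced
        nadh = 2.0 + 2.0 * self.tca_nadh
        return self.glycolysis_atp + 2.0 + nadh * self.etc_atp_per_nadh

    def validate(self) -> None:
        if self.respiration_atp_per_glucose <= self.fermentation_atp_per_glucose:
            raise ValueError(
                "toy model config infeasible: respiration must yield more ATP "
                f"per glucose ({self.respiration_atp_per_glucose}) than "
                f"fermentation ({self.fermentation_atp_per_glucose})")
        for name in ("glucose_max_uptake", "amino_acid_max_uptake",
                     "biomass_atp", "biomass_pyr"):
            if not getattr(self, name) > 0:
                raise ValueError(f"toy model config: {name} must be positive")


def _build_model(name, mets, reactions, biomass_id, genes) -> MetabolicModel:
    """Assemble a MetabolicModel from {rxn: (stoich, lb, ub, gpr_str)}."""
    met_index = {m: i for i, m in enumerate(mets)}
    rxn_ids = list(reactions)
    rows, cols, vals = [], [], []
    lb, ub, gprs = [], [], {}
    exchange = set()
    for j, rid in enumerate(rxn_ids):
        stoich, lo, hi, gpr_str = reactions[rid]
        for met, coeff in stoich.items():
            rows.append(met_index[met])
            cols.append(j)
            vals.append(float(coeff))
        if len(stoich) == 1:
            exchange.add(rid)
        lb.append(lo)
        ub.append(hi)
        gprs[rid] = parse_gpr(gpr_str) if gpr_str else None
    S = sparse.coo_matrix((vals, (rows, cols)),
                          shape=(len(mets), len(rxn_ids))).tocsc()
    return MetabolicModel(rxn_ids, list(mets), S, np.array(lb), np.array(ub),
                          gprs, sorted(genes), biomass_id, exchange, name=name)


def make_toy_model(cfg: ToyModelConfig | None = None,
                   sbml_path=None) -> MetabolicModel:
    """Build the toy Crabtree network (optionally writing it as SBML).

    The unconstrained model is feasible and growth-positive, and pure
    respiration is its optimal strategy; enzyme-capacity overrides are
    what tip it into overflow metabolism.
    """
    cfg = cfg or ToyModelConfig()
    cfg.validate()
    mets = ["glc_e", "glc_c", "o2_e", "o2_c", "co2_c", "co2_e",
            "etoh_c", "etoh_e", "aa_e", "aa_c",
            "pyr_c", "atp_c", "adp_c", "nadh_c", "nad_c"]
    B = 1000.0
    g_atp, t_nadh, e_atp = cfg.glycolysis_atp, cfg.tca_nadh, cfg.etc_atp_per_nadh
    reactions = {
        "EX_glc": ({"glc_e": -1}, -cfg.glucose_max_uptake, B, ""),
        "EX_o2": ({"o2_e": -1}, -B, B, ""),
        "EX_co2": ({"co2_e": -1}, 0.0, B, ""),
        "EX_etoh": ({"etoh_e": -1}, 0.0, B, ""),
        "EX_aa": ({"aa_e": -1}, -cfg.amino_acid_max_uptake, B, ""),
        "GLCt": ({"glc_e": -1, "glc_c": 1}, 0.0, B, "HXT1"),
        "O2t": ({"o2_e": -1, "o2_c": 1}, 0.0, B, ""),
        "CO2t": ({"co2_c": -1, "co2_e": 1}, 0.0, B, ""),
        "ETOHt": ({"etoh_c": -1, "etoh_e": 1}, 0.0, B, ""),
        "AAt": ({"aa_e": -1, "aa_c": 1}, 0.0, B, "AAP1"),
        "GLYC": ({"glc_c": -1, "adp_c": -g_atp, "nad_c": -2,
                  "pyr_c": 2, "atp_c": g_atp, "nadh_c": 2}, 0.0, B,
                 "GLY1 and GLY2"),
        "FERM": ({"pyr_c": -1, "nadh_c": -1,
                  "etoh_c": 1, "nad_c": 1, "co2_c": 1}, 0.0, B,
                 "PDC1 or PDC2"),
        "TCA": ({"pyr_c": -1, "nad_c": -t_nadh, "adp_c": -1,
                 "nadh_c": t_nadh, "atp_c": 1, "co2_c": 3}, 0.0, B, "CIT1"),
        "ETC": ({"nadh_c": -1, "o2_c": -0.5, "adp_c": -e_atp,
                 "nad_c": 1, "atp_c": e_atp}, 0.0, B, "QCR8 and QCR2"),
        "AACAT": ({"aa_c": -1, "nad_c": -1, "adp_c": -1,
                   "pyr_c": 1, "nadh_c": 1, "atp_c": 1}, 0.0, B, "AAC1"),
        "BIOMASS": ({"pyr_c": -cfg.biomass_pyr, "atp_c": -cfg.biomass_atp,
                     "nadh_c": -cfg.biomass_nadh,
                     "adp_c": cfg.biomass_atp, "nad_c": cfg.biomass_nadh},
                    0.0, B, ""),
    }
    for i in range(1, cfg.n_decoys + 1):
        reactions[f"DECOY{i}"] = ({"atp_c": -1, "adp_c": 1}, 0.0, B, f"DEC{i}")
    genes = {"HXT1", "GLY1", "GLY2", "PDC1", "PDC2", "CIT1", "QCR8", "QCR2",
             "AAP1", "AAC1"} | {f"DEC{i}" for i in range(1, cfg.n_decoys + 1)}
    model = _build_model("toy_crabtree", mets, reactions, "BIOMASS", genes)

    # currency moieties must be conserved for the yield gap to be real
    for pair in (("atp_c", "adp_c"), ("nadh_c", "nad_c")):
        rows = [model.metabolite_ids.index(m) for m in pair]
        net = np.abs(np.asarray(model.S[rows, :].sum(axis=0))).max()
        if net > 1e-9:
            raise ValueError(f"toy model config unbalanced in {pair}")

    from .fba import fba  # deferred: fba imports constraints
    sol = fba(model)
    if not sol.optimal or sol.growth_rate <= 0:
        raise ValueError("toy model config yields no unconstrained growth "
                         f"(status {sol.status})")
    if sbml_path is not None:
        from .sbml import write_sbml_fbc
        write_sbml_fbc(model, sbml_path)
    return model


def make_toy_medium(cfg: ToyModelConfig | None = None) -> MediumSpec:
    cfg = cfg or ToyModelConfig()
    return MediumSpec({"EX_glc": cfg.glucose_max_uptake,
                       "EX_o2": 1000.0,
                       "EX_aa": cfg.amino_acid_max_uptake})


@dataclass
class ToyProteomics:
    """Synthetic omics for the toy model.

    ``kcats`` contains the deliberately under-estimated (planted) entries
    used by the relaxation tests; ``true_kcats`` is the clean table.
    Counts are in copy-number units directly, via the identity
    calibration.
    """

    marginals: list[ProteinMarginal]
    corr: CorrelationModel
    kcats: KcatTable
    true_kcats: KcatTable
    planted: dict[str, float]
    cal: CalibrationModel
    calibration_rows: list[tuple[float, float, float]]
    calibration_truth: tuple[float, float]


def _marginal(gene: str, mean: float, cv: float) -> ProteinMarginal:
    shape = 1.0 / cv ** 2
    return ProteinMarginal(gene, shape, mean / shape, n_retained=18)


# gene -> (mean copies per cell, CV, turnover number s^-1)
_TOY_EXPRESSION = {
    "HXT1": (190_000.0, 0.30, 300.0),
    "GLY1": (104_000.0, 0.35, 900.0),
    "GLY2": (48_000.0, 0.35, 1700.0),
    "PDC1": (167_000.0, 0.40, 440.0),
    "PDC2": (630.0, 0.60, 440.0),
    "CIT1": (5_200.0, 0.40, 2029.0),
    "QCR8": (97.0, 0.50, 38_000.0),
    "QCR2": (45_000.0, 0.30, 38_000.0),
    "AAP1": (20_000.0, 0.40, 1000.0),
    "AAC1": (20_000.0, 0.40, 500.0),
}

_FERMENT_BLOCK = ("HXT1", "GLY1", "GLY2", "PDC1", "PDC2")
_RESPIRE_BLOCK = ("CIT1", "QCR8", "QCR2")


def make_toy_proteomics(
    model: MetabolicModel,
    cfg: ToyModelConfig | None = None,
    seed: int = 0,
    plant_low: dict[str, float] | None = None,
    within_block_corr: float = 0.6,
    cross_block_corr: float = -0.3,
) -> ToyProteomics:
    """Generate marginals, correlations, kcats and calibration rows.

    Marginals are gamma with CVs in 0.1-1.0 and means echoing the scale
    of real yeast glycolytic/respiratory enzyme abundances (the
    respiratory complex subunit is expressed at ~100 copies). The
    correlation model puts positive blocks within the fermentative and
    respiratory gene sets and a negative block between them. ``plant_low``
    maps genes to the factor by which their kcat is under-estimated
    (default: the glucose transporter 100x too low).
    """
    cfg = cfg or ToyModelConfig()
    if plant_low is None:
        plant_low = {"HXT1": 100.0}
    rng = np.random.Generator(np.random.Philox(key=seed))

    expression = dict(_TOY_EXPRESSION)
    expression["QCR8"] = (cfg.respiration_mean_copies, 0.50, 38_000.0)
    for i in range(1, cfg.n_decoys + 1):
        expression[f"DEC{i}"] = (5_000.0, 0.50, 1000.0)

    marginals = [_marginal(g, mean, cv) for g, (mean, cv, _) in expression.items()]
    true_kcats = KcatTable({g: k for g, (_, _, k) in expression.items()})
    kcats = true_kcats.copy()
    for gene, factor in plant_low.items():
        if not factor >= 1:
            raise ValueError("plant_low factors must be >= 1")
        kcats.set(gene, true_kcats.kcat(gene) / factor, "planted-low")

    order = list(expression)
    R = np.eye(len(order))
    pos = {g: i for i, g in enumerate(order)}
    for block in (_FERMENT_BLOCK, _RESPIRE_BLOCK):
        for a in block:
            for b in block:
                if a != b:
                    R[pos[a], pos[b]] = within_block_corr
    for a in _FERMENT_BLOCK:
        for b in _RESPIRE_BLOCK:
            R[pos[a], pos[b]] = R[pos[b], pos[a]] = cross_block_corr
    corr = CorrelationModel(order, R)

    # noiseless power-law calibration rows regenerate a known (a, b)
    a_true, b_true = 2.87, 1.5577
    fluor = np.geomspace(10.0, 4000.0, 8)
    ratios = rng.uniform(0.6, 2.0, size=fluor.size)
    rows = [(a_true * f ** b_true / r, f, r) for f, r in zip(fluor, ratios)]

    return ToyProteomics(
        marginals=marginals,
        corr=corr,
        kcats=kcats,
        true_kcats=true_kcats,
        planted=dict(plant_low),
        cal=IDENTITY_CAL,
        calibration_rows=rows,
        calibration_truth=(a_true, b_true),
    )


def sample_with_marginal_family(
    n_cells: int,
    marginals: list[ProteinMarginal],
    kind: str,
    cal: CalibrationModel,
    seed: int,
):
    """Sample counts with the gamma marginals swapped for another family.

    Control experiment: ``normal`` keeps each protein's mean and standard
    deviation, ``uniform`` keeps the mean (support [0, 2*mean]); both are
    clipped below at the calibration floor. Used to show that the
    population's growth-rate distribution depends on the gamma shape of
    protein noise, not only on its first moments.
    """
    from .sampling import CellCounts

    if kind not in ("normal", "uniform"):
        raise ValueError("kind must be 'normal' or 'uniform'")
    rng = np.random.Generator(np.random.Philox(key=seed))
    cols = []
    for m in marginals:
        mean, sd = m.mean, np.sqrt(m.shape) * m.scale
        if kind == "normal":
            x = rng.normal(mean, sd, size=n_cells)
        else:
            x = rng.uniform(0.0, 2.0 * mean, size=n_cells)
        cols.append(np.maximum(cal.convert(np.maximum(x, 0.0)), cal.floor))
    return CellCounts(np.column_stack(cols), [m.protein_id for m in marginals],
                      seed)


# ---------------------------------------------------------------------------
# Minimal planted-defect fixtures for the relaxation algorithms

@dataclass
class ChainFixture:
    """Linear substrate -> biomass chain with planted-low kcats."""

    model: MetabolicModel
    medium: MediumSpec
    marginals: list[ProteinMarginal]
    cal: CalibrationModel
    kcats: KcatTable          # with planted defects
    true_kcats: KcatTable
    planted_genes: list[str]
    candidate_genes: list[str] = field(default_factory=list)


def make_planted_chain(deficit: float = 100.0, seed: int = 0) -> ChainFixture:
    """Substrate uptake chain whose transporter kcat is ``deficit``x too low.

    With the true kcat the transporter capacity (mean ~17) comfortably
    exceeds the substrate cap (10), so growth is medium-limited; the
    planted table caps it ``deficit``-fold lower. Doubling must therefore
    raise the planted kcat ceil(log2(deficit)) times before the batch
    mean growth recovers to the clean-table value.
    """
    if deficit <= 1:
        raise ValueError("deficit must exceed 1")
    reactions = {
        "EX_S": ({"s_e": -1}, -10.0, 1000.0, ""),
        "T": ({"s_e": -1, "s_c": 1}, 0.0, 1000.0, "T1"),
        "BIOMASS": ({"s_c": -20.0}, 0.0, 1000.0, ""),
    }
    model = _build_model("planted_chain", ["s_e", "s_c"], reactions,
                         "BIOMASS", {"T1"})
    marginals = [_marginal("T1", 190_000.0, 0.30)]
    true_kcats = KcatTable({"T1": 300.0})
    kcats = KcatTable({"T1": 300.0 / deficit}, {"T1": "planted-low"})
    return ChainFixture(model, MediumSpec({"EX_S": 10.0}), marginals,
                        IDENTITY_CAL, kcats, true_kcats, ["T1"])


def make_planted_ga_fixture(n_candidates: int = 12, seed: int = 0) -> ChainFixture:
    """Two-step chain with 2 planted-low kcats among ``n_candidates`` genes.

    The two pathway enzymes' curated kcats are 1000x below the lifted
    value, so only genomes lifting both recover realistic growth; the
    remaining candidate genes drive zero-flux decoy reactions, making
    their bits fitness-neutral (the degenerate part of the search space).
    """
    if n_candidates < 3:
        raise ValueError("need at least 3 candidate genes")
    n_decoys = n_candidates - 2
    reactions = {
        "EX_S": ({"s_e": -1}, -10.0, 1000.0, ""),
        "EX_W": ({"w_e": -1}, 0.0, 1000.0, ""),
        "T": ({"s_e": -1, "s_c": 1}, 0.0, 1000.0, "PA"),
        "C": ({"s_c": -1, "m_c": 1}, 0.0, 1000.0, "PB"),
        "BIOMASS": ({"m_c": -20.0}, 0.0, 1000.0, ""),
    }
    genes = {"PA", "PB"}
    for i in range(1, n_decoys + 1):
        reactions[f"DECOY{i}"] = ({"s_c": -1, "w_e": 1}, 0.0, 1000.0, f"DEC{i}")
        genes.add(f"DEC{i}")
    model = _build_model("planted_ga_chain", ["s_e", "s_c", "m_c", "w_e"],
                         reactions, "BIOMASS", genes)
    marginals = [_marginal("PA", 1050.0, 0.30), _marginal("PB", 1050.0, 0.30)]
    marginals += [_marginal(f"DEC{i}", 5000.0, 0.50) for i in range(1, n_decoys + 1)]
    kcats = KcatTable({"PA": 38.0, "PB": 38.0},
                      {"PA": "planted-low", "PB": "planted-low"})
    for i in range(1, n_decoys + 1):
        kcats.set(f"DEC{i}", 1000.0)
    true_kcats = kcats.copy()
    for g in ("PA", "PB"):
        true_kcats.set(g, 38_000.0, "lifted-38000")
    candidates = ["PA", "PB"] + [f"DEC{i}" for i in range(1, n_decoys + 1)]
    return ChainFixture(model, MediumSpec({"EX_S": 10.0}), marginals,
                        IDENTITY_CAL, kcats, true_kcats, ["PA", "PB"],
                        candidate_genes=candidates)
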