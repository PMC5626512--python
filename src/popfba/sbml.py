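"""SBML Level 3 + FBC import/export of metabolic models.

Genome-scale reconstructions are distributed as SBML with the flux
balance constraints (fbc) package carrying bounds, gene products,
gene-product associations and the biomass objective. The reader extracts
everything :class:`~popfba.constraints.MetabolicModel` needs; the writer
round-trips the same information so synthetic fixtures can exercise the
full file path.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse

import libsbml

from . import gpr as gpr_mod
from .constraints import MetabolicModel

__all__ = ["read_sbml_fbc", "write_sbml_fbc"]


def _association_to_expr(assoc, rxn_id: str, label_of: dict[str, str]) -> gpr_mod.GPRExpr:
    if assoc is None:
        raise ValueError(f"reaction {rxn_id!r}: empty gene association")
    if isinstance(assoc, libsbml.GeneProductRef):
        gp = assoc.getGeneProduct()
        return gpr_mod.Gene(label_of.get(gp, gp))
    children = [
        _association_to_expr(assoc.getAssociation(i), rxn_id, label_of)
        for i in range(assoc.getNumAssociations())
    ]
    if not children:
        raise ValueError(f"reaction {rxn_id!r}: malformed gene association")
    if isinstance(assoc, libsbml.FbcAnd):
        return children[0] if len(children) == 1 else gpr_mod.And(tuple(children))
    if isinstance(assoc, libsbml.FbcOr):
        return children[0] if len(children) == 1 else gpr_mod.Or(tuple(children))
    raise ValueError(f"reaction {rxn_id!r}: unsupported association node")


def read_sbml_fbc(path) -> MetabolicModel:
    """Read an SBML L3 + FBC model into a :class:`MetabolicModel`.

    Requires an active FBC objective (the biomass reaction) and an fbc
    gene-product list; boundary-condition species are dropped from the
    stoichiometry, and reactions touching a single metabolite are
    classified as exchanges.
    """
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        raise ValueError(
            f"SBML parse error in {path}: "
            f"{doc.getError(0).getMessage().strip()}")
    model = doc.getModel()
    if model is None:
        raise ValueError(f"no model in SBML file {path}")
    mplug = model.getPlugin("fbc")
    if mplug is None:
        raise ValueError("model has no fbc plugin; SBML L3 + FBC is required")

    if mplug.getNumGeneProducts() == 0:
        raise ValueError("SBML model has no fbc:listOfGeneProducts")
    label_of: dict[str, str] = {}
    for i in range(mplug.getNumGeneProducts()):
        gp = mplug.getGeneProduct(i)
        label_of[gp.getId()] = gp.getLabel() or gp.getId()
    gene_ids = sorted(set(label_of.values()))

    obj = mplug.getActiveObjective()
    if obj is None or obj.getNumFluxObjectives() == 0:
        raise ValueError("SBML model has no active FBC objective")
    biomass_id = obj.getFluxObjective(0).getReaction()

    boundary = {model.getSpecies(i).getId()
                for i in range(model.getNumSpecies())
                if model.getSpecies(i).getBoundaryCondition()}
    met_ids = [model.getSpecies(i).getId()
               for i in range(model.getNumSpecies())
               if model.getSpecies(i).getId() not in boundary]
    met_index = {m: i for i, m in enumerate(met_ids)}

    rxn_ids, lbs, ubs, gprs = [], [], [], {}
    rows, cols, vals = [], [], []
    exchange_ids = set()
    for j in range(model.getNumReactions()):
        rxn = model.getReaction(j)
        rid = rxn.getId()
        rxn_ids.append(rid)
        rplug = rxn.getPlugin("fbc")
        if rplug is None:
            raise ValueError(f"reaction {rid!r} lacks fbc bounds")
        lb_par = model.getParameter(rplug.getLowerFluxBound())
        ub_par = model.getParameter(rplug.getUpperFluxBound())
        if lb_par is None or ub_par is None:
            raise ValueError(f"reaction {rid!r}: missing flux bound parameter")
        lbs.append(lb_par.getValue())
        ubs.append(ub_par.getValue())

        touched = 0
        for k in range(rxn.getNumReactants()):
            sr = rxn.getReactant(k)
            if sr.getSpecies() in met_index:
                rows.append(met_index[sr.getSpecies()])
                cols.append(j)
                vals.append(-sr.getStoichiometry())
                touched += 1
        for k in range(rxn.getNumProducts()):
            sr = rxn.getProduct(k)
            if sr.getSpecies() in met_index:
                rows.append(met_index[sr.getSpecies()])
                cols.append(j)
                vals.append(sr.getStoichiometry())
                touched += 1
        if touched == 1:
            exchange_ids.add(rid)

        gpa = rplug.getGeneProductAssociation()
        if gpa is not None:
            try:
                gprs[rid] = _association_to_expr(gpa.getAssociation(), rid, label_of)
            except gpr_mod.GPRParseError as exc:
                raise ValueError(f"reaction {rid!r}: malformed GPR ({exc})") from exc
        else:
            gprs[rid] = None

    S = sparse.coo_matrix(
        (vals, (rows, cols)), shape=(len(met_ids), len(rxn_ids))).tocsc()
    return MetabolicModel(
        reaction_ids=rxn_ids,
        metabolite_ids=met_ids,
        S=S,
        lb=np.array(lbs),
        ub=np.array(ubs),
        gpr=gprs,
        gene_ids=gene_ids,
        biomass_id=biomass_id,
        exchange_ids=exchange_ids,
        name=model.getId() or "model",
    )


def _expr_to_association(expr: gpr_mod.GPRExpr, parent, gp_id_of: dict[str, str]) -> None:
    if isinstance(expr, gpr_mod.Gene):
        ref = parent.createGeneProductRef()
        ref.setGeneProduct(gp_id_of[expr.name])
        return
    node = parent.createAnd() if isinstance(expr, gpr_mod.And) else parent.createOr()
    for child in expr.children:
        _expr_to_association(child, node, gp_id_of)


def write_sbml_fbc(model: MetabolicModel, path) -> None:
    """Write a :class:`MetabolicModel` as SBML L3V1 with FBC v2."""
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml = doc.createModel()
    sbml.setId(model.name.replace(" ", "_") or "model")
    mplug = sbml.getPlugin("fbc")
    mplug.setStrict(True)

    comp = sbml.createCompartment()
    comp.setId("c")
    comp.setConstant(True)
    comp.setSize(1.0)

    for met in model.metabolite_ids:
        sp = sbml.createSpecies()
        sp.setId(met)
        sp.setCompartment("c")
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)

    gp_id_of = {}
    for g in model.gene_ids:
        gp = mplug.createGeneProduct()
        gid = "G_" + g.replace("-", "_").replace(".", "_")
        gp.setId(gid)
        gp.setLabel(g)
        gp_id_of[g] = gid

    def bound_param(value: float) -> str:
        pid = ("fb_m" if value < 0 else "fb_") + f"{abs(value):.12g}".replace(
            ".", "_").replace("+", "").replace("-", "m")
        if sbml.getParameter(pid) is None:
            par = sbml.createParameter()
            par.setId(pid)
            par.setValue(float(value))
            par.setConstant(True)
        return pid

    Scoo = model.S.tocoo()
    by_rxn: dict[int, list[tuple[int, float]]] = {}
    for i, j, v in zip(Scoo.row, Scoo.col, Scoo.data):
        by_rxn.setdefault(int(j), []).append((int(i), float(v)))

    for j, rid in enumerate(model.reaction_ids):
        rxn = sbml.createReaction()
        rxn.setId(rid)
        rxn.setFast(False)
        rxn.setReversible(bool(model.lb[j] < 0))
        rplug = rxn.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(model.lb[j]))
        rplug.setUpperFluxBound(bound_param(model.ub[j]))
        for i, coeff in sorted(by_rxn.get(j, [])):
            sr = rxn.createReactant() if coeff < 0 else rxn.createProduct()
            sr.setSpecies(model.metabolite_ids[i])
            sr.setStoichiometry(abs(coeff))
            sr.setConstant(True)
        expr = model.gpr.get(rid)
        if expr is not None:
            gpa = rplug.createGeneProductAssociation()
            _expr_to_association(expr, gpa, gp_id_of)

    obj = mplug.createObjective()
    obj.setId("obj")
    obj.setType("maximize")
    fo = obj.createFluxObjective()
    fo.setReaction(model.biomass_id)
    fo.setCoefficient(1.0)
    mplug.setActiveObjectiveId("obj")

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise IOError(f"failed to write SBML to {path}")
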