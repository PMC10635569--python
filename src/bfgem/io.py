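"""Model readers and writers: SBML Level 3 + FBC, COBRA JSON, tabular.

All three dialects round-trip the same information: metabolites with
compartments and formulas, reactions with stoichiometry, bounds, gene
rules and functional class, and the objective.  Reaction class is
carried as an SBO term in SBML, a ``notes`` entry in JSON, and an
explicit column in the tabular dialect.

The tabular dialect is an ``.xlsx`` workbook (or a directory of two
TSV files) with a ``metabolites`` sheet (id, name, compartment,
formula) and a ``reactions`` sheet (id, name, equation, lower_bound,
upper_bound, gene_rule, subsystem, kind, objective); equations use the
conventions ``2 a_c + b_c --> c_c`` and ``<=>`` for reversible.
"""

from __future__ import annotations

import json
import math
import re
from pathlib import Path

import libsbml
import pandas as pd

from .model import (
    ElementalFormula,
    GeneRule,
    Metabolite,
    MetabolicModel,
    ModelValidationError,
    Reaction,
    classify_reaction,
)

__all__ = ["read_model", "write_model", "parse_equation", "read_spreadsheet_model"]


class ParseError(ValueError):
    """Raised when an input file cannot be interpreted as a model."""


_SBO_BY_KIND = {
    "exchange": 627,
    "demand": 628,
    "biomass": 629,
    "maintenance": 630,
    "transport": 185,
    "metabolic": 176,
}
_KIND_BY_SBO = {v: k for k, v in _SBO_BY_KIND.items()}


def _detect_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".xml", ".sbml"):
        return "sbml"
    if suffix == ".json":
        return "json"
    if suffix == ".xlsx" or path.is_dir():
        return "tabular"
    raise ParseError(f"cannot infer model format from {path.name!r}")


def read_model(path: str | Path, format: str = "auto") -> MetabolicModel:
    """Read a model file in SBML-FBC, COBRA-JSON, or tabular format."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _detect_format(path) if format == "auto" else format
    if fmt == "sbml":
        model = _read_sbml(path)
    elif fmt == "json":
        model = _read_json(path)
    elif fmt == "tabular":
        model = _read_tabular(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    model.validate()
    return model


def write_model(model: MetabolicModel, path: str | Path, format: str = "auto") -> Path:
    """Write a model in the requested dialect; returns the path written."""
    path = Path(path)
    fmt = _detect_format(path) if format == "auto" else format
    if fmt == "sbml":
        _write_sbml(model, path)
    elif fmt == "json":
        _write_json(model, path)
    elif fmt == "tabular":
        _write_tabular(model, path)
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


# -- equations -------------------------------------------------------------

_ARROWS = ("<=>", "<->", "-->", "->", "=>")


def parse_equation(text: str) -> tuple[dict[str, float], bool]:
    """Parse ``2 a_c + b_c --> c_c`` into (stoichiometry, reversible)."""
    arrow = next((a for a in _ARROWS if a in text), None)
    if arrow is None:
        raise ParseError(f"no reaction arrow in equation {text!r}")
    reversible = arrow in ("<=>", "<->")
    lhs_text, rhs_text = text.split(arrow, 1)
    stoich: dict[str, float] = {}

    def add_side(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split("+"):
            term = term.strip()
            if not term:
                continue
            parts = term.split()
            if len(parts) == 1:
                coef, met = 1.0, parts[0]
            elif len(parts) == 2:
                try:
                    coef = float(parts[0])
                except ValueError as exc:
                    raise ParseError(f"bad coefficient in term {term!r}") from exc
                met = parts[1]
            else:
                raise ParseError(f"bad equation term {term!r}")
            stoich[met] = stoich.get(met, 0.0) + sign * coef

    add_side(lhs_text, -1.0)
    add_side(rhs_text, +1.0)
    stoich = {m: c for m, c in stoich.items() if c != 0}
    if not stoich:
        raise ParseError(f"equation {text!r} has empty net stoichiometry")
    return stoich, reversible


# -- COBRA JSON ------------------------------------------------------------

def _read_json(path: Path) -> MetabolicModel:
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path.name}: invalid JSON ({exc})") from exc
    for key in ("metabolites", "reactions"):
        if key not in data:
            raise ParseError(f"{path.name}: missing {key!r} array")
    model = MetabolicModel(model_id=data.get("id", path.stem))
    for rec in data["metabolites"]:
        try:
            formula = rec.get("formula") or None
            model.add_metabolite(
                Metabolite(
                    rec["id"],
                    rec.get("name", ""),
                    rec.get("compartment", "c"),
                    ElementalFormula.parse(formula) if formula else None,
                )
            )
        except (KeyError, ValueError) as exc:
            raise ParseError(f"{path.name}: bad metabolite record {rec.get('id')!r}: {exc}") from exc
    objective_id = None
    for rec in data["reactions"]:
        try:
            notes = rec.get("notes") or {}
            rxn = Reaction(
                rec["id"],
                {m: float(c) for m, c in rec["metabolites"].items()},
                float(rec.get("lower_bound", -1000.0)),
                float(rec.get("upper_bound", 1000.0)),
                name=rec.get("name", ""),
                subsystem=rec.get("subsystem", ""),
                gene_rule=GeneRule.parse(rec.get("gene_reaction_rule", "")),
                kind=notes.get("bfgem_kind", "metabolic"),
                notes={k: v for k, v in notes.items() if k != "bfgem_kind"},
            )
        except (KeyError, ValueError, ModelValidationError) as exc:
            raise ParseError(f"{path.name}: bad reaction record {rec.get('id')!r}: {exc}") from exc
        model.add_reaction(rxn)
        if float(rec.get("objective_coefficient", 0.0)) != 0.0:
            objective_id = rxn.id
        if "bfgem_kind" not in (rec.get("notes") or {}):
            rxn.kind = _infer_kind(model, rxn)
    model.objective_id = objective_id
    return model


def _infer_kind(model: MetabolicModel, rxn: Reaction) -> str:
    rid = rxn.id.lower()
    if "biomass" in rid:
        return "biomass"
    if rid == "atpm" or "maintenance" in rxn.name.lower():
        return "maintenance"
    if rid.startswith("dm_"):
        return "demand"
    return classify_reaction(model, rxn)


def _write_json(model: MetabolicModel, path: Path) -> None:
    data = {
        "id": model.id,
        "version": "1",
        "compartments": {c: c for c in sorted(model.compartments)},
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "formula": str(m.formula) if m.formula else "",
            }
            for m in model.metabolites.values()
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "metabolites": {m: c for m, c in r.stoichiometry.items()},
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gene_reaction_rule": r.gene_rule.to_string(),
                "subsystem": r.subsystem,
                "objective_coefficient": 1.0 if r.id == model.objective_id else 0.0,
                "notes": {**r.notes, "bfgem_kind": r.kind},
            }
            for r in model.reactions.values()
        ],
        "genes": [{"id": g, "name": g} for g in model.genes],
    }
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1)


# -- SBML L3 + FBC ---------------------------------------------------------

def _sbml_check(obj, what: str) -> None:
    if obj is None:
        raise RuntimeError(f"libsbml failed to create {what}")


def _write_sbml(model: MetabolicModel, path: Path) -> None:
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(re.sub(r"\W", "_", model.id))
    fbc = sm.getPlugin("fbc")
    fbc.setStrict(False)

    for cid in sorted(model.compartments):
        comp = sm.createCompartment()
        comp.setId(cid)
        comp.setConstant(True)

    for met in model.metabolites.values():
        sp = sm.createSpecies()
        sp.setId(f"M_{met.id}")
        sp.setName(met.name or met.id)
        sp.setCompartment(met.compartment)
        sp.setConstant(False)
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        if met.formula is not None:
            sp.getPlugin("fbc").setChemicalFormula(str(met.formula))

    for g in model.genes:
        gp = fbc.createGeneProduct()
        gp.setId(f"G_{g}")
        gp.setLabel(g)

    bound_ids: dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_ids:
            pid = f"fb_{len(bound_ids)}"
            par = sm.createParameter()
            par.setId(pid)
            par.setValue(value)
            par.setConstant(True)
            bound_ids[value] = pid
        return bound_ids[value]

    def build_assoc(parent, node) -> None:
        if isinstance(node, str):
            ref = parent.createGeneProductRef()
            ref.setGeneProduct(f"G_{node}")
            return
        op, children = node
        grp = parent.createAnd() if op == "and" else parent.createOr()
        for child in children:
            build_assoc(grp, child)

    for rxn in model.reactions.values():
        sr = sm.createReaction()
        sr.setId(f"R_{rxn.id}")
        sr.setName(rxn.name or rxn.id)
        sr.setFast(False)
        sr.setReversible(rxn.lower_bound < 0)
        sr.setSBOTerm(_SBO_BY_KIND[rxn.kind])
        rf = sr.getPlugin("fbc")
        rf.setLowerFluxBound(bound_param(rxn.lower_bound))
        rf.setUpperFluxBound(bound_param(rxn.upper_bound))
        for met_id, coef in rxn.stoichiometry.items():
            ref = sr.createReactant() if coef < 0 else sr.createProduct()
            ref.setSpecies(f"M_{met_id}")
            ref.setStoichiometry(abs(float(coef)))
            ref.setConstant(True)
        if not rxn.gene_rule.is_empty:
            gpa = rf.createGeneProductAssociation()
            build_assoc(gpa, rxn.gene_rule.tree)

    if model.objective_id is not None:
        obj = fbc.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        flux_obj = obj.createFluxObjective()
        flux_obj.setReaction(f"R_{model.objective_id}")
        flux_obj.setCoefficient(1.0)
        fbc.setActiveObjectiveId("obj")

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise RuntimeError(f"failed to write SBML to {path}")


def _strip_prefix(sid: str, prefix: str) -> str:
    return sid[len(prefix):] if sid.startswith(prefix) else sid


def _read_sbml(path: Path) -> MetabolicModel:
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ParseError(f"{path.name}: SBML parse error: {err.getMessage().strip()}")
    sm = doc.getModel()
    if sm is None:
        raise ParseError(f"{path.name}: no model element")
    model = MetabolicModel(model_id=sm.getId() or path.stem)
    for i in range(sm.getNumSpecies()):
        sp = sm.getSpecies(i)
        formula_text = ""
        fp = sp.getPlugin("fbc")
        if fp is not None and fp.isSetChemicalFormula():
            formula_text = fp.getChemicalFormula()
        model.add_metabolite(
            Metabolite(
                _strip_prefix(sp.getId(), "M_"),
                sp.getName(),
                sp.getCompartment(),
                ElementalFormula.parse(formula_text) if formula_text else None,
            )
        )
    gene_labels = {}
    fbc = sm.getPlugin("fbc")
    if fbc is not None:
        for i in range(fbc.getNumGeneProducts()):
            gp = fbc.getGeneProduct(i)
            gene_labels[gp.getId()] = gp.getLabel() or _strip_prefix(gp.getId(), "G_")

    def read_assoc(node):
        if node is None:
            return None
        if isinstance(node, libsbml.GeneProductRef):
            gid = node.getGeneProduct()
            return gene_labels.get(gid, _strip_prefix(gid, "G_"))
        children = [read_assoc(node.getAssociation(i)) for i in range(node.getNumAssociations())]
        op = "and" if isinstance(node, libsbml.FbcAnd) else "or"
        if len(children) == 1:
            return children[0]
        return (op, children)

    objective_id = None
    if fbc is not None and fbc.getActiveObjective() is not None:
        active = fbc.getActiveObjective()
        if active.getNumFluxObjectives() > 0:
            objective_id = _strip_prefix(active.getFluxObjective(0).getReaction(), "R_")

    for i in range(sm.getNumReactions()):
        sr = sm.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(sr.getNumReactants()):
            ref = sr.getReactant(j)
            mid = _strip_prefix(ref.getSpecies(), "M_")
            stoich[mid] = stoich.get(mid, 0.0) - ref.getStoichiometry()
        for j in range(sr.getNumProducts()):
            ref = sr.getProduct(j)
            mid = _strip_prefix(ref.getSpecies(), "M_")
            stoich[mid] = stoich.get(mid, 0.0) + ref.getStoichiometry()
        rf = sr.getPlugin("fbc")
        lb, ub = -1000.0, 1000.0
        if rf is not None:
            if rf.isSetLowerFluxBound():
                par = sm.getParameter(rf.getLowerFluxBound())
                if par is not None:
                    lb = par.getValue()
            if rf.isSetUpperFluxBound():
                par = sm.getParameter(rf.getUpperFluxBound())
                if par is not None:
                    ub = par.getValue()
        tree = None
        if rf is not None and rf.isSetGeneProductAssociation():
            tree = read_assoc(rf.getGeneProductAssociation().getAssociation())
        kind = _KIND_BY_SBO.get(sr.getSBOTerm())
        rxn = Reaction(
            _strip_prefix(sr.getId(), "R_"),
            stoich,
            lb,
            ub,
            name=sr.getName(),
            gene_rule=GeneRule(tree),
        )
        model.add_reaction(rxn)
        rxn.kind = kind if kind is not None else _infer_kind(model, rxn)
    model.objective_id = objective_id
    return model


# -- tabular ---------------------------------------------------------------

_MET_COLUMNS = ["id", "name", "compartment", "formula"]
_RXN_COLUMNS = [
    "id", "name", "equation", "lower_bound", "upper_bound",
    "gene_rule", "subsystem", "kind", "objective",
]


def _metabolite_frame(model: MetabolicModel) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "formula": str(m.formula) if m.formula else "",
            }
            for m in model.metabolites.values()
        ],
        columns=_MET_COLUMNS,
    )


def _reaction_frame(model: MetabolicModel) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id": r.id,
                "name": r.name,
                "equation": r.equation(),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gene_rule": r.gene_rule.to_string(),
                "subsystem": r.subsystem,
                "kind": r.kind,
                "objective": 1 if r.id == model.objective_id else 0,
            }
            for r in model.reactions.values()
        ],
        columns=_RXN_COLUMNS,
    )


def _write_tabular(model: MetabolicModel, path: Path) -> None:
    mets, rxns = _metabolite_frame(model), _reaction_frame(model)
    if path.suffix.lower() == ".xlsx":
        with pd.ExcelWriter(path, engine="openpyxl") as xl:
            mets.to_excel(xl, sheet_name="metabolites", index=False)
            rxns.to_excel(xl, sheet_name="reactions", index=False)
    else:
        path.mkdir(parents=True, exist_ok=True)
        mets.to_csv(path / "metabolites.tsv", sep="\t", index=False)
        rxns.to_csv(path / "reactions.tsv", sep="\t", index=False)


def _frames_to_model(
    mets: pd.DataFrame, rxns: pd.DataFrame, model_id: str
) -> MetabolicModel:
    model = MetabolicModel(model_id=model_id)
    for _, row in mets.iterrows():
        formula = str(row.get("formula", "") or "")
        model.add_metabolite(
            Metabolite(
                str(row["id"]),
                str(row.get("name", "") or ""),
                str(row["compartment"]),
                ElementalFormula.parse(formula) if formula else None,
            )
        )
    objective_id = None
    for _, row in rxns.iterrows():
        stoich, reversible = parse_equation(str(row["equation"]))
        lb = row.get("lower_bound")
        ub = row.get("upper_bound")
        lb = float(lb) if lb is not None and not _isna(lb) else (-1000.0 if reversible else 0.0)
        ub = float(ub) if ub is not None and not _isna(ub) else 1000.0
        rule_text = row.get("gene_rule", "")
        rxn = Reaction(
            str(row["id"]),
            stoich,
            lb,
            ub,
            name=str(row.get("name", "") or ""),
            subsystem=str(row.get("subsystem", "") or ""),
            gene_rule=GeneRule.parse("" if _isna(rule_text) else str(rule_text)),
            kind=str(row.get("kind", "metabolic") or "metabolic"),
        )
        model.add_reaction(rxn)
        if not _isna(row.get("objective", 0)) and float(row.get("objective", 0) or 0) != 0:
            objective_id = rxn.id
    model.objective_id = objective_id
    return model


def _isna(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def _read_tabular(path: Path) -> MetabolicModel:
    if path.suffix.lower() == ".xlsx":
        try:
            mets = pd.read_excel(path, sheet_name="metabolites")
            rxns = pd.read_excel(path, sheet_name="reactions")
        except ValueError as exc:
            raise ParseError(f"{path.name}: {exc}") from exc
    else:
        met_path, rxn_path = path / "metabolites.tsv", path / "reactions.tsv"
        if not met_path.exists() or not rxn_path.exists():
            raise ParseError(f"{path}: expected metabolites.tsv and reactions.tsv")
        mets = pd.read_csv(met_path, sep="\t")
        rxns = pd.read_csv(rxn_path, sep="\t")
    for frame, required, label in ((mets, ("id", "compartment"), "metabolites"),
                                   (rxns, ("id", "equation"), "reactions")):
        missing = [c for c in required if c not in frame.columns]
        if missing:
            raise ParseError(f"{path.name}: {label} sheet lacks columns {missing}")
    return _frames_to_model(mets, rxns, path.stem)


# Loose spreadsheet importer: accepts common alternative column spellings
# seen in distributed supplementary workbooks.  Best-effort, not normative.
_ALIASES = {
    "id": ("id", "reaction id", "abbreviation", "rxn", "reaction"),
    "equation": ("equation", "reaction formula", "formula", "rxn formula"),
    "lower_bound": ("lower_bound", "lower bound", "lb"),
    "upper_bound": ("upper_bound", "upper bound", "ub"),
    "gene_rule": ("gene_rule", "gpr", "gene reaction rule", "gene association", "grrule"),
    "subsystem": ("subsystem", "pathway"),
    "name": ("name", "description", "reaction name"),
}
_MET_ALIASES = {
    "id": ("id", "metabolite id", "abbreviation", "metabolite"),
    "name": ("name", "description", "metabolite name"),
    "compartment": ("compartment", "comp"),
    "formula": ("formula", "chemical formula", "charged formula", "neutral formula"),
}


def _remap(frame: pd.DataFrame, aliases: dict) -> pd.DataFrame:
    lower = {str(c).strip().lower(): c for c in frame.columns}
    rename = {}
    for canonical, options in aliases.items():
        for opt in options:
            if opt in lower:
                rename[lower[opt]] = canonical
                break
    return frame.rename(columns=rename)


def read_spreadsheet_model(path: str | Path) -> MetabolicModel:
    """Best-effort importer for externally produced model workbooks.

    Sheet names and column headers are matched case-insensitively
    against common spellings; metabolite compartments fall back to the
    trailing ``_c``/``_p``/``_e`` id suffix when no compartment column
    exists.
    """
    path = Path(path)
    book = pd.read_excel(path, sheet_name=None)
    sheets = {str(k).strip().lower(): v for k, v in book.items()}
    rxn_sheet = next((sheets[k] for k in sheets if "reaction" in k or "rxn" in k), None)
    met_sheet = next((sheets[k] for k in sheets if "metabolite" in k or "met" in k), None)
    if rxn_sheet is None or met_sheet is None:
        raise ParseError(f"{path.name}: could not locate reactions/metabolites sheets")
    mets = _remap(met_sheet, _MET_ALIASES)
    rxns = _remap(rxn_sheet, _ALIASES)
    if "compartment" not in mets.columns:
        mets = mets.assign(
            compartment=[
                mid.rsplit("_", 1)[-1] if str(mid).rsplit("_", 1)[-1] in ("c", "p", "e") else "c"
                for mid in mets["id"].astype(str)
            ]
        )
    return _frames_to_model(mets, rxns, path.stem)
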