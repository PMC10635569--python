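"""Core data structures for constraint-based metabolic models.

A model is a set of metabolites distributed over three compartments
(cytosol ``c``, periplasm ``p``, extracellular space ``e``), a set of
reactions with flux bounds and gene-protein-reaction (GPR) rules, and a
designated objective reaction (usually biomass).  The convention
throughout is the standard COBRA one: exchange reactions are written
``met_e <=> (nothing)`` so that negative flux means uptake and positive
flux means secretion, and fluxes are in mmol/gDW/h.
"""

from __future__ import annotations

import copy
import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping

import numpy as np
from scipy import sparse

__all__ = [
    "ElementalFormula",
    "Metabolite",
    "GeneRule",
    "Reaction",
    "MetabolicModel",
    "ModelStatistics",
    "MassBalanceReport",
    "ModelValidationError",
    "stoichiometric_matrix",
    "check_mass_balance",
    "model_statistics",
]

COMPARTMENTS = ("c", "p", "e")

# Standard atomic weights (IUPAC 2021, abridged).  The pseudo-element "R"
# denotes a cycled carrier moiety (tRNA, acyl-carrier protein, ...) and
# carries zero mass: carriers are regenerated, never consumed.
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "Se": 78.971, "F": 18.998, "Cl": 35.45, "Br": 79.904,
    "I": 126.904, "Na": 22.990, "K": 39.098, "Mg": 24.305, "Ca": 40.078,
    "Fe": 55.845, "Zn": 65.38, "Cu": 63.546, "Mn": 54.938, "Co": 58.933,
    "Mo": 95.95, "Ni": 58.693, "W": 183.84, "R": 0.0,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*(?:\.\d+)?(?:/\d+)?)")


class ModelValidationError(ValueError):
    """Raised when a model or one of its components violates an invariant."""


class FormulaError(ValueError):
    """Raised when an elemental formula string cannot be parsed."""


@dataclass(frozen=True)
class ElementalFormula:
    """Elemental composition with non-negative rational counts.

    Counts are :class:`fractions.Fraction` so that averaged compositions
    (e.g. a representative membrane lipid averaged over chain lengths)
    are representable exactly.  The pseudo-element ``R`` marks a carrier
    moiety and contributes no mass.
    """

    counts: Mapping[str, Fraction]

    def __post_init__(self) -> None:
        clean: dict[str, Fraction] = {}
        for el, n in dict(self.counts).items():
            n = Fraction(n)
            if n < 0:
                raise FormulaError(f"negative count for element {el!r}")
            if n > 0:
                clean[el] = n
        if not clean:
            raise FormulaError("formula must contain at least one element")
        object.__setattr__(self, "counts", clean)

    @classmethod
    def parse(cls, text: str) -> "ElementalFormula":
        """Parse a Hill-style formula string, e.g. ``C6H12O6`` or ``R``.

        Fractional counts are accepted both as decimals (``C17.5``) and
        as explicit fractions (``C35/2``).
        """
        text = text.strip()
        if not text:
            raise FormulaError("empty formula")
        pos = 0
        counts: dict[str, Fraction] = {}
        for m in _FORMULA_TOKEN.finditer(text):
            if m.start() != pos:
                raise FormulaError(f"unparseable formula {text!r} at offset {pos}")
            pos = m.end()
            el, num = m.group(1), m.group(2)
            if el not in ATOMIC_WEIGHTS:
                raise FormulaError(f"unknown element {el!r} in {text!r}")
            counts[el] = counts.get(el, Fraction(0)) + (Fraction(num) if num else Fraction(1))
        if pos != len(text):
            raise FormulaError(f"unparseable formula {text!r} at offset {pos}")
        return cls(counts)

    def count(self, element: str) -> Fraction:
        return self.counts.get(element, Fraction(0))

    @property
    def mass(self) -> float:
        """Molar mass in g/mol (R contributes zero)."""
        return float(sum(ATOMIC_WEIGHTS[el] * float(n) for el, n in self.counts.items()))

    def __str__(self) -> str:
        parts = []
        for el in sorted(self.counts, key=lambda e: (e != "C", e != "H", e)):
            n = self.counts[el]
            if n == 1:
                parts.append(el)
            elif n.denominator == 1:
                parts.append(f"{el}{n.numerator}")
            else:
                parts.append(f"{el}{float(n):g}")
        return "".join(parts)


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    formula: ElementalFormula | None = None

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ModelValidationError(
                f"metabolite {self.id!r}: compartment {self.compartment!r} "
                f"not in {COMPARTMENTS}"
            )
        if isinstance(self.formula, str):
            self.formula = ElementalFormula.parse(self.formula)


class GeneRule:
    """Boolean AND/OR tree over gene identifiers.

    Isozymes are ORed, subunits of a complex are ANDed.  An empty rule
    means the reaction has no gene association and is never disabled by
    a knockout.  The tree is either ``None`` (empty), a gene-id string
    (leaf), or a tuple ``(op, children)`` with ``op`` in ``{"and","or"}``.
    """

    __slots__ = ("tree",)

    def __init__(self, tree=None):
        self.tree = tree

    @classmethod
    def parse(cls, text: str | None) -> "GeneRule":
        if text is None or not text.strip():
            return cls(None)
        tokens = re.findall(r"\(|\)|[Aa][Nn][Dd]\b|[Oo][Rr]\b|&&?|\|\|?|[^\s()&|]+", text)
        pos = 0

        def peek():
            return tokens[pos] if pos < len(tokens) else None

        def expect(tok):
            nonlocal pos
            if peek() != tok:
                raise ModelValidationError(f"bad gene rule {text!r}: expected {tok!r}")
            pos += 1

        def parse_or():
            nonlocal pos
            terms = [parse_and()]
            while peek() is not None and (peek().lower() == "or" or peek() in ("|", "||")):
                pos += 1
                terms.append(parse_and())
            return terms[0] if len(terms) == 1 else ("or", terms)

        def parse_and():
            nonlocal pos
            terms = [parse_atom()]
            while peek() is not None and (peek().lower() == "and" or peek() in ("&", "&&")):
                pos += 1
                terms.append(parse_atom())
            return terms[0] if len(terms) == 1 else ("and", terms)

        def parse_atom():
            nonlocal pos
            tok = peek()
            if tok is None:
                raise ModelValidationError(f"bad gene rule {text!r}: unexpected end")
            if tok == "(":
                pos += 1
                node = parse_or()
                expect(")")
                return node
            if tok == ")" or tok.lower() in ("and", "or"):
                raise ModelValidationError(f"bad gene rule {text!r}: unexpected {tok!r}")
            pos += 1
            return tok

        tree = parse_or()
        if pos != len(tokens):
            raise ModelValidationError(f"bad gene rule {text!r}: trailing tokens")
        return cls(tree)

    @property
    def is_empty(self) -> bool:
        return self.tree is None

    def genes(self) -> frozenset[str]:
        out: set[str] = set()

        def walk(node):
            if node is None:
                return
            if isinstance(node, str):
                out.add(node)
            else:
                for child in node[1]:
                    walk(child)

        walk(self.tree)
        return frozenset(out)

    def evaluate(self, knocked_out: Iterable[str] = ()) -> bool:
        """Truth value with knocked-out genes false and all others true."""
        ko = set(knocked_out)

        def walk(node) -> bool:
            if isinstance(node, str):
                return node not in ko
            op, children = node
            if op == "and":
                return all(walk(c) for c in children)
            return any(walk(c) for c in children)

        if self.tree is None:
            return True
        return walk(self.tree)

    def to_string(self) -> str:
        def walk(node, parent_op=None) -> str:
            if isinstance(node, str):
                return node
            op, children = node
            inner = f" {op} ".join(walk(c, op) for c in children)
            if parent_op is not None and parent_op != op:
                return f"({inner})"
            return inner

        return "" if self.tree is None else walk(self.tree)

    def __eq__(self, other) -> bool:
        return isinstance(other, GeneRule) and self.tree == other.tree

    def __repr__(self) -> str:
        return f"GeneRule({self.to_string()!r})"


REACTION_KINDS = ("exchange", "transport", "metabolic", "biomass", "maintenance", "demand")


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = -1000.0
    upper_bound: float = 1000.0
    name: str = ""
    subsystem: str = ""
    gene_rule: GeneRule = field(default_factory=GeneRule)
    kind: str = "metabolic"
    notes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if isinstance(self.gene_rule, str):
            self.gene_rule = GeneRule.parse(self.gene_rule)
        if self.kind not in REACTION_KINDS:
            raise ModelValidationError(f"reaction {self.id!r}: unknown kind {self.kind!r}")
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def equation(self, model: "MetabolicModel | None" = None) -> str:
        """Human-readable / tabular-dialect equation string."""
        lhs, rhs = [], []
        for met, coef in sorted(self.stoichiometry.items()):
            mag = abs(coef)
            term = met if mag == 1 else f"{mag:.15g} {met}"
            (lhs if coef < 0 else rhs).append(term)
        arrow = "<=>" if self.lower_bound < 0 else "-->"
        return f"{' + '.join(lhs)} {arrow} {' + '.join(rhs)}".strip()


@dataclass
class ModelStatistics:
    n_reactions: int
    n_metabolite_instances: int
    n_unique_metabolites: int
    n_genes: int
    n_exchange: int
    n_transport: int
    n_metabolic: int
    n_biomass: int = 0
    n_maintenance: int = 0
    n_demand: int = 0


@dataclass
class MassBalanceReport:
    """Outcome of an element-conservation audit.

    ``violations`` holds one ``(reaction_id, element, imbalance)`` entry
    per reaction and element whose net production is nonzero; hydrogen
    is exempt (proton bookkeeping is not tracked, matching the charge-
    agnostic convention).  ``unverifiable`` lists reactions skipped
    because a participant has no formula.
    """

    violations: list[tuple[str, str, Fraction]]
    unverifiable: list[str]

    @property
    def ok(self) -> bool:
        return not self.violations


class MetabolicModel:
    """A genome-scale (or toy) metabolic network.

    Maintains insertion order of metabolites and reactions; ids are
    unique.  The gene list is derived from the union of GPR leaves.
    """

    def __init__(
        self,
        model_id: str = "model",
        metabolites: Iterable[Metabolite] = (),
        reactions: Iterable[Reaction] = (),
        objective_id: str | None = None,
    ):
        self.id = model_id
        self.metabolites: dict[str, Metabolite] = {}
        self.reactions: dict[str, Reaction] = {}
        self.objective_id = objective_id
        for m in metabolites:
            self.add_metabolite(m)
        for r in reactions:
            self.add_reaction(r)

    # -- construction ---------------------------------------------------
    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise ModelValidationError(f"duplicate metabolite id {met.id!r}")
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self.reactions:
            raise ModelValidationError(f"duplicate reaction id {rxn.id!r}")
        for met_id in rxn.stoichiometry:
            if met_id not in self.metabolites:
                raise ModelValidationError(
                    f"reaction {rxn.id!r} references unknown metabolite {met_id!r}"
                )
        self.reactions[rxn.id] = rxn

    def remove_reaction(self, rxn_id: str) -> Reaction:
        if rxn_id not in self.reactions:
            raise ModelValidationError(f"no reaction {rxn_id!r}")
        if rxn_id == self.objective_id:
            self.objective_id = None
        return self.reactions.pop(rxn_id)

    def copy(self) -> "MetabolicModel":
        return copy.deepcopy(self)

    # -- views -----------------------------------------------------------
    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for rxn in self.reactions.values():
            for g in sorted(rxn.gene_rule.genes()):
                seen.setdefault(g)
        return list(seen)

    @property
    def compartments(self) -> set[str]:
        return {m.compartment for m in self.metabolites.values()}

    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions.values() if r.kind == "exchange"]

    @property
    def objective(self) -> Reaction:
        if self.objective_id is None:
            raise ModelValidationError("model has no objective reaction")
        return self.reactions[self.objective_id]

    def metabolite_index(self) -> dict[str, int]:
        return {m: i for i, m in enumerate(self.metabolites)}

    def reaction_index(self) -> dict[str, int]:
        return {r: i for i, r in enumerate(self.reactions)}

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        """Check all structural invariants; raise on the first violation."""
        for rxn in self.reactions.values():
            if rxn.lower_bound > rxn.upper_bound:
                raise ModelValidationError(f"reaction {rxn.id!r}: inverted bounds")
            if rxn.kind == "exchange":
                if len(rxn.stoichiometry) != 1:
                    raise ModelValidationError(
                        f"exchange {rxn.id!r} must touch exactly one metabolite"
                    )
                (met_id,) = rxn.stoichiometry
                if self.metabolites[met_id].compartment != "e":
                    raise ModelValidationError(
                        f"exchange {rxn.id!r} metabolite {met_id!r} is not extracellular"
                    )
        if self.objective_id is not None and self.objective_id not in self.reactions:
            raise ModelValidationError(f"objective {self.objective_id!r} not in model")

    def __repr__(self) -> str:
        return (
            f"<MetabolicModel {self.id}: {len(self.metabolites)} metabolites, "
            f"{len(self.reactions)} reactions, {len(self.genes)} genes>"
        )


# -- module-level operations ----------------------------------------------

def stoichiometric_matrix(model: MetabolicModel) -> sparse.csc_matrix:
    """Sparse stoichiometric matrix S (metabolite instances x reactions).

    Rows follow ``model.metabolites`` order, columns ``model.reactions``
    order; S[i, j] is the signed coefficient of metabolite i in reaction
    j (negative = consumed).
    """
    met_idx = model.metabolite_index()
    rows, cols, vals = [], [], []
    for j, rxn in enumerate(model.reactions.values()):
        for met_id, coef in rxn.stoichiometry.items():
            rows.append(met_idx[met_id])
            cols.append(j)
            vals.append(float(coef))
    return sparse.csc_matrix(
        (vals, (rows, cols)), shape=(len(model.metabolites), len(model.reactions))
    )


def check_mass_balance(model: MetabolicModel) -> MassBalanceReport:
    """Audit element conservation for every internal reaction.

    Exchange, biomass, and demand reactions exchange matter with the
    environment (or lump macromolecular synthesis) and are exempt.
    Hydrogen imbalances are tolerated everywhere; every other element,
    including the carrier pseudo-element R, must balance exactly.
    """
    violations: list[tuple[str, str, Fraction]] = []
    unverifiable: list[str] = []
    for rxn in model.reactions.values():
        if rxn.kind in ("exchange", "biomass", "demand"):
            continue
        formulas = {}
        missing = False
        for met_id in rxn.stoichiometry:
            f = model.metabolites[met_id].formula
            if f is None:
                missing = True
                break
            formulas[met_id] = f
        if missing:
            unverifiable.append(rxn.id)
            continue
        net: dict[str, Fraction] = {}
        for met_id, coef in rxn.stoichiometry.items():
            for el, n in formulas[met_id].counts.items():
                net[el] = net.get(el, Fraction(0)) + Fraction(coef).limit_denominator(10**9) * n
        for el in sorted(net):
            if el != "H" and net[el] != 0:
                violations.append((rxn.id, el, net[el]))
    return MassBalanceReport(violations, unverifiable)


def _base_id(met_id: str) -> str:
    """Strip a trailing compartment suffix from a BiGG-style metabolite id."""
    for c in COMPARTMENTS:
        if met_id.endswith(f"_{c}"):
            return met_id[: -(len(c) + 1)]
    return met_id


def classify_reaction(model: MetabolicModel, rxn: Reaction) -> str:
    """Infer a reaction's kind from its structure (used by readers).

    Exchange: touches exactly one metabolite, in the extracellular
    compartment.  Transport: participants span at least two
    compartments.  Everything else is metabolic; biomass/maintenance/
    demand are annotations the reader may set from ids or roles.
    """
    mets = [model.metabolites[m] for m in rxn.stoichiometry]
    if len(mets) == 1 and mets[0].compartment == "e":
        return "exchange"
    if len({m.compartment for m in mets}) >= 2:
        return "transport"
    return "metabolic"


def model_statistics(model: MetabolicModel) -> ModelStatistics:
    """Counts of reactions by class and metabolites by instance/identity.

    Transport = non-exchange reaction whose participants span two or
    more compartments (recomputed structurally, not trusted from the
    stored ``kind``); unique metabolites collapse compartment copies.
    """
    n_ex = n_tr = n_met = n_bio = n_maint = n_dem = 0
    for rxn in model.reactions.values():
        if rxn.kind == "biomass":
            n_bio += 1
        elif rxn.kind == "maintenance":
            n_maint += 1
        elif rxn.kind == "demand":
            n_dem += 1
        else:
            cls = classify_reaction(model, rxn)
            if cls == "exchange":
                n_ex += 1
            elif cls == "transport":
                n_tr += 1
            else:
                n_met += 1
    unique = {_base_id(m) for m in model.metabolites}
    return ModelStatistics(
        n_reactions=len(model.reactions),
        n_metabolite_instances=len(model.metabolites),
        n_unique_metabolites=len(unique),
        n_genes=len(model.genes),
        n_exchange=n_ex,
        n_transport=n_tr,
        n_metabolic=n_met,
        n_biomass=n_bio,
        n_maintenance=n_maint,
        n_demand=n_dem,
    )
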