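"""Linear-programming core: FBA, FVA, deletions, blocked reactions.

Flux balance analysis solves

    max  c . v
    s.t. S v = 0,   lb <= v <= ub

where S is the stoichiometric matrix and the objective is usually the
biomass reaction, whose flux is the specific growth rate mu (1/h).  All
LPs go through scipy's HiGHS interface with a fixed, single-threaded
configuration so repeated runs return identical objective values even
when the optimal flux vector is degenerate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .model import MetabolicModel, Reaction, GeneRule, stoichiometric_matrix

__all__ = [
    "MediumSpec",
    "FluxSolution",
    "FvaResult",
    "InfeasibleError",
    "apply_medium",
    "optimize",
    "flux_variability",
    "blocked_reactions",
    "dead_end_metabolites",
    "evaluate_gene_rule",
    "knockout_reactions",
    "single_gene_deletion",
    "component_producibility",
    "max_product_at_growth",
]

# Conventional numerical tolerances: LP feasibility, and the flux level
# below which a reaction is considered unable to carry flux ("blocked",
# "no growth").
FEASIBILITY_TOL = 1e-9
ZERO_FLUX_TOL = 1e-6


class InfeasibleError(RuntimeError):
    """Raised when a base LP that an operation requires has no solution."""


@dataclass
class MediumSpec:
    """Growth-medium definition as exchange uptake caps.

    ``uptake_limits`` maps exchange-reaction id -> maximal uptake rate
    (mmol/gDW/h, non-negative).  Applying the medium sets each listed
    exchange's lower bound to ``-limit``, closes every unlisted exchange
    to uptake, and opens all exchanges to secretion at
    ``secretion_bound``.
    """

    uptake_limits: dict[str, float] = field(default_factory=dict)
    secretion_bound: float = 1000.0

    def __post_init__(self) -> None:
        for ex, lim in self.uptake_limits.items():
            if lim < 0:
                raise ValueError(f"uptake limit for {ex!r} must be non-negative")


@dataclass
class FluxSolution:
    status: str  # optimal | infeasible | unbounded
    objective_value: float | None
    fluxes: dict[str, float] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.status == "optimal"

    def __getitem__(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]


@dataclass
class FvaResult:
    """Per-reaction flux ranges at a stated fraction of the optimum."""

    fraction_of_optimum: float
    optimum: float
    ranges: dict[str, tuple[float, float]]

    def __getitem__(self, rxn_id: str) -> tuple[float, float]:
        return self.ranges[rxn_id]


def apply_medium(model: MetabolicModel, medium: MediumSpec) -> MetabolicModel:
    """Return a copy of the model constrained to the given medium."""
    exchange_ids = {r.id for r in model.exchanges()}
    unknown = set(medium.uptake_limits) - exchange_ids
    if unknown:
        raise ValueError(
            f"medium lists non-exchange ids {sorted(unknown)}; "
            f"valid exchanges: {sorted(exchange_ids)}"
        )
    out = model.copy()
    for rxn in out.reactions.values():
        if rxn.kind != "exchange":
            continue
        limit = medium.uptake_limits.get(rxn.id, 0.0)
        rxn.lower_bound = -float(limit)
        rxn.upper_bound = float(medium.secretion_bound)
    return out


_HIGHS_OPTIONS = {"presolve": True}


def _solve_lp(c, A_eq, b_eq, bounds, A_ub=None, b_ub=None):
    return linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
        options=_HIGHS_OPTIONS,
    )


def _lp_parts(model: MetabolicModel):
    S = stoichiometric_matrix(model)
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions.values()]
    return S, bounds


def optimize(
    model: MetabolicModel,
    objective: str | None = None,
    direction: str = "max",
    _extra_ub: tuple | None = None,
) -> FluxSolution:
    """Solve the FBA linear program for the given objective reaction.

    Infeasible or unbounded problems are reported through ``status``,
    never as silent zeros.  The returned objective value is the LP
    optimum, which is unique even when flux vectors are degenerate.
    """
    if direction not in ("max", "min"):
        raise ValueError("direction must be 'max' or 'min'")
    obj_id = objective if objective is not None else model.objective_id
    if obj_id is None or obj_id not in model.reactions:
        raise ValueError(f"objective reaction {obj_id!r} not in model")
    S, bounds = _lp_parts(model)
    rxn_ids = list(model.reactions)
    n = len(rxn_ids)
    c = np.zeros(n)
    c[rxn_ids.index(obj_id)] = -1.0 if direction == "max" else 1.0
    A_ub = b_ub = None
    if _extra_ub is not None:
        A_ub, b_ub = _extra_ub
    res = _solve_lp(c, S, np.zeros(S.shape[0]), bounds, A_ub, b_ub)
    if res.status == 2:
        return FluxSolution("infeasible", None)
    if res.status == 3:
        return FluxSolution("unbounded", None)
    if not res.success:
        raise RuntimeError(f"LP solver failure: {res.message}")
    sign = -1.0 if direction == "max" else 1.0
    fluxes = dict(zip(rxn_ids, res.x))
    return FluxSolution("optimal", sign * res.fun, fluxes)


def _growth_constraint_row(model: MetabolicModel, obj_id: str, floor: float):
    """Row enforcing objective >= floor, as A_ub x <= b_ub."""
    n = len(model.reactions)
    row = np.zeros((1, n))
    row[0, list(model.reactions).index(obj_id)] = -1.0
    return row, np.array([-floor])


def flux_variability(
    model: MetabolicModel,
    fraction_of_optimum: float = 1.0,
    reactions: Iterable[str] | None = None,
    objective: str | None = None,
) -> FvaResult:
    """Min and max flux per reaction with the objective held near its optimum.

    The objective is constrained to at least ``fraction_of_optimum``
    times its FBA maximum; at fraction 0 the ranges are those of the
    unconstrained flux cone within bounds.
    """
    if not 0.0 <= fraction_of_optimum <= 1.0:
        raise ValueError("fraction_of_optimum must lie in [0, 1]")
    obj_id = objective if objective is not None else model.objective_id
    base = optimize(model, objective=obj_id)
    if not base.ok:
        raise InfeasibleError(f"base FBA problem is {base.status}")
    S, bounds = _lp_parts(model)
    rxn_ids = list(model.reactions)
    targets = list(reactions) if reactions is not None else rxn_ids
    A_ub = b_ub = None
    if fraction_of_optimum > 0:
        A_ub, b_ub = _growth_constraint_row(
            model, obj_id, fraction_of_optimum * base.objective_value
        )
    ranges: dict[str, tuple[float, float]] = {}
    zeros = np.zeros(S.shape[0])
    for rid in targets:
        j = rxn_ids.index(rid)
        c = np.zeros(len(rxn_ids))
        c[j] = 1.0
        lo = _solve_lp(c, S, zeros, bounds, A_ub, b_ub)
        hi = _solve_lp(-c, S, zeros, bounds, A_ub, b_ub)
        if not (lo.success and hi.success):
            raise InfeasibleError(f"FVA subproblem for {rid!r} failed")
        vmin, vmax = lo.fun, -hi.fun
        if vmin > vmax:  # solver noise on a fixed flux
            vmin = vmax = 0.5 * (vmin + vmax)
        ranges[rid] = (vmin, vmax)
    return FvaResult(fraction_of_optimum, base.objective_value, ranges)


def blocked_reactions(model: MetabolicModel, tol: float = ZERO_FLUX_TOL) -> set[str]:
    """Reactions unable to carry flux with every exchange fully open.

    All exchange lower bounds are opened to -1000 and upper bounds to
    +1000 before testing, so a reaction is blocked only for structural
    reasons (gaps, dead ends), not because of the medium.
    """
    probe = model.copy()
    for rxn in probe.reactions.values():
        if rxn.kind == "exchange":
            rxn.lower_bound, rxn.upper_bound = -1000.0, 1000.0
    S, bounds = _lp_parts(probe)
    rxn_ids = list(probe.reactions)
    zeros = np.zeros(S.shape[0])
    blocked: set[str] = set()
    for j, rid in enumerate(rxn_ids):
        c = np.zeros(len(rxn_ids))
        c[j] = 1.0
        hi = _solve_lp(-c, S, zeros, bounds)
        if hi.success and -hi.fun > tol:
            continue
        lo = _solve_lp(c, S, zeros, bounds)
        if lo.success and lo.fun < -tol:
            continue
        blocked.add(rid)
    return blocked


def dead_end_metabolites(model: MetabolicModel) -> set[str]:
    """Metabolites that can only ever be produced or only ever consumed.

    Reversibility is honoured: a reversible reaction can both produce
    and consume each participant.  A metabolite touched by a single
    reaction is a dead end regardless of reversibility, since it has no
    partner reaction to cycle with.
    """
    can_produce: set[str] = set()
    can_consume: set[str] = set()
    touched: dict[str, set[str]] = {}
    for rxn in model.reactions.values():
        fwd = rxn.upper_bound > 0
        rev = rxn.lower_bound < 0
        for met_id, coef in rxn.stoichiometry.items():
            touched.setdefault(met_id, set()).add(rxn.id)
            if (coef > 0 and fwd) or (coef < 0 and rev):
                can_produce.add(met_id)
            if (coef < 0 and fwd) or (coef > 0 and rev):
                can_consume.add(met_id)
    dead: set[str] = set()
    for met_id in model.metabolites:
        rxns = touched.get(met_id, set())
        internal = {r for r in rxns if model.reactions[r].kind != "exchange"}
        has_exchange = len(rxns) > len(internal)
        if len(internal) <= 1 and not has_exchange:
            dead.add(met_id)
        elif not (met_id in can_produce and met_id in can_consume):
            dead.add(met_id)
    return dead


def evaluate_gene_rule(rule: GeneRule, knocked_out: Iterable[str] = ()) -> bool:
    """Boolean GPR value under a knockout set (empty rule is always true)."""
    return rule.evaluate(knocked_out)


def knockout_reactions(model: MetabolicModel, genes: Iterable[str]) -> set[str]:
    """Reactions disabled (GPR false) when the given genes are knocked out."""
    ko = set(genes)
    out = set()
    for rxn in model.reactions.values():
        if not rxn.gene_rule.is_empty and not rxn.gene_rule.evaluate(ko):
            out.add(rxn.id)
    return out


def apply_knockout(model: MetabolicModel, genes: Iterable[str]) -> MetabolicModel:
    """Copy of the model with all GPR-disabled reactions closed to zero flux."""
    out = model.copy()
    for rid in knockout_reactions(model, genes):
        rxn = out.reactions[rid]
        rxn.lower_bound = rxn.upper_bound = 0.0
    return out


def single_gene_deletion(
    model: MetabolicModel,
    genes: Iterable[str] | None = None,
    essentiality_threshold: float = ZERO_FLUX_TOL,
) -> dict[str, float]:
    """Growth rate after each single-gene knockout.

    For each gene, every reaction whose GPR evaluates false under the
    knockout has its bounds closed to zero, and the model is
    re-optimized.  Infeasible knockout problems are recorded as zero
    growth.  A gene is essential when its recorded growth falls below
    ``essentiality_threshold``.
    """
    gene_list = list(genes) if genes is not None else model.genes
    results: dict[str, float] = {}
    for g in gene_list:
        hit = knockout_reactions(model, {g})
        if not hit:
            if "_wt" not in results:
                wt = optimize(model)
                results["_wt"] = wt.objective_value if wt.ok else 0.0
            results[g] = results["_wt"]
            continue
        ko_model = model.copy()
        for rid in hit:
            rxn = ko_model.reactions[rid]
            rxn.lower_bound = rxn.upper_bound = 0.0
        sol = optimize(ko_model)
        results[g] = sol.objective_value if sol.ok else 0.0
    results.pop("_wt", None)
    return results


def essential_genes(
    model: MetabolicModel,
    genes: Iterable[str] | None = None,
    threshold: float = ZERO_FLUX_TOL,
) -> set[str]:
    growth = single_gene_deletion(model, genes)
    return {g for g, mu in growth.items() if mu < threshold}


def carrier_partner(model: MetabolicModel, component: str) -> str | None:
    """Released carrier paired with a charged biomass component, if any.

    Carrier-built monomers enter the biomass reaction in their charged
    form (amino-acyl tRNA, nucleotide sugar) and release the free
    carrier at the same coefficient; both forms share the carrier
    pseudo-element R.  For such components the meaningful producibility
    probe is the net charging conversion, not a bare demand (the
    carrier moiety is a conserved pool).
    """
    biomass = model.objective
    formula = model.metabolites[component].formula
    if formula is None or formula.count("R") == 0:
        return None
    consumed = biomass.stoichiometry.get(component, 0.0)
    if consumed >= 0:
        return None
    for met, coef in biomass.stoichiometry.items():
        if met == component or coef <= 0 or abs(coef + consumed) > 1e-9:
            continue
        partner = model.metabolites[met].formula
        if partner is not None and partner.count("R") == formula.count("R"):
            return met
    return None


def component_producibility(
    model: MetabolicModel,
    component: str,
    medium: MediumSpec | None = None,
    release: str | None = None,
) -> float:
    """Maximal production flux of one biomass component.

    A temporary demand reaction ``component ->`` (or the conversion
    ``component -> release`` for carrier-charged components, see
    :func:`carrier_partner`) is installed, maximized and removed; the
    optimum is returned (0 for an infeasible problem).  The component
    must be consumed by the biomass reaction.
    """
    biomass = model.objective
    if component not in biomass.stoichiometry:
        raise ValueError(f"{component!r} is not a biomass component")
    if biomass.stoichiometry[component] >= 0:
        raise ValueError(f"{component!r} is produced, not consumed, by biomass")
    probe = apply_medium(model, medium) if medium is not None else model.copy()
    dm_id = f"DM__{component}"
    stoich = {component: -1.0}
    if release is not None:
        stoich[release] = 1.0
    probe.add_reaction(
        Reaction(dm_id, stoich, lower_bound=0.0, upper_bound=1000.0, kind="demand")
    )
    sol = optimize(probe, objective=dm_id)
    return sol.objective_value if sol.ok else 0.0


def max_product_at_growth(
    model: MetabolicModel,
    medium: MediumSpec,
    product: str,
    growth_fraction: float = 0.95,
) -> FluxSolution:
    """Maximize a product's secretion with growth pinned near its optimum.

    Growth is constrained into ``[growth_fraction * mu*, mu*]`` and the
    product exchange flux maximized; the full flux vector is returned so
    co-produced metabolites can be read off.
    """
    if product not in model.reactions:
        raise ValueError(f"product exchange {product!r} not in model")
    constrained = apply_medium(model, medium)
    base = optimize(constrained)
    if not base.ok or base.objective_value <= ZERO_FLUX_TOL:
        raise InfeasibleError("model does not grow on the given medium")
    mu_star = base.objective_value
    biomass = constrained.objective
    biomass.lower_bound = growth_fraction * mu_star
    biomass.upper_bound = mu_star
    sol = optimize(constrained, objective=product)
    if not sol.ok:
        raise InfeasibleError(
            f"product maximization infeasible at growth fraction {growth_fraction}"
        )
    return sol
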