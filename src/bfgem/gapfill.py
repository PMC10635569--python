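"""Component-driven greedy gap filling against a universal reaction pool.

A draft reconstruction typically cannot synthesize every biomass
precursor.  Gap filling opens all exchanges, asks which biomass
components can be produced, and then greedily pulls reactions from a
universal pool (e.g. reactions collected from reference databases):
in each round the candidate that most increases the number of
producible components is added, ties broken by lexicographic reaction
id so the procedure is deterministic.  When no single reaction helps,
pairs of candidates are scored jointly (serial gaps need two insertions
at once) up to a configurable budget.  Added reactions carry no gene
rule and are flagged for downstream evidence review.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

from .fba import MediumSpec, ZERO_FLUX_TOL, component_producibility
from .model import MetabolicModel, ModelValidationError, Reaction

__all__ = [
    "UniversalReactionPool",
    "GapFillResult",
    "producible_components",
    "gap_fill",
]


@dataclass
class UniversalReactionPool:
    """Candidate reactions (no gene rules) with a provenance tag each."""

    reactions: list[Reaction]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen = set()
        for rxn in self.reactions:
            if rxn.id in seen:
                raise ModelValidationError(f"duplicate pool reaction id {rxn.id!r}")
            seen.add(rxn.id)

    def validate_against(self, model: MetabolicModel) -> None:
        clash = {r.id for r in self.reactions} & set(model.reactions)
        if clash:
            raise ModelValidationError(
                f"pool reaction ids already in model: {sorted(clash)}"
            )


@dataclass
class GapFillResult:
    added: list[str]
    producible_before: set[str]
    producible_after: set[str]
    unproducible: set[str]
    rounds: list[dict] = field(default_factory=list)

    @property
    def complete(self) -> bool:
        return not self.unproducible


def _open_exchanges(model: MetabolicModel) -> MetabolicModel:
    out = model.copy()
    for rxn in out.reactions.values():
        if rxn.kind == "exchange":
            rxn.lower_bound, rxn.upper_bound = -1000.0, 1000.0
    return out


def biomass_components(model: MetabolicModel) -> list[str]:
    """Metabolites the biomass reaction consumes, excluding GAM currency.

    The ATP-hydrolysis species of the growth-associated maintenance
    term are energetic bookkeeping, not precursors, and are skipped.
    """
    biomass = model.objective
    currency = set(biomass.notes.get("gam_metabolites", ()))
    return sorted(
        m for m, c in biomass.stoichiometry.items() if c < 0 and m not in currency
    )


def producible_components(
    model: MetabolicModel,
    medium: MediumSpec | None = None,
    threshold: float = ZERO_FLUX_TOL,
    open_exchanges: bool = True,
) -> set[str]:
    """Biomass components the network can synthesize.

    With no medium given and ``open_exchanges`` on, every exchange is
    opened to uptake at 1000 mmol/gDW/h; a stated medium is applied
    instead when given; with ``open_exchanges`` off the model's current
    bounds are used as-is.  Each component is probed with a temporary
    demand reaction (the charging conversion for carrier-coupled
    components) and counts as producible when its maximal production
    flux exceeds ``threshold``.
    """
    from .fba import carrier_partner

    if medium is not None:
        probe = model
    elif open_exchanges:
        probe = _open_exchanges(model)
    else:
        probe = model
    out = set()
    for comp in biomass_components(model):
        release = carrier_partner(model, comp)
        if component_producibility(probe, comp, medium=medium, release=release) > threshold:
            out.add(comp)
    return out


def _with_reactions(model: MetabolicModel, rxns: list[Reaction]) -> MetabolicModel:
    out = model.copy()
    for rxn in rxns:
        for met_id in rxn.stoichiometry:
            if met_id not in out.metabolites:
                raise ModelValidationError(
                    f"pool reaction {rxn.id!r} references metabolite {met_id!r} "
                    "absent from the model"
                )
        out.add_reaction(rxn)
    return out


def gap_fill(
    model: MetabolicModel,
    pool: UniversalReactionPool,
    medium: MediumSpec | None = None,
    try_pairs: bool = True,
    pair_budget: int = 200,
    threshold: float = ZERO_FLUX_TOL,
) -> GapFillResult:
    """Greedy component-count gap filling.

    Each round scores every remaining pool reaction by how many extra
    biomass components become producible when it is added; the best
    strictly-improving candidate (lexicographic tie-break) is kept.
    Reactions that only enlarge flux magnitudes are never added.  When
    no single candidate helps and ``try_pairs`` is on, unordered pairs
    are scored jointly, up to ``pair_budget`` pair evaluations per
    round.  Components still unproducible at termination are reported,
    not raised.
    """
    if not pool.reactions:
        raise ValueError("universal reaction pool is empty")
    pool.validate_against(model)
    current = model.copy()
    before = producible_components(current, medium=medium, threshold=threshold)
    all_components = set(biomass_components(current))
    producible = set(before)
    remaining = sorted(pool.reactions, key=lambda r: r.id)
    added: list[str] = []
    rounds: list[dict] = []

    while producible != all_components and remaining:
        best_gain, best_choice = 0, None
        for rxn in remaining:
            trial = _with_reactions(current, [rxn])
            gain = len(producible_components(trial, medium=medium, threshold=threshold)) - len(
                producible
            )
            if gain > best_gain or (
                gain == best_gain and gain > 0 and (rxn.id,) < tuple(r.id for r in best_choice)
            ):
                best_gain, best_choice = gain, (rxn,)
        if best_choice is None and try_pairs:
            budget = pair_budget
            for pair in combinations(remaining, 2):
                if budget <= 0:
                    break
                budget -= 1
                trial = _with_reactions(current, list(pair))
                gain = len(
                    producible_components(trial, medium=medium, threshold=threshold)
                ) - len(producible)
                if gain > best_gain or (
                    gain == best_gain
                    and gain > 0
                    and tuple(r.id for r in pair) < tuple(r.id for r in best_choice)
                ):
                    best_gain, best_choice = gain, pair
        if best_choice is None:
            break
        current = _with_reactions(current, list(best_choice))
        chosen_ids = [r.id for r in best_choice]
        chosen_set = set(chosen_ids)
        remaining = [r for r in remaining if r.id not in chosen_set]
        producible = producible_components(current, medium=medium, threshold=threshold)
        added.extend(chosen_ids)
        rounds.append(
            {"added": chosen_ids, "gain": best_gain, "producible": len(producible)}
        )

    return GapFillResult(
        added=added,
        producible_before=before,
        producible_after=producible,
        unproducible=all_components - producible,
        rounds=rounds,
    )
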