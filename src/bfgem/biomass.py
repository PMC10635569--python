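"""Biomass objective assembly from macromolecular composition data.

The biomass pseudo-reaction consumes monomer precursors in the measured
dry-weight proportions of the organism (protein, lipid, carbohydrate,
DNA, RNA, plus an unmeasured cofactor/mineral remainder) and its flux is
the specific growth rate mu.  Monomers built into polymers through
activated carriers (tRNAs for amino acids, nucleotide sugars for
carbohydrate units) are consumed in their carrier-charged form and the
free carrier is released, which forces flux through the charging
reactions and charges the cell the associated ATP cost.

Coefficients are normalized so that one flux unit of biomass consumes
exactly 1 gram of dry weight, using the molar mass of the *free*
monomer (the carrier moiety is cycled, not consumed, and weighs
nothing).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

from .model import (
    ElementalFormula,
    MetabolicModel,
    ModelValidationError,
    Reaction,
)

__all__ = [
    "MacroComposition",
    "MonomerDistribution",
    "CarrierMap",
    "BiomassSpec",
    "redistribute_missing",
    "equal_split_lipids",
    "build_biomass",
    "set_maintenance",
    "CURRENCY_METABOLITES",
]

STRUCTURAL_CATEGORIES = ("protein", "lipid", "carbohydrate", "DNA", "RNA")

# BiGG ids of the ATP-hydrolysis currency metabolites in the cytosol.
CURRENCY_METABOLITES = {
    "atp": "atp_c",
    "h2o": "h2o_c",
    "adp": "adp_c",
    "pi": "pi_c",
    "h": "h_c",
}


@dataclass
class MacroComposition:
    """Dry-weight mass fractions per macromolecular category.

    Measured categories need not sum to one; the remainder is taken to
    be the unmeasured cofactor, mineral, and small-metabolite
    contribution.
    """

    fractions: dict[str, float]

    def __post_init__(self) -> None:
        for cat, f in self.fractions.items():
            if f < 0:
                raise ValueError(f"negative mass fraction for {cat!r}")
        if sum(self.fractions.values()) > 1.0 + 1e-9:
            raise ValueError("measured mass fractions exceed 1")

    @property
    def remainder(self) -> float:
        return max(0.0, 1.0 - sum(self.fractions.values()))


@dataclass
class MonomerDistribution:
    """Within-category shares per monomer, on a mass or mole basis."""

    category: str
    shares: dict[str, float]
    basis: str = "mass"  # mass | mole

    def __post_init__(self) -> None:
        if self.basis not in ("mass", "mole"):
            raise ValueError("basis must be 'mass' or 'mole'")
        for met, s in self.shares.items():
            if s < 0:
                raise ValueError(f"negative share for {met!r}")

    def normalized(self) -> "MonomerDistribution":
        total = sum(self.shares.values())
        if total <= 0:
            raise ValueError(f"distribution for {self.category!r} sums to zero")
        return replace(self, shares={m: s / total for m, s in self.shares.items()})


# monomer id -> (charged carrier id, released carrier id)
CarrierMap = Mapping[str, tuple[str, str]]


@dataclass
class BiomassSpec:
    composition: MacroComposition
    distributions: list[MonomerDistribution]
    carriers: dict[str, tuple[str, str]] = field(default_factory=dict)
    gam: float = 0.0   # mmol ATP hydrolysed per gDW of biomass formed
    ngam: float = 0.0  # mmol ATP/gDW/h drained regardless of growth
    coefficients: dict[str, float] = field(default_factory=dict)


def redistribute_missing(
    dist: MonomerDistribution, missing: list[str]
) -> MonomerDistribution:
    """Spread unmeasured abundance equally over the unmeasured monomers.

    Composition assays often omit a few monomers (e.g. asparagine,
    glutamine, and tryptophan in acid-hydrolysis amino-acid data); the
    shortfall 1 - sum(measured) is divided equally between them.
    """
    s = sum(dist.shares.values())
    if s > 1.0 + 1e-9:
        raise ValueError(f"measured shares for {dist.category!r} sum to {s} > 1")
    if not missing:
        return dist
    per = (1.0 - s) / len(missing)
    shares = dict(dist.shares)
    for m in missing:
        shares[m] = shares.get(m, 0.0) + per
    return replace(dist, shares=shares)


def equal_split_lipids(
    category_fraction: float,
    chain_classes: Mapping[str, tuple[float, list[str]]],
) -> MonomerDistribution:
    """Turn per-chain-class lipid data into a per-species distribution.

    Lipid assays report the share of each chain length/desaturation
    class, not of individual species; each class's share is divided
    equally among the representative lipids modeled for that class.
    ``chain_classes`` maps class name -> (class share, representatives).
    Shares are normalized within the category and then scaled to the
    category's behaviour-neutral [0, 1] range (the category mass
    fraction itself lives in :class:`MacroComposition`).
    """
    total = sum(share for share, _ in chain_classes.values())
    if total <= 0:
        raise ValueError("lipid class shares sum to zero")
    shares: dict[str, float] = {}
    for cls, (share, reps) in chain_classes.items():
        if not reps:
            raise ValueError(f"lipid class {cls!r} has no representative species")
        per = (share / total) / len(reps)
        for lipid in reps:
            shares[lipid] = shares.get(lipid, 0.0) + per
    del category_fraction  # recorded in MacroComposition, kept for call symmetry
    return MonomerDistribution("lipid", shares, basis="mass")


def _free_monomer_mass(model: MetabolicModel, met_id: str) -> float:
    met = model.metabolites.get(met_id)
    if met is None:
        raise ModelValidationError(f"biomass monomer {met_id!r} not in model")
    if met.formula is None:
        raise ModelValidationError(f"biomass monomer {met_id!r} has no formula")
    mass = met.formula.mass
    if mass <= 0:
        raise ModelValidationError(f"biomass monomer {met_id!r} has zero molar mass")
    return mass


def monomer_millimoles(
    model: MetabolicModel, composition: MacroComposition, dist: MonomerDistribution
) -> dict[str, float]:
    """mmol of each monomer per gDW implied by one category's data."""
    frac = composition.fractions.get(dist.category)
    if frac is None:
        raise ValueError(f"composition has no fraction for {dist.category!r}")
    dist = dist.normalized()
    out: dict[str, float] = {}
    if dist.basis == "mass":
        for met, share in dist.shares.items():
            out[met] = 1000.0 * frac * share / _free_monomer_mass(model, met)
    else:
        mean_mass = sum(
            share * _free_monomer_mass(model, met) for met, share in dist.shares.items()
        )
        total_mmol = 1000.0 * frac / mean_mass
        for met, share in dist.shares.items():
            out[met] = total_mmol * share
    return out


def build_biomass(
    model: MetabolicModel,
    spec: BiomassSpec,
    biomass_id: str = "BIOMASS",
    currency: Mapping[str, str] = CURRENCY_METABOLITES,
) -> MetabolicModel:
    """Install the biomass objective reaction implied by a composition spec.

    Monomers with an entry in the carrier map are consumed in their
    charged-carrier form with the free carrier released at the same
    coefficient; all others are consumed free.  Coefficients are scaled
    so the free-monomer mass drawn per unit flux is exactly 1 g/gDW,
    then the growth-associated maintenance (GAM) ATP hydrolysis is added
    and the reaction is made the objective.
    """
    out = model.copy()
    mmol: dict[str, float] = {}
    for dist in spec.distributions:
        for met, v in monomer_millimoles(out, spec.composition, dist).items():
            mmol[met] = mmol.get(met, 0.0) + v
    if not mmol:
        raise ValueError("biomass spec yields no components")

    # normalize: sum over monomers of coeff * free MW == 1000 mg/gDW
    total_mass = sum(v * _free_monomer_mass(out, met) for met, v in mmol.items())
    scale = 1000.0 / total_mass
    coefficients = {met: v * scale for met, v in mmol.items()}

    stoich: dict[str, float] = {}
    for met, coeff in coefficients.items():
        carrier = spec.carriers.get(met)
        if carrier is None:
            stoich[met] = stoich.get(met, 0.0) - coeff
        else:
            charged, released = carrier
            for cid in (charged, released):
                if cid not in out.metabolites:
                    raise ModelValidationError(f"carrier metabolite {cid!r} not in model")
            stoich[charged] = stoich.get(charged, 0.0) - coeff
            stoich[released] = stoich.get(released, 0.0) + coeff

    if biomass_id in out.reactions:
        out.remove_reaction(biomass_id)
    rxn = Reaction(
        biomass_id,
        stoich,
        lower_bound=0.0,
        upper_bound=1000.0,
        name="Biomass objective",
        kind="biomass",
    )
    out.add_reaction(rxn)
    out.objective_id = biomass_id
    spec.coefficients = coefficients
    return set_maintenance(out, spec.gam, spec.ngam, currency=currency)


def set_maintenance(
    model: MetabolicModel,
    gam: float,
    ngam: float,
    ngam_id: str = "ATPM",
    currency: Mapping[str, str] = CURRENCY_METABOLITES,
) -> MetabolicModel:
    """Install ATP maintenance costs.

    GAM (mmol ATP/gDW) is written into the biomass reaction as
    ``gam ATP + gam H2O -> gam ADP + gam Pi + gam H`` on top of the
    biosynthetic coefficients; NGAM (mmol ATP/gDW/h) is enforced as a
    dedicated ATP-hydrolysis reaction whose lower bound pins the drain.
    Calling again replaces the previous values.
    """
    if gam < 0 or ngam < 0:
        raise ValueError("maintenance coefficients must be non-negative")
    out = model.copy()
    missing = [m for m in currency.values() if m not in out.metabolites]
    if missing:
        raise ModelValidationError(f"currency metabolites absent from model: {missing}")
    atp, h2o, adp, pi, h = (currency[k] for k in ("atp", "h2o", "adp", "pi", "h"))

    biomass = out.objective
    previous = biomass.notes.get("gam", 0.0)
    delta = gam - previous
    for met, sign in ((atp, -1.0), (h2o, -1.0), (adp, +1.0), (pi, +1.0), (h, +1.0)):
        coeff = biomass.stoichiometry.get(met, 0.0) + sign * delta
        if abs(coeff) < 1e-12:
            biomass.stoichiometry.pop(met, None)
        else:
            biomass.stoichiometry[met] = coeff
    biomass.notes["gam"] = gam
    # currency species of the GAM term: maintenance bookkeeping, not precursors
    biomass.notes["gam_metabolites"] = [atp, h2o, adp, pi, h]

    if ngam_id not in out.reactions:
        out.add_reaction(
            Reaction(
                ngam_id,
                {atp: -1.0, h2o: -1.0, adp: 1.0, pi: 1.0, h: 1.0},
                lower_bound=ngam,
                upper_bound=1000.0,
                name="Non-growth ATP maintenance",
                kind="maintenance",
            )
        )
    else:
        out.reactions[ngam_id].lower_bound = ngam
    return out
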