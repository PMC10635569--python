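"""Headline analyses: nutrient screens, fermentation envelopes, carbon
balance, growth efficiency, co-metabolism, and supplementation scans.

These pipelines reproduce the standard interrogations of a curated
anaerobe model: which nutrients raise the growth rate (validated
against experimental utilization calls as sensitivity/specificity),
how much of each fermentation product can be secreted at a nearly
optimal growth rate, where the carbon goes, how efficiently each
substrate's carbon is turned into biomass, and how fermentation-product
and amino-acid mixtures reshape growth and gene essentiality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd

from .fba import (
    MediumSpec,
    FluxSolution,
    ZERO_FLUX_TOL,
    apply_medium,
    component_producibility,
    knockout_reactions,
    max_product_at_growth,
    optimize,
    single_gene_deletion,
)
from .gapfill import biomass_components, producible_components
from .model import MetabolicModel

__all__ = [
    "ScreenResult",
    "EnvelopeTable",
    "CarbonBalance",
    "EfficiencyResult",
    "CoMetabolismResult",
    "nutrient_screen",
    "fermentation_envelope",
    "carbon_balance",
    "growth_efficiency",
    "co_metabolism",
    "supplementation_scan",
    "VFA_MIX",
]

# Fermentation-product mixture used in co-metabolism simulations.
VFA_MIX = ("EX_ac_e", "EX_ppa_e", "EX_but_e", "EX_etoh_e", "EX_pyr_e")


def _exchange_carbon(model: MetabolicModel, ex_id: str) -> Fraction:
    rxn = model.reactions[ex_id]
    (met_id,) = rxn.stoichiometry
    formula = model.metabolites[met_id].formula
    if formula is None:
        raise ValueError(f"exchanged metabolite {met_id!r} has no formula")
    return formula.count("C")


@dataclass
class ScreenResult:
    table: pd.DataFrame  # per-nutrient delta mu, call, experimental label
    base_mu: float
    sensitivity: float | None
    specificity: float | None
    untestable: list[str] = field(default_factory=list)


def nutrient_screen(
    model: MetabolicModel,
    base_medium: MediumSpec,
    nutrients: list[str],
    per_nutrient_uptake: float = 20.0,
    growth_threshold: float = 0.01,
    experimental: dict[str, bool] | None = None,
) -> ScreenResult:
    """Growth with and without each nutrient added to a base medium.

    A nutrient is called positive when the growth-rate increase is at
    least ``growth_threshold`` (1/h).  If experimental utilization
    calls are supplied, sensitivity TP/(TP+FN) and specificity
    TN/(TN+FP) are computed over testable nutrients.
    """
    exchange_ids = {r.id for r in model.exchanges()}
    base_sol = optimize(apply_medium(model, base_medium))
    base_mu = base_sol.objective_value if base_sol.ok else 0.0
    rows, untestable = [], []
    for nut in nutrients:
        if nut not in exchange_ids:
            untestable.append(nut)
            continue
        limits = dict(base_medium.uptake_limits)
        limits[nut] = max(limits.get(nut, 0.0), per_nutrient_uptake)
        sol = optimize(apply_medium(model, MediumSpec(limits, base_medium.secretion_bound)))
        mu = sol.objective_value if sol.ok else 0.0
        delta = mu - base_mu
        rows.append(
            {
                "nutrient": nut,
                "mu_with": mu,
                "delta_mu": delta,
                "predicted_growth": delta >= growth_threshold,
                "experimental_growth": None if experimental is None else experimental.get(nut),
            }
        )
    table = pd.DataFrame(rows).set_index("nutrient") if rows else pd.DataFrame()
    sens = spec = None
    if experimental is not None and len(table):
        labeled = table.dropna(subset=["experimental_growth"])
        exp = labeled["experimental_growth"].astype(bool)
        pred = labeled["predicted_growth"].astype(bool)
        tp = int((pred & exp).sum())
        fn = int((~pred & exp).sum())
        tn = int((~pred & ~exp).sum())
        fp = int((pred & ~exp).sum())
        sens = tp / (tp + fn) if tp + fn else None
        spec = tn / (tn + fp) if tn + fp else None
    return ScreenResult(table, base_mu, sens, spec, untestable)


@dataclass
class EnvelopeTable:
    """Fermentation-product output rates at a pinned growth window.

    Row i = fluxes of every listed product (columns) when product i's
    secretion is the quantity being maximized; the diagonal is each
    product's attainable maximum.  Off-diagonal entries are one optimal
    vertex among possibly many (solver degeneracy), so only the
    diagonal is a reproducible point value.
    """

    table: pd.DataFrame
    growth_window: tuple[float, float]
    carbon: pd.DataFrame


def fermentation_envelope(
    model: MetabolicModel,
    medium: MediumSpec,
    products: list[str],
    growth_fraction: float = 0.95,
    include_co2: str | None = "EX_co2_e",
) -> EnvelopeTable:
    """Maximize each product with growth pinned to near-optimal.

    CO2 is appended to the reported columns when present in the model.
    A product whose pathway is absent or incomplete simply maximizes to
    zero; that is a model phenotype, not an error.
    """
    cols = list(products)
    if include_co2 and include_co2 in model.reactions and include_co2 not in cols:
        cols.append(include_co2)
    base = optimize(apply_medium(model, medium))
    if not base.ok or base.objective_value <= ZERO_FLUX_TOL:
        raise ValueError("model does not grow on the given medium")
    mu_star = base.objective_value
    rows = {}
    carbon_rows = {}
    for prod in products:
        sol = max_product_at_growth(model, medium, prod, growth_fraction)
        rows[prod] = {c: max(0.0, sol.fluxes.get(c, 0.0)) for c in cols}
        cb = carbon_balance(model, sol)
        carbon_rows[prod] = {
            "carbon_in": cb.carbon_in,
            "carbon_out_products": cb.carbon_out,
            "carbon_in_biomass": cb.carbon_biomass,
            "fraction_to_products": cb.fraction_to_products,
        }
    table = pd.DataFrame.from_dict(rows, orient="index")[cols]
    return EnvelopeTable(
        table,
        (growth_fraction * mu_star, mu_star),
        pd.DataFrame.from_dict(carbon_rows, orient="index"),
    )


@dataclass
class CarbonBalance:
    carbon_in: float          # C-mmol/gDW/h entering through exchanges
    carbon_out: float         # C-mmol/gDW/h leaving as secreted products
    carbon_biomass: float     # balance: fixed into biomass at steady state
    fraction_to_products: float


def carbon_balance(model: MetabolicModel, solution: FluxSolution) -> CarbonBalance:
    """Carbon accounting of a flux solution over the exchange reactions.

    Influx = sum over uptaking exchanges of |flux| x carbon count;
    product efflux likewise over secreting exchanges; at steady state
    the difference is the carbon fixed into biomass.
    """
    c_in = c_out = 0.0
    for rxn in model.exchanges():
        v = solution.fluxes.get(rxn.id, 0.0)
        if abs(v) <= ZERO_FLUX_TOL:
            continue
        ncarbon = float(_exchange_carbon(model, rxn.id))
        if ncarbon == 0:
            continue
        if v < 0:
            c_in += -v * ncarbon
        else:
            c_out += v * ncarbon
    return CarbonBalance(
        carbon_in=c_in,
        carbon_out=c_out,
        carbon_biomass=c_in - c_out,
        fraction_to_products=(c_out / c_in) if c_in > 0 else 0.0,
    )


@dataclass
class EfficiencyResult:
    substrate: str
    carbon_per_molecule: float
    uptake_bound: float        # mmol/gDW/h, = total C flux / carbon count
    realized_carbon_uptake: float  # C-mmol/gDW/h actually drawn
    mu: float
    efficiency: float          # growth per unit of carbon taken up


def growth_efficiency(
    model: MetabolicModel,
    substrate: str,
    base_medium: MediumSpec | None = None,
    total_c_flux: float = 120.0,
) -> EfficiencyResult:
    """Biomass yield per C-mmol of one substrate.

    The substrate's exchange is capped at ``total_c_flux`` divided by
    its carbon count, so every substrate is offered the same carbon
    flux; the efficiency is growth divided by the carbon actually taken
    up.  A substrate the model cannot catabolize scores 0.
    """
    ncarbon = float(_exchange_carbon(model, substrate))
    if ncarbon == 0:
        raise ValueError(f"substrate {substrate!r} contains no carbon")
    bound = total_c_flux / ncarbon
    limits = dict(base_medium.uptake_limits) if base_medium else {}
    limits[substrate] = bound
    sol = optimize(apply_medium(model, MediumSpec(limits)))
    mu = sol.objective_value if sol.ok else 0.0
    realized = -sol.fluxes.get(substrate, 0.0) * ncarbon if sol.ok else 0.0
    efficiency = mu / realized if realized > ZERO_FLUX_TOL else 0.0
    return EfficiencyResult(substrate, ncarbon, bound, max(0.0, realized), mu, efficiency)


@dataclass
class CoMetabolismResult:
    growth: pd.DataFrame        # carbon source x regime -> mu
    improved: pd.DataFrame      # carbon source x regime -> bool (vs "none")
    essential: dict[tuple[str, str], set[str]]       # (source, regime) -> genes
    blocked_components: dict[tuple[str, str], dict[str, int]]
    differential: dict[tuple[str, str, str], set[str]]  # (source, A, B) -> essential(A)-essential(B)


REGIMES = ("none", "VFA", "AA", "both")


def co_metabolism(
    model: MetabolicModel,
    carbon_sources: list[str],
    vfa_mix: tuple[str, ...] = VFA_MIX,
    aa_mix: tuple[str, ...] = (),
    base_medium: MediumSpec | None = None,
    cap: float = 20.0,
    improvement_threshold: float = 0.001,
    essentiality: bool = True,
    aa_cap: float | None = None,
) -> CoMetabolismResult:
    """Growth and essentiality across supplement regimes.

    For each carbon source the model is simulated with neither mixture,
    the fermentation-product (VFA) mixture, the amino-acid mixture, or
    both, each member capped at ``cap`` mmol/gDW/h (``aa_cap`` may
    lower the amino-acid cap separately).  A regime improves growth
    when mu rises by more than ``improvement_threshold`` over the bare
    source.  With ``essentiality`` on, single-gene deletions are run
    per source x regime and each essential gene is scored by how many
    biomass components its knockout leaves unproducible.
    """
    vfa = [x for x in vfa_mix if x in model.reactions]
    aas = [x for x in aa_mix if x in model.reactions]
    base_limits = dict(base_medium.uptake_limits) if base_medium else {}

    def regime_medium(source: str | None, regime: str) -> MediumSpec:
        limits = dict(base_limits)
        if source is not None:
            limits[source] = cap
        if regime in ("VFA", "both"):
            for x in vfa:
                limits[x] = max(limits.get(x, 0.0), cap)
        if regime in ("AA", "both"):
            for x in aas:
                limits[x] = max(limits.get(x, 0.0), aa_cap if aa_cap is not None else cap)
        return MediumSpec(limits)

    growth_rows, improved_rows = {}, {}
    essential: dict[tuple[str, str], set[str]] = {}
    blocked: dict[tuple[str, str], dict[str, int]] = {}
    for source in carbon_sources:
        mus = {}
        for regime in REGIMES:
            medium = regime_medium(source, regime)
            constrained = apply_medium(model, medium)
            sol = optimize(constrained)
            mu = sol.objective_value if sol.ok else 0.0
            mus[regime] = mu
            if essentiality and mu > ZERO_FLUX_TOL:
                deletions = single_gene_deletion(constrained)
                ess = {g for g, m in deletions.items() if m < ZERO_FLUX_TOL}
                essential[(source, regime)] = ess
                counts: dict[str, int] = {}
                for g in sorted(ess):
                    ko = constrained.copy()
                    for rid in knockout_reactions(constrained, {g}):
                        rxn = ko.reactions[rid]
                        rxn.lower_bound = rxn.upper_bound = 0.0
                    producible = producible_components(
                        ko, open_exchanges=False, threshold=ZERO_FLUX_TOL
                    )
                    counts[g] = len(set(biomass_components(ko)) - producible)
                blocked[(source, regime)] = counts
        growth_rows[source] = mus
        improved_rows[source] = {
            r: (mus[r] - mus["none"]) > improvement_threshold for r in REGIMES
        }

    differential: dict[tuple[str, str, str], set[str]] = {}
    if essentiality:
        for source in carbon_sources:
            for a in REGIMES:
                for b in REGIMES:
                    if a != b and (source, a) in essential and (source, b) in essential:
                        differential[(source, a, b)] = essential[(source, a)] - essential[(source, b)]
    return CoMetabolismResult(
        growth=pd.DataFrame.from_dict(growth_rows, orient="index")[list(REGIMES)],
        improved=pd.DataFrame.from_dict(improved_rows, orient="index")[list(REGIMES)],
        essential=essential,
        blocked_components=blocked,
        differential=differential,
    )


def supplementation_scan(
    model: MetabolicModel,
    medium: MediumSpec,
    products: list[str],
    supplement_c_flux: float = 10.0,
    growth_fraction: float = 0.95,
    supplements: list[str] | None = None,
    ratio_pair: tuple[str, str] = ("EX_ac_e", "EX_ppa_e"),
) -> pd.DataFrame:
    """Rank carbon supplements by how much they raise each product maximum.

    Each candidate supplement (every carbon-containing model exchange
    by default) is added to the medium at an uptake bound of
    ``supplement_c_flux`` divided by its carbon count, the fermentation
    envelope diagonal is recomputed, and the change versus the
    unsupplemented medium is reported, together with the shift in the
    acetate:propionate ratio when both exchanges exist.  Carbon-free
    candidates are excluded (the carbon-flux scaling is undefined for
    them) unless passed explicitly in ``supplements``.
    """
    if supplements is None:
        supplements = [
            r.id for r in model.exchanges() if _exchange_carbon(model, r.id) > 0
        ]

    def diagonal(med: MediumSpec) -> dict[str, float]:
        out = {}
        for prod in products:
            sol = max_product_at_growth(model, med, prod, growth_fraction)
            out[prod] = max(0.0, sol.fluxes.get(prod, 0.0))
        return out

    def ratio(diag: dict[str, float]) -> float | None:
        a, p = ratio_pair
        if a in diag and p in diag and diag[p] > ZERO_FLUX_TOL:
            return diag[a] / diag[p]
        return None

    base_diag = diagonal(medium)
    base_ratio = ratio(base_diag)
    rows = []
    for supp in supplements:
        ncarbon = float(_exchange_carbon(model, supp))
        bound = supplement_c_flux / ncarbon if ncarbon > 0 else supplement_c_flux
        limits = dict(medium.uptake_limits)
        limits[supp] = limits.get(supp, 0.0) + bound
        diag = diagonal(MediumSpec(limits, medium.secretion_bound))
        row = {"supplement": supp, "uptake_bound": bound}
        for prod in products:
            row[f"delta_{prod}"] = diag[prod] - base_diag[prod]
        r = ratio(diag)
        row["acetate_propionate_ratio"] = r
        row["ratio_shift"] = (r - base_ratio) if (r is not None and base_ratio is not None) else None
        rows.append(row)
    df = pd.DataFrame(rows).set_index("supplement")
    for prod in products:
        df[f"rank_{prod}"] = df[f"delta_{prod}"].rank(ascending=False, method="min").astype(int)
    return df
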