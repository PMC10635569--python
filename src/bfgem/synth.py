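"""Synthetic fixtures: toy fermentation networks with known LP optima.

The flagship fixture is a toy anaerobic fermenter that mirrors the
topology of saccharolytic gut bacteria: one carbohydrate enters, a
lumped glycolysis yields pyruvate and substrate-level ATP, pyruvate is
either spilled to fermentation exits (acetate with extra ATP, lactate,
ethanol) or drawn into biosynthesis of three biomass precursors (an
amino acid built onto a tRNA-like carrier, a representative lipid, a
cell-wall carbohydrate unit).  Every optimum is derivable in closed
form, so the LP engine, the biomass builder, and the maintenance
calibrator can all be checked against pencil-and-paper values.

Closed-form growth law (ATP-limited regime)
-------------------------------------------
Let U be the substrate uptake (mmol/gDW/h) and a, l, c the biomass
coefficients (mmol/gDW) of the amino acid, lipid, and carbohydrate
component.  Glycolysis yields 2 ATP and 2 pyruvate per glucose, the
acetate exit yields 1 ATP per pyruvate, and biosynthesis costs
2a + 2l + c ATP and a + 4l pyruvate plus c glucose per gDW.  Sending
all spare pyruvate through the acetate exit and balancing ATP gives

    mu = (4 U - NGAM) / (GAM + 3 a + 6 l + 5 c)

valid while spare pyruvate 2(U - c mu) - (a + 4 l) mu >= 0, i.e. while
ATP rather than carbon limits growth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .biomass import BiomassSpec, MacroComposition, MonomerDistribution, build_biomass
from .calibration import GrowthObservation, predict_mu
from .fba import MediumSpec
from .gapfill import UniversalReactionPool, producible_components
from .model import Metabolite, MetabolicModel, Reaction

__all__ = [
    "ToySpec",
    "toy_fermenter",
    "toy_medium",
    "toy_biomass_spec",
    "expected_growth",
    "expected_max_product",
    "make_gapped",
    "synth_calibration",
    "composition_fixture",
    "toy_chain",
    "toy_parallel",
    "toy_branch",
]

# fermentation branch catalogue: id -> (gene rule, ATP yield per pyruvate)
_BRANCHES = [("ac", "g_ack", 1.0), ("lac", "g_ldh1 or g_ldh2", 0.0), ("etoh", "g_pdc", 0.0)]


@dataclass
class ToySpec:
    """Parameters of the toy fermenter.

    ``n_branches`` selects fermentation exits in the fixed order
    acetate (ATP-yielding), lactate, ethanol.  ``gam``/``ngam`` are the
    maintenance coefficients installed at construction;
    ``include_periplasm`` routes substrate import through a periplasmic
    intermediate so transport classification is exercised.
    """

    seed: int = 0
    n_branches: int = 2
    include_periplasm: bool = False
    supplement_exchanges: bool = False
    gam: float = 24.9
    ngam: float = 38.9
    uptake: float = 20.0
    composition: dict[str, float] = field(
        default_factory=lambda: {"protein": 0.55, "lipid": 0.25, "carbohydrate": 0.15}
    )

    def __post_init__(self) -> None:
        if not 1 <= self.n_branches <= len(_BRANCHES):
            raise ValueError(f"n_branches must be in [1, {len(_BRANCHES)}]")


def toy_biomass_spec(spec: ToySpec) -> BiomassSpec:
    comp = MacroComposition(dict(spec.composition))
    dists = [
        MonomerDistribution("protein", {"aa_c": 1.0}, basis="mass"),
        MonomerDistribution("lipid", {"lip_c": 1.0}, basis="mass"),
        MonomerDistribution("carbohydrate", {"carb_c": 1.0}, basis="mass"),
    ]
    carriers = {"aa_c": ("aatrna_c", "trna_c")}
    return BiomassSpec(comp, dists, carriers, gam=spec.gam, ngam=spec.ngam)


def toy_medium(spec: ToySpec) -> MediumSpec:
    """Minimal glucose/ammonia medium for the toy, water freely exchanged."""
    return MediumSpec(
        {"EX_glc_e": spec.uptake, "EX_nh3_e": 1000.0, "EX_h2o_e": 1000.0}
    )


def toy_fermenter(spec: ToySpec | None = None) -> MetabolicModel:
    """Build the toy fermenter (20-40 reactions, all optima closed-form)."""
    spec = spec or ToySpec()
    m = MetabolicModel(model_id=f"toy_fermenter_seed{spec.seed}")

    def met(mid, formula, comp):
        m.add_metabolite(Metabolite(mid, mid, comp, formula))

    met("glc_e", "C6H12O6", "e")
    if spec.include_periplasm:
        met("glc_p", "C6H12O6", "p")
    met("glc_c", "C6H12O6", "c")
    met("nh3_e", "H3N", "e")
    met("nh3_c", "H3N", "c")
    met("h2o_e", "H2O", "e")
    met("h2o_c", "H2O", "c")
    met("h_e", "H", "e")
    met("h_c", "H", "c")
    met("pyr_c", "C3H4O3", "c")
    met("atp_c", "RPO3", "c")
    met("adp_c", "R", "c")
    met("pi_c", "HO4P", "c")
    met("co2_c", "CO2", "c")
    met("co2_e", "CO2", "e")
    met("aa_c", "C3H7NO2", "c")
    met("trna_c", "R", "c")
    met("aatrna_c", "C3H6NOR", "c")
    met("lip_c", "C10H16O6", "c")
    met("carb_c", "C6H10O5", "c")
    branch_formulas = {"ac": "C2H4O2", "lac": "C3H6O3", "etoh": "C2H6O"}
    branches = _BRANCHES[: spec.n_branches]
    for name, _, _ in branches:
        met(f"{name}_c", branch_formulas[name], "c")
        met(f"{name}_e", branch_formulas[name], "e")

    def rxn(rid, stoich, lb, ub, gpr="", kind="metabolic", name=""):
        m.add_reaction(
            Reaction(rid, stoich, lb, ub, name=name or rid, gene_rule=gpr, kind=kind)
        )

    # exchanges (default bounds; media override these)
    rxn("EX_glc_e", {"glc_e": -1}, -spec.uptake, 1000, kind="exchange")
    rxn("EX_nh3_e", {"nh3_e": -1}, -1000, 1000, kind="exchange")
    rxn("EX_h2o_e", {"h2o_e": -1}, -1000, 1000, kind="exchange")
    rxn("EX_h_e", {"h_e": -1}, 0, 1000, kind="exchange")
    rxn("EX_co2_e", {"co2_e": -1}, 0, 1000, kind="exchange")
    for name, _, _ in branches:
        rxn(f"EX_{name}_e", {f"{name}_e": -1}, 0, 1000, kind="exchange")

    # transport
    if spec.include_periplasm:
        rxn("GLCt_pp", {"glc_e": -1, "glc_p": 1}, 0, 1000, gpr="g_glct1 or g_glct2")
        rxn("GLCt_cp", {"glc_p": -1, "glc_c": 1}, 0, 1000, gpr="g_glct3")
    else:
        rxn("GLCt", {"glc_e": -1, "glc_c": 1}, 0, 1000, gpr="g_glct1 or g_glct2")
    rxn("NH3t", {"nh3_e": -1, "nh3_c": 1}, 0, 1000)
    rxn("H2Ot", {"h2o_e": -1, "h2o_c": 1}, -1000, 1000)
    rxn("Ht", {"h_c": -1, "h_e": 1}, 0, 1000)
    rxn("CO2t", {"co2_c": -1, "co2_e": 1}, 0, 1000)
    for name, _, _ in branches:
        rxn(f"{name.upper()}t", {f"{name}_c": -1, f"{name}_e": 1}, 0, 1000)

    # lumped glycolysis: glc + 2 ADP + 2 Pi -> 2 pyr + 2 ATP + 2 H2O
    rxn(
        "GLYC",
        {"glc_c": -1, "adp_c": -2, "pi_c": -2, "pyr_c": 2, "atp_c": 2, "h2o_c": 2},
        0, 1000, gpr="g_glyc1 and g_glyc2", name="Glycolysis (lumped)",
    )
    # fermentation exits from pyruvate
    rxn("ACK", {"pyr_c": -1, "adp_c": -1, "pi_c": -1, "ac_c": 1, "co2_c": 1, "atp_c": 1},
        0, 1000, gpr="g_ack", name="Acetate exit (substrate-level ATP)")
    if spec.n_branches >= 2:
        rxn("LDH", {"pyr_c": -1, "lac_c": 1}, 0, 1000, gpr="g_ldh1 or g_ldh2",
            name="Lactate exit")
    if spec.n_branches >= 3:
        rxn("PDC", {"pyr_c": -1, "etoh_c": 1, "co2_c": 1}, 0, 1000, gpr="g_pdc",
            name="Ethanol exit")

    # biosynthesis
    rxn("AAS", {"pyr_c": -1, "nh3_c": -1, "atp_c": -1, "aa_c": 1, "adp_c": 1, "pi_c": 1},
        0, 1000, gpr="g_aas", name="Amino acid synthesis")
    rxn("TRNACH",
        {"aa_c": -1, "atp_c": -1, "trna_c": -1, "aatrna_c": 1, "adp_c": 1, "pi_c": 1},
        0, 1000, gpr="g_trna", name="tRNA charging")
    rxn("LIPS",
        {"pyr_c": -4, "atp_c": -2, "lip_c": 1, "adp_c": 2, "pi_c": 2, "co2_c": 2},
        0, 1000, gpr="g_lips", name="Lipid synthesis")
    rxn("CARBS", {"glc_c": -1, "atp_c": -1, "carb_c": 1, "adp_c": 1, "pi_c": 1},
        0, 1000, gpr="g_carbs", name="Cell-wall carbohydrate synthesis")

    if spec.supplement_exchanges:
        # co-metabolism machinery: acetate can re-enter and feed lipid
        # synthesis (at a steep ATP cost, so glucose routes stay optimal
        # on minimal medium), and the amino acid can be imported directly.
        m.reactions["ACt"].lower_bound = -1000.0
        rxn("LIPSA",
            {"ac_c": -5, "atp_c": -8, "h2o_c": -4,
             "lip_c": 1, "adp_c": 8, "pi_c": 8},
            0, 1000, gpr="g_lipsa", name="Lipid synthesis from acetate")
        met("aa_e", "C3H7NO2", "e")
        rxn("EX_aa_e", {"aa_e": -1}, 0, 1000, kind="exchange")
        rxn("AAt", {"aa_e": -1, "aa_c": 1}, 0, 1000)

    m = build_biomass(m, toy_biomass_spec(spec))
    m.validate()
    return m


def _biomass_coeffs(model: MetabolicModel) -> tuple[float, float, float]:
    biomass = model.objective
    a = -biomass.stoichiometry["aatrna_c"]
    l = -biomass.stoichiometry["lip_c"]
    c = -biomass.stoichiometry["carb_c"]
    return a, l, c


def expected_growth(
    model: MetabolicModel, uptake: float, gam: float, ngam: float
) -> float:
    """Closed-form optimal growth rate of the toy (ATP-limited regime).

    mu = (4 U - NGAM) / (GAM + 3a + 6l + 5c); raises if the parameters
    leave the ATP-limited regime the formula assumes.
    """
    a, l, c = _biomass_coeffs(model)
    mu = (4.0 * uptake - ngam) / (gam + 3.0 * a + 6.0 * l + 5.0 * c)
    mu = max(mu, 0.0)
    spare = 2.0 * (uptake - c * mu) - (a + 4.0 * l) * mu
    if spare < -1e-9:
        raise ValueError("parameters leave the ATP-limited regime; no closed form")
    return mu


def expected_max_product(
    model: MetabolicModel,
    uptake: float,
    gam: float,
    ngam: float,
    product: str,
    growth_fraction: float = 0.95,
) -> float:
    """Closed-form product maximum at a pinned growth rate.

    At mu = growth_fraction * mu(opt), spare pyruvate is
    2(U - c mu) - (a + 4l) mu; the acetate exit must run at whatever
    rate closes the ATP balance, and the rest of the spare pyruvate is
    free.  Maximal acetate routes everything through the ATP-yielding
    exit (the surplus ATP is burned by the maintenance reaction);
    maximal lactate/ethanol routes everything except the ATP-mandated
    acetate flux.
    """
    a, l, c = _biomass_coeffs(model)
    mu = growth_fraction * expected_growth(model, uptake, gam, ngam)
    spare = 2.0 * (uptake - c * mu) - (a + 4.0 * l) * mu
    # ATP balance: 2 G + v_ack = (2a + 2l + c + gam) mu + ngam
    g_flux = uptake - c * mu
    v_ack = (2 * a + 2 * l + c + gam) * mu + ngam - 2.0 * g_flux
    v_ack = max(v_ack, 0.0)
    if product == "EX_ac_e":
        return spare
    if product in ("EX_lac_e", "EX_etoh_e"):
        return spare - v_ack
    raise ValueError(f"no closed form for product {product!r}")


def toy_chain(uptake: float = 10.0) -> MetabolicModel:
    """Minimal linear chain: EX_S -> transport -> S doubling -> biomass.

    Uptake binds at ``uptake`` and the doubling step makes the biomass
    optimum exactly ``2 * uptake``; useful as the smallest LP sanity
    fixture (4 metabolites, 4 reactions plus biomass).
    """
    m = MetabolicModel(model_id="toy_chain")
    m.add_metabolite(Metabolite("s_e", "substrate", "e", "C2H4O2"))
    m.add_metabolite(Metabolite("s_c", "substrate", "c", "C2H4O2"))
    m.add_metabolite(Metabolite("p_c", "precursor", "c", "CH2O"))
    m.add_reaction(Reaction("EX_s_e", {"s_e": -1}, -uptake, 1000, kind="exchange"))
    m.add_reaction(Reaction("St", {"s_e": -1, "s_c": 1}, 0, 1000, gene_rule="g_t"))
    m.add_reaction(
        Reaction("SPLIT", {"s_c": -1, "p_c": 2}, 0, 1000, gene_rule="g_split")
    )
    m.add_reaction(
        Reaction("BIOMASS", {"p_c": -1}, 0, 1000, kind="biomass")
    )
    m.objective_id = "BIOMASS"
    m.validate()
    return m


def toy_parallel(uptake: float = 10.0) -> MetabolicModel:
    """Chain with a duplicated internal step: degenerate optimal vertices.

    The objective optimum is ``uptake`` however flux splits between the
    duplicates; used to check that degenerate optima are handled and
    that FVA reports the full [0, uptake] range per duplicate.
    """
    m = MetabolicModel(model_id="toy_parallel")
    m.add_metabolite(Metabolite("a_e", "a", "e", "CH2O"))
    m.add_metabolite(Metabolite("a_c", "a", "c", "CH2O"))
    m.add_metabolite(Metabolite("b_c", "b", "c", "CH2O"))
    m.add_reaction(Reaction("EX_a_e", {"a_e": -1}, -uptake, 1000, kind="exchange"))
    m.add_reaction(Reaction("At", {"a_e": -1, "a_c": 1}, 0, 1000))
    m.add_reaction(Reaction("D1", {"a_c": -1, "b_c": 1}, 0, 1000))
    m.add_reaction(Reaction("D2", {"a_c": -1, "b_c": 1}, 0, 1000))
    m.add_reaction(Reaction("BIOMASS", {"b_c": -1}, 0, 1000, kind="biomass"))
    m.objective_id = "BIOMASS"
    return m


def toy_branch(uptake: float = 10.0, rich_cap: float = 4.0) -> MetabolicModel:
    """Two competing branches of unequal yield, the richer one capped.

    Optimum mixes branches: 3*rich_cap + 2*(uptake - rich_cap) when the
    cap binds, so the LP must trade capacity against yield.
    """
    m = MetabolicModel(model_id="toy_branch")
    m.add_metabolite(Metabolite("a_e", "a", "e", "C6H12O6"))
    m.add_metabolite(Metabolite("a_c", "a", "c", "C6H12O6"))
    m.add_metabolite(Metabolite("b_c", "b", "c", "C2H4O2"))
    m.add_reaction(Reaction("EX_a_e", {"a_e": -1}, -uptake, 1000, kind="exchange"))
    m.add_reaction(Reaction("At", {"a_e": -1, "a_c": 1}, 0, 1000))
    m.add_reaction(Reaction("LOW", {"a_c": -1, "b_c": 2}, 0, 1000))
    m.add_reaction(Reaction("RICH", {"a_c": -1, "b_c": 3}, 0, rich_cap))
    m.add_reaction(Reaction("BIOMASS", {"b_c": -1}, 0, 1000, kind="biomass"))
    m.objective_id = "BIOMASS"
    return m


def make_gapped(
    model: MetabolicModel,
    removed_ids: list[str] | None = None,
    n_remove: int = 1,
    seed: int = 0,
    n_decoys: int = 5,
) -> tuple[MetabolicModel, UniversalReactionPool]:
    """Remove biosynthetic reactions and return the gapped model + pool.

    The pool contains the removed reactions (stripped of gene rules,
    as universal-database entries carry none) plus seeded decoy
    reactions over fresh dead-end metabolites that can never help.
    A removal that blocks no biomass component triggers a warning.
    """
    import warnings

    synthesis = [
        r.id
        for r in model.reactions.values()
        if r.kind == "metabolic" and model.objective_id
        and set(r.stoichiometry) & set(model.objective.stoichiometry)
    ]
    rng = np.random.default_rng(seed)
    if removed_ids is None:
        # prefer removals that actually orphan a biomass component
        baseline = producible_components(model)
        chosen: list[str] = []
        for rid in rng.permutation(synthesis).tolist():
            trial = model.copy()
            trial.remove_reaction(rid)
            if producible_components(trial) != baseline:
                chosen.append(rid)
            if len(chosen) == n_remove:
                break
        removed_ids = sorted(chosen) or sorted(
            rng.choice(synthesis, size=n_remove, replace=False).tolist()
        )
    for rid in removed_ids:
        if model.reactions[rid].kind == "exchange":
            raise ValueError(f"cannot gap an exchange reaction ({rid!r})")

    before = producible_components(model)
    gapped = model.copy()
    pool_rxns = []
    for rid in removed_ids:
        rxn = gapped.remove_reaction(rid)
        pool_rxns.append(
            Reaction(rxn.id, dict(rxn.stoichiometry), rxn.lower_bound, rxn.upper_bound,
                     name=rxn.name, kind=rxn.kind)
        )
    after = producible_components(gapped)
    if before == after:
        warnings.warn(f"removing {removed_ids} blocked no biomass component")

    provenance = {r.id: "removed" for r in pool_rxns}
    for i in range(n_decoys):
        a_id, b_id = f"decoy{i}a_c", f"decoy{i}b_c"
        for mid in (a_id, b_id):
            if mid not in gapped.metabolites:
                gapped.add_metabolite(Metabolite(mid, mid, "c", "C2H4O2"))
        coef = float(rng.integers(1, 3))
        rid = f"DECOY{i}"
        pool_rxns.append(Reaction(rid, {a_id: -coef, b_id: coef}, 0, 1000))
        provenance[rid] = "decoy"
    pool_rxns.sort(key=lambda r: r.id)
    return gapped, UniversalReactionPool(pool_rxns, provenance)


def synth_calibration(
    model: MetabolicModel,
    gam: float,
    ngam: float,
    media: list[tuple[str, MediumSpec]],
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> list[GrowthObservation]:
    """Generate growth observations from known maintenance coefficients.

    Observed rates are the model's own predictions at (gam, ngam),
    optionally perturbed by multiplicative Gaussian noise of relative
    standard deviation ``noise_sigma``.  Media where the model cannot
    grow are excluded with a warning; a single usable medium triggers
    an identifiability warning (two unknowns, one equation).
    """
    import warnings

    rng = np.random.default_rng(seed)
    out: list[GrowthObservation] = []
    for label, medium in media:
        mu = predict_mu(model, gam, ngam, medium)
        if mu <= 1e-9:
            warnings.warn(f"medium {label!r} supports no growth; excluded")
            continue
        if noise_sigma > 0:
            mu *= max(1e-6, 1.0 + noise_sigma * rng.standard_normal())
        out.append(GrowthObservation(label, medium, mu))
    if len(out) == 1:
        warnings.warn(
            "single growth observation: GAM and NGAM are confounded "
            "(two unknowns, one equation)"
        )
    return out


def composition_fixture(seed: int = 0):
    """Random composition tables + a skeleton model that can host them.

    Returns ``(spec, model)``: category fractions that deliberately sum
    to less than one (the rest is the unmeasured cofactor/mineral
    remainder), an amino-acid table missing three monomers (the classic
    asparagine/glutamine/tryptophan gap, to exercise redistribution), a
    lipid chain-class table, and a tRNA-style carrier map for one amino
    acid.  The skeleton model holds every referenced metabolite with a
    formula plus the ATP-hydrolysis currency metabolites.
    """
    from .biomass import equal_split_lipids, redistribute_missing

    rng = np.random.default_rng(seed)
    base = np.array([0.52, 0.22, 0.12, 0.04, 0.06])  # protein lipid carb DNA RNA
    jitter = rng.uniform(-0.02, 0.02, size=5)
    fracs = np.clip(base + jitter, 0.01, None)
    fracs *= rng.uniform(0.90, 0.97) / fracs.sum()  # keep a positive remainder
    comp = MacroComposition(
        dict(zip(("protein", "lipid", "carbohydrate", "DNA", "RNA"), map(float, fracs)))
    )

    aa_ids = ["ala_x_c", "gly_x_c", "glu_x_c", "asn_x_c", "gln_x_c", "trp_x_c"]
    measured = rng.dirichlet(np.ones(3)) * rng.uniform(0.85, 0.95)
    aa_table = MonomerDistribution(
        "protein", dict(zip(aa_ids[:3], map(float, measured))), basis="mass"
    )
    protein = redistribute_missing(aa_table, aa_ids[3:])

    lipid_classes = {
        "c16:0": (float(rng.uniform(0.3, 0.6)), ["lip160a_c", "lip160b_c"]),
        "c18:1": (float(rng.uniform(0.2, 0.5)), ["lip181_c"]),
    }
    lipid = equal_split_lipids(comp.fractions["lipid"], lipid_classes)

    carb = MonomerDistribution("carbohydrate", {"glcn_c": 1.0}, basis="mass")
    dna = MonomerDistribution(
        "DNA",
        dict(zip(["damp_c", "dcmp_c", "dgmp_c", "dtmp_c"], map(float, rng.dirichlet(np.ones(4))))),
        basis="mole",
    )
    rna = MonomerDistribution(
        "RNA",
        dict(zip(["amp_c", "cmp_c", "gmp_c", "ump_c"], map(float, rng.dirichlet(np.ones(4))))),
        basis="mole",
    )
    carriers = {"ala_x_c": ("alatrna_x_c", "trna_x_c")}
    spec = BiomassSpec(comp, [protein, lipid, carb, dna, rna], carriers)

    formulas = {
        "ala_x_c": "C3H7NO2", "gly_x_c": "C2H5NO2", "glu_x_c": "C5H9NO4",
        "asn_x_c": "C4H8N2O3", "gln_x_c": "C5H10N2O3", "trp_x_c": "C11H12N2O2",
        "lip160a_c": "C37H74NO8P", "lip160b_c": "C35H68O10P",
        "lip181_c": "C41H78NO8P",
        "glcn_c": "C6H10O5",
        "damp_c": "C10H14N5O6P", "dcmp_c": "C9H14N3O7P",
        "dgmp_c": "C10H14N5O7P", "dtmp_c": "C10H15N2O8P",
        "amp_c": "C10H14N5O7P", "cmp_c": "C9H14N3O8P",
        "gmp_c": "C10H14N5O8P", "ump_c": "C9H13N2O9P",
        "alatrna_x_c": "C3H6NOR", "trna_x_c": "R",
        "atp_c": "C10H16N5O13P3", "adp_c": "C10H15N5O10P2",
        "pi_c": "HO4P", "h2o_c": "H2O", "h_c": "H",
    }
    skeleton = MetabolicModel(model_id=f"composition_skeleton_seed{seed}")
    for mid, formula in formulas.items():
        skeleton.add_metabolite(Metabolite(mid, mid, "c", formula))
    return spec, skeleton
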