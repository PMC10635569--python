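"""Analysis workflows: screen, envelope, carbon balance, efficiency,
co-metabolism, supplementation."""

from __future__ import annotations

import numpy as np
import pytest

from bfgem.biomass import set_maintenance
from bfgem.fba import MediumSpec, apply_medium, flux_variability, optimize
from bfgem.synth import (
    ToySpec,
    expected_growth,
    expected_max_product,
    toy_fermenter,
    toy_medium,
)
from bfgem.workflows import (
    carbon_balance,
    co_metabolism,
    fermentation_envelope,
    growth_efficiency,
    nutrient_screen,
    supplementation_scan,
)

MINERAL_BASE = MediumSpec({"EX_nh3_e": 1000.0, "EX_h2o_e": 1000.0})


@pytest.fixture(scope="module")
def supplemented_toy():
    return toy_fermenter(ToySpec(supplement_exchanges=True))


class TestNutrientScreen:
    def test_sole_carbon_source_called_positive(self, toy):
        res = nutrient_screen(toy, MINERAL_BASE, ["EX_glc_e"])
        assert bool(res.table.loc["EX_glc_e", "predicted_growth"])

    def test_unimportable_product_called_negative(self, toy):
        # lactate's transporter only exports, so the nutrient cannot help
        res = nutrient_screen(toy, MINERAL_BASE, ["EX_lac_e"])
        assert not bool(res.table.loc["EX_lac_e", "predicted_growth"])

    def test_saturating_nutrient_called_negative(self, toy, toy_spec):
        res = nutrient_screen(toy, toy_medium(toy_spec), ["EX_nh3_e"])
        assert res.table.loc["EX_nh3_e", "delta_mu"] == pytest.approx(0.0, abs=1e-8)
        assert not bool(res.table.loc["EX_nh3_e", "predicted_growth"])

    def test_missing_exchange_reported_untestable(self, toy):
        res = nutrient_screen(toy, MINERAL_BASE, ["EX_ghost_e", "EX_glc_e"])
        assert res.untestable == ["EX_ghost_e"]
        assert list(res.table.index) == ["EX_glc_e"]

    def test_confusion_matrix_aggregates(self, toy):
        labels = {"EX_glc_e": True, "EX_lac_e": True, "EX_co2_e": False}
        res = nutrient_screen(
            toy, MINERAL_BASE, list(labels), experimental=labels
        )
        # glc: TP; lac: FN (no import path); co2: TN
        assert res.sensitivity == pytest.approx(0.5)
        assert res.specificity == pytest.approx(1.0)


class TestFermentationEnvelope:
    def test_diagonal_matches_closed_form(self, toy, toy_spec):
        env = fermentation_envelope(
            toy, toy_medium(toy_spec), ["EX_ac_e", "EX_lac_e"], growth_fraction=0.95
        )
        for prod in ("EX_ac_e", "EX_lac_e"):
            assert env.table.loc[prod, prod] == pytest.approx(
                expected_max_product(toy, toy_spec.uptake, toy_spec.gam, toy_spec.ngam, prod),
                abs=1e-6,
            )

    def test_diagonal_dominates_column(self, toy, toy_spec):
        env = fermentation_envelope(
            toy, toy_medium(toy_spec), ["EX_ac_e", "EX_lac_e"], growth_fraction=0.95
        )
        for prod in ("EX_ac_e", "EX_lac_e"):
            assert env.table[prod].max() <= env.table.loc[prod, prod] + 1e-8

    def test_single_branch_collapses_envelope(self):
        spec = ToySpec(n_branches=1)
        model = toy_fermenter(spec)
        env = fermentation_envelope(model, toy_medium(spec), ["EX_ac_e"])
        assert list(env.table.index) == ["EX_ac_e"]
        assert env.table.loc["EX_ac_e", "EX_ac_e"] > 0

    def test_growth_fraction_one_rows_identical_when_unique(self, chain):
        env = fermentation_envelope(
            chain, MediumSpec({"EX_s_e": 10.0}), ["EX_s_e"], growth_fraction=1.0,
            include_co2=None,
        )
        # single pathway: the only row equals the FBA point
        assert env.growth_window[0] == pytest.approx(env.growth_window[1])

    def test_absent_pathway_reports_zero_not_error(self, toy, toy_spec):
        # a product with an exchange but no complete synthesis pathway
        # (the butyrate situation) maximizes to zero instead of failing
        from bfgem.model import Metabolite, Reaction

        model = toy.copy()
        model.add_metabolite(Metabolite("but_e", "butyrate", "e", "C4H8O2"))
        model.add_reaction(Reaction("EX_but_e", {"but_e": -1}, 0, 1000, kind="exchange"))
        env = fermentation_envelope(model, toy_medium(toy_spec), ["EX_but_e", "EX_ac_e"])
        assert env.table.loc["EX_but_e", "EX_but_e"] == pytest.approx(0.0, abs=1e-6)
        assert env.table.loc["EX_ac_e", "EX_ac_e"] > 0

    def test_co2_column_appended(self, toy, toy_spec):
        env = fermentation_envelope(toy, toy_medium(toy_spec), ["EX_ac_e"])
        assert "EX_co2_e" in env.table.columns

    def test_no_growth_medium_raises(self, toy):
        with pytest.raises(ValueError, match="does not grow"):
            fermentation_envelope(toy, MINERAL_BASE, ["EX_ac_e"])


class TestCarbonBalance:
    def test_full_recovery_without_growth(self, toy, toy_spec):
        # force zero growth: all carbon in must come back out
        resting = set_maintenance(toy, 0.0, 0.0)
        resting.objective.upper_bound = 0.0
        constrained = apply_medium(resting, toy_medium(toy_spec))
        sol = optimize(constrained, objective="EX_ac_e")
        cb = carbon_balance(resting, sol)
        assert cb.carbon_out == pytest.approx(cb.carbon_in, rel=1e-9)
        assert cb.fraction_to_products == pytest.approx(1.0, rel=1e-9)

    def test_steady_state_identity_against_biomass_composition(self, toy, toy_spec):
        """Carbon not secreted equals the biomass carbon demand mu * sum(coeff * C)."""
        sol = optimize(apply_medium(toy, toy_medium(toy_spec)))
        cb = carbon_balance(toy, sol)
        biomass = toy.objective
        carbon_per_gdw = sum(
            -coef * float(toy.metabolites[met].formula.count("C"))
            for met, coef in biomass.stoichiometry.items()
            if coef < 0 and toy.metabolites[met].formula is not None
        )
        assert cb.carbon_biomass == pytest.approx(
            carbon_per_gdw * sol.objective_value, rel=1e-9
        )
        assert cb.carbon_in == pytest.approx(6 * toy_spec.uptake, rel=1e-9)

    def test_envelope_rows_conserve_carbon(self, toy, toy_spec):
        env = fermentation_envelope(toy, toy_medium(toy_spec), ["EX_ac_e", "EX_lac_e"])
        total = env.carbon["carbon_out_products"] + env.carbon["carbon_in_biomass"]
        assert np.allclose(total, env.carbon["carbon_in"], rtol=1e-9)


class TestGrowthEfficiency:
    def test_uptake_bound_scales_with_carbon_count(self, toy):
        row = growth_efficiency(toy, "EX_glc_e", base_medium=MINERAL_BASE)
        assert row.carbon_per_molecule == 6
        assert row.uptake_bound == pytest.approx(20.0)

    def test_uncatabolizable_substrate_scores_zero(self, toy):
        row = growth_efficiency(toy, "EX_lac_e", base_medium=MINERAL_BASE)
        assert row.efficiency == 0.0

    def test_carbon_free_substrate_rejected(self, toy):
        with pytest.raises(ValueError, match="no carbon"):
            growth_efficiency(toy, "EX_nh3_e", base_medium=MINERAL_BASE)

    def test_efficiency_value_consistent_with_closed_form(self, toy, toy_spec):
        row = growth_efficiency(toy, "EX_glc_e", base_medium=MINERAL_BASE)
        mu = expected_growth(toy, 20.0, toy_spec.gam, toy_spec.ngam)
        assert row.mu == pytest.approx(mu, abs=1e-8)
        assert row.efficiency == pytest.approx(mu / 120.0, rel=1e-6)

    def test_linear_scaling_invariance_without_fixed_drain(self, toy):
        # with NGAM = 0 the LP is scale-invariant, so efficiency is too
        linear = set_maintenance(toy, 24.9, 0.0)
        eff1 = growth_efficiency(linear, "EX_glc_e", base_medium=MINERAL_BASE,
                                 total_c_flux=120.0).efficiency
        eff2 = growth_efficiency(linear, "EX_glc_e", base_medium=MINERAL_BASE,
                                 total_c_flux=240.0).efficiency
        assert eff1 == pytest.approx(eff2, rel=1e-9)


@pytest.fixture(scope="module")
def result(supplemented_toy):
    return co_metabolism(
        supplemented_toy,
        ["EX_glc_e", "EX_lac_e"],
        aa_mix=("EX_aa_e",),
        base_medium=MINERAL_BASE,
        essentiality=True,
    )


class TestCoMetabolism:
    def test_amino_acids_raise_growth_on_glucose(self, result, supplemented_toy):
        mus = result.growth.loc["EX_glc_e"]
        assert mus["AA"] > mus["none"] + 0.001
        assert bool(result.improved.loc["EX_glc_e", "AA"])

    def test_carbon_only_mixture_cannot_help_when_atp_limits(self, result):
        """Fermentation products add carbon the cell already spills, so the
        ATP-limited optimum is unchanged and no essentiality shifts."""
        mus = result.growth.loc["EX_glc_e"]
        assert mus["VFA"] == pytest.approx(mus["none"], abs=1e-8)
        assert not bool(result.improved.loc["EX_glc_e", "VFA"])
        assert result.essential[("EX_glc_e", "VFA")] == result.essential[("EX_glc_e", "none")]

    def test_amino_acid_uptake_rescues_biosynthesis_gene(self, result):
        assert result.differential[("EX_glc_e", "none", "AA")] == {"g_aas"}
        assert result.differential[("EX_glc_e", "AA", "none")] == set()

    def test_blocked_component_counts_shrink_with_amino_acids(self, result):
        none_counts = result.blocked_components[("EX_glc_e", "none")]
        aa_counts = result.blocked_components[("EX_glc_e", "AA")]
        assert none_counts["g_aas"] == 1          # only the charged carrier
        assert "g_aas" not in aa_counts           # no longer essential
        assert len(aa_counts) < len(none_counts)  # essential-gene count drops
        for gene, count in aa_counts.items():     # shared genes block no more
            assert count <= none_counts[gene]

    def test_growth_rates_match_amino_acid_closed_form(self, result, supplemented_toy):
        # with free amino acid import the synthesis pyruvate+ATP cost drops:
        # mu = (4U - NGAM) / (GAM + a + 6l + 5c)
        biomass = supplemented_toy.objective
        a = -biomass.stoichiometry["aatrna_c"]
        l = -biomass.stoichiometry["lip_c"]
        c = -biomass.stoichiometry["carb_c"]
        mu_aa = (4 * 20.0 - 38.9) / (24.9 + a + 6 * l + 5 * c)
        assert result.growth.loc["EX_glc_e", "AA"] == pytest.approx(mu_aa, abs=1e-8)

    def test_non_importable_source_never_grows(self, result):
        assert result.growth.loc["EX_lac_e"].abs().max() < 1e-8


class TestSupplementationScan:
    def test_self_supplement_equals_raised_bound(self, toy, toy_spec):
        """Adding the base carbon source at 10 C-mmol/gDW/h is the same as
        raising its uptake bound by 10/6 mmol/gDW/h."""
        medium = toy_medium(toy_spec)
        scan = supplementation_scan(
            toy, medium, ["EX_ac_e"], supplement_c_flux=10.0,
            supplements=["EX_glc_e"],
        )
        raised = MediumSpec(dict(medium.uptake_limits))
        raised.uptake_limits["EX_glc_e"] += 10.0 / 6.0
        env_base = fermentation_envelope(toy, medium, ["EX_ac_e"])
        env_up = fermentation_envelope(toy, raised, ["EX_ac_e"])
        expected_delta = (
            env_up.table.loc["EX_ac_e", "EX_ac_e"] - env_base.table.loc["EX_ac_e", "EX_ac_e"]
        )
        assert scan.loc["EX_glc_e", "delta_EX_ac_e"] == pytest.approx(expected_delta, abs=1e-6)

    def test_supplements_never_decrease_product_maxima(self, toy, toy_spec):
        scan = supplementation_scan(toy, toy_medium(toy_spec), ["EX_ac_e", "EX_lac_e"])
        for prod in ("EX_ac_e", "EX_lac_e"):
            assert (scan[f"delta_{prod}"] >= -1e-8).all()

    def test_best_supplement_ranked_first(self, toy, toy_spec):
        scan = supplementation_scan(toy, toy_medium(toy_spec), ["EX_ac_e"])
        best = scan["delta_EX_ac_e"].idxmax()
        assert scan.loc[best, "rank_EX_ac_e"] == 1
        assert best == "EX_glc_e"  # the only catabolizable carbon source
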