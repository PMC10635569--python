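"""Model data structures, formats, and formula-level QC."""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import pytest

from bfgem.fba import optimize
from bfgem.io import ParseError, parse_equation, read_model, read_spreadsheet_model, write_model
from bfgem.model import (
    ElementalFormula,
    GeneRule,
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
    check_mass_balance,
    model_statistics,
    stoichiometric_matrix,
)


class TestElementalFormula:
    @pytest.mark.parametrize(
        "text, element, count",
        [
            ("C6H12O6", "C", 6),
            ("C6H12O6", "O", 6),
            ("R", "R", 1),
            ("C3H6NOR", "R", 1),
            ("HO4P", "P", 1),
            ("C17.5H32O2", "C", Fraction(35, 2)),
            ("C35/2H32O2", "C", Fraction(35, 2)),
        ],
    )
    def test_parse_counts(self, text, element, count):
        assert ElementalFormula.parse(text).count(element) == Fraction(count)

    def test_carrier_pseudo_element_has_zero_mass(self):
        assert ElementalFormula.parse("R").mass == 0.0
        with_r = ElementalFormula.parse("C3H7NO2R").mass
        without = ElementalFormula.parse("C3H7NO2").mass
        assert with_r == pytest.approx(without)

    def test_glucose_molar_mass(self):
        assert ElementalFormula.parse("C6H12O6").mass == pytest.approx(180.156, abs=0.01)

    @pytest.mark.parametrize("bad", ["", "6C", "Xx3", "C-2"])
    def test_rejects_malformed(self, bad):
        with pytest.raises(ValueError):
            ElementalFormula.parse(bad)

    def test_string_round_trip(self):
        for text in ["C6H12O6", "C3H6NOR", "HO4P", "C10H14N5O6P"]:
            f = ElementalFormula.parse(text)
            assert ElementalFormula.parse(str(f)).counts == f.counts


class TestGeneRule:
    @pytest.mark.parametrize(
        "rule, ko, expected",
        [
            ("g1 or g2", {"g1"}, True),        # isozyme survives
            ("g1 and g2", {"g1"}, False),      # complex dies
            ("", {"g1"}, True),                # no association, unaffected
            ("(g1 and g2) or g3", {"g1"}, True),
            ("(g1 and g2) or g3", {"g1", "g3"}, False),
            ("g1 or g2", {"g1", "g2"}, False),
        ],
    )
    def test_evaluate(self, rule, ko, expected):
        assert GeneRule.parse(rule).evaluate(ko) is expected

    def test_genes_and_string_round_trip(self):
        rule = GeneRule.parse("(gA and gB) or gC")
        assert rule.genes() == {"gA", "gB", "gC"}
        assert GeneRule.parse(rule.to_string()) == rule

    def test_malformed_rule_raises_at_parse_time(self):
        with pytest.raises(ModelValidationError):
            GeneRule.parse("g1 and (g2 or")


class TestModelInvariants:
    def test_duplicate_ids_rejected(self, chain):
        with pytest.raises(ModelValidationError):
            chain.add_reaction(Reaction("St", {"s_e": -1, "s_c": 1}, 0, 1000))

    def test_unknown_metabolite_rejected(self, chain):
        with pytest.raises(ModelValidationError):
            chain.add_reaction(Reaction("BAD", {"ghost_c": -1}, 0, 1000))

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ModelValidationError):
            Reaction("X", {}, lower_bound=1.0, upper_bound=-1.0)

    def test_exchange_must_be_extracellular_single_metabolite(self):
        m = MetabolicModel()
        m.add_metabolite(Metabolite("x_c", "x", "c"))
        m.add_reaction(Reaction("EX_x", {"x_c": -1}, -10, 1000, kind="exchange"))
        with pytest.raises(ModelValidationError):
            m.validate()

    def test_gene_list_is_union_of_rule_leaves(self, toy):
        leaves = set()
        for rxn in toy.reactions.values():
            leaves |= rxn.gene_rule.genes()
        assert set(toy.genes) == leaves


class TestStoichiometricMatrix:
    def test_column_matches_definition(self):
        m = MetabolicModel()
        m.add_metabolite(Metabolite("a_c", "a", "c"))
        m.add_metabolite(Metabolite("b_c", "b", "c"))
        m.add_reaction(Reaction("R1", {"a_c": -1, "b_c": 2}, 0, 1000))
        S = stoichiometric_matrix(m).toarray()
        assert S[:, 0].tolist() == [-1.0, 2.0]

    def test_exchange_columns_have_unit_support(self, toy):
        S = stoichiometric_matrix(toy).tocsc()
        rxn_ids = list(toy.reactions)
        for rxn in toy.exchanges():
            col = S[:, rxn_ids.index(rxn.id)]
            assert col.nnz == 1

    def test_steady_state_residual_of_fba_solution(self, toy_on_glucose):
        sol = optimize(toy_on_glucose)
        S = stoichiometric_matrix(toy_on_glucose)
        v = np.array([sol.fluxes[r] for r in toy_on_glucose.reactions])
        assert np.max(np.abs(S @ v)) < 1e-6


class TestMassBalance:
    @staticmethod
    def _two_met_model(prod_coeff: float):
        m = MetabolicModel()
        m.add_metabolite(Metabolite("glc_c", "glucose", "c", "C6H12O6"))
        m.add_metabolite(Metabolite("lac_c", "lactate", "c", "C3H6O3"))
        m.add_reaction(Reaction("SPLIT", {"glc_c": -1, "lac_c": prod_coeff}, 0, 1000))
        return m

    def test_balanced_split_passes(self):
        assert check_mass_balance(self._two_met_model(2.0)).ok

    def test_imbalanced_split_reports_carbon_and_oxygen(self):
        report = check_mass_balance(self._two_met_model(1.0))
        found = {(el, imb) for _, el, imb in report.violations}
        assert ("C", Fraction(-3)) in found
        assert ("O", Fraction(-3)) in found

    def test_hydrogen_exempt(self):
        m = MetabolicModel()
        m.add_metabolite(Metabolite("a_c", "a", "c", "C2H6O"))
        m.add_metabolite(Metabolite("b_c", "b", "c", "C2H4O"))
        m.add_reaction(Reaction("DH", {"a_c": -1, "b_c": 1}, 0, 1000))
        assert check_mass_balance(m).ok

    def test_carrier_cycling_balances_r(self, toy):
        # tRNA charging moves the R moiety from free to charged carrier
        assert check_mass_balance(toy).ok

    def test_unknown_formula_reported_as_unverifiable(self):
        m = MetabolicModel()
        m.add_metabolite(Metabolite("a_c", "a", "c", "C2H6O"))
        m.add_metabolite(Metabolite("b_c", "b", "c", None))
        m.add_reaction(Reaction("X", {"a_c": -1, "b_c": 1}, 0, 1000))
        report = check_mass_balance(m)
        assert report.ok and report.unverifiable == ["X"]


class TestModelStatistics:
    def test_toy_counts_by_construction(self, toy):
        stats = model_statistics(toy)
        n_classified = (
            stats.n_exchange + stats.n_transport + stats.n_metabolic
            + stats.n_biomass + stats.n_maintenance + stats.n_demand
        )
        assert n_classified == stats.n_reactions == len(toy.reactions)
        assert stats.n_exchange == len(toy.exchanges())
        assert stats.n_unique_metabolites <= stats.n_metabolite_instances

    def test_periplasm_adds_transport_step(self):
        from bfgem.synth import ToySpec, toy_fermenter

        flat = model_statistics(toy_fermenter(ToySpec()))
        deep = model_statistics(toy_fermenter(ToySpec(include_periplasm=True)))
        assert deep.n_transport == flat.n_transport + 1

    def test_transport_classification_invariant_under_reordering(self, toy):
        reordered = MetabolicModel(
            model_id=toy.id,
            metabolites=list(toy.copy().metabolites.values()),
            reactions=list(reversed(list(toy.copy().reactions.values()))),
            objective_id=toy.objective_id,
        )
        a, b = model_statistics(toy), model_statistics(reordered)
        assert (a.n_exchange, a.n_transport, a.n_metabolic) == (
            b.n_exchange, b.n_transport, b.n_metabolic
        )


class TestFormats:
    def test_equation_parser(self):
        stoich, reversible = parse_equation("2 a_c + b_c --> 3 c_c")
        assert stoich == {"a_c": -2.0, "b_c": -1.0, "c_c": 3.0}
        assert not reversible
        _, reversible = parse_equation("a_c <=> b_c")
        assert reversible
        with pytest.raises(ParseError):
            parse_equation("a_c b_c")

    @pytest.mark.parametrize("fmt, filename", [
        ("json", "model.json"),
        ("sbml", "model.xml"),
        ("tabular", "model.xlsx"),
        ("tabular", "model_dir"),
    ])
    def test_round_trip(self, toy, tmp_path, fmt, filename):
        path = write_model(toy, tmp_path / filename, format=fmt)
        back = read_model(path, format=fmt)
        assert set(back.metabolites) == set(toy.metabolites)
        assert set(back.reactions) == set(toy.reactions)
        assert back.objective_id == toy.objective_id
        for rid, rxn in toy.reactions.items():
            other = back.reactions[rid]
            assert set(other.stoichiometry) == set(rxn.stoichiometry)
            for met, coef in rxn.stoichiometry.items():
                assert other.stoichiometry[met] == pytest.approx(coef, rel=1e-9)
            assert other.lower_bound == pytest.approx(rxn.lower_bound)
            assert other.upper_bound == pytest.approx(rxn.upper_bound)
            assert other.gene_rule == rxn.gene_rule
            assert other.kind == rxn.kind
        for mid, met in toy.metabolites.items():
            assert back.metabolites[mid].compartment == met.compartment
            if met.formula is not None:
                assert back.metabolites[mid].formula.counts == met.formula.counts

    def test_auto_format_detection(self, toy, tmp_path):
        for name in ("m.json", "m.xml", "m.xlsx"):
            write_model(toy, tmp_path / name)
            assert len(read_model(tmp_path / name).reactions) == len(toy.reactions)

    def test_round_trip_preserves_fba_optimum(self, toy, tmp_path):
        base = optimize(toy).objective_value
        for name in ("m.json", "m.xml", "m.xlsx"):
            again = optimize(read_model(write_model(toy, tmp_path / name)))
            assert again.objective_value == pytest.approx(base, rel=1e-9)

    def test_malformed_json_raises_parse_error(self, tmp_path):
        bad = tmp_path / "bad.json"
        bad.write_text("{not json")
        with pytest.raises(ParseError):
            read_model(bad)

    def test_duplicate_reaction_id_raises(self, tmp_path):
        bad = tmp_path / "dup.json"
        bad.write_text(
            '{"metabolites": [{"id": "a_e", "compartment": "e"}],'
            ' "reactions": ['
            '{"id": "EX_a", "metabolites": {"a_e": -1}},'
            '{"id": "EX_a", "metabolites": {"a_e": -1}}]}'
        )
        with pytest.raises((ParseError, ModelValidationError)):
            read_model(bad)

    def test_loose_spreadsheet_importer_handles_alias_columns(self, toy, tmp_path):
        import pandas as pd

        path = tmp_path / "loose.xlsx"
        mets = pd.DataFrame(
            [
                {"Metabolite ID": m.id, "Description": m.name,
                 "Charged Formula": str(m.formula) if m.formula else ""}
                for m in toy.metabolites.values()
            ]
        )
        rxns = pd.DataFrame(
            [
                {"Abbreviation": r.id, "Reaction Formula": r.equation(),
                 "LB": r.lower_bound, "UB": r.upper_bound,
                 "GPR": r.gene_rule.to_string()}
                for r in toy.reactions.values()
            ]
        )
        with pd.ExcelWriter(path) as xl:
            mets.to_excel(xl, sheet_name="Metabolite List", index=False)
            rxns.to_excel(xl, sheet_name="Reaction List", index=False)
        model = read_spreadsheet_model(path)
        assert set(model.reactions) == set(toy.reactions)
        assert model.metabolites["glc_e"].compartment == "e"
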