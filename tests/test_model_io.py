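"""Model I/O: GPR parsing/evaluation, stoichiometric matrix, SBML/JSON
round trips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gutflux.model_io import (
    GPRParseError,
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
    elemental_imbalance,
    evaluate_gpr,
    parse_gpr,
    read_model,
    stoichiometric_matrix,
    write_model,
)


class TestGPRParsing:
    def test_and_or_precedence(self):
        rule = parse_gpr("(b0001 and b0002) or b0003")
        assert rule.to_string() == "b0001 and b0002 or b0003"
        assert rule.genes() == {"b0001", "b0002", "b0003"}
        # b3 alone satisfies the OR branch
        assert evaluate_gpr(rule, {"b0001": 1, "b0002": 0, "b0003": 1}) == 1
        assert evaluate_gpr(rule, {"b0001": 1, "b0002": 0, "b0003": 0}) == 0

    def test_empty_rule_is_unconditional(self):
        rule = parse_gpr("")
        assert rule.is_empty
        assert evaluate_gpr(rule, {}) == 1
        assert evaluate_gpr(rule, {"b1": 0}) == 1

    @pytest.mark.parametrize("bad", ["b0001 and", "and b0001", "(b0001 or b0002",
                                     "b0001)", "b0001 or or b0002"])
    def test_malformed_rules_raise_with_position(self, bad):
        with pytest.raises(GPRParseError) as exc:
            parse_gpr(bad)
        assert "position" in str(exc.value)

    def test_and_is_min_or_is_max_on_scores(self):
        rule = parse_gpr("a and b or c")
        assert evaluate_gpr(rule, {"a": 0.9, "b": 0.2, "c": 0.4}) == pytest.approx(0.4)

    def test_missing_genes_default_absent(self):
        rule = parse_gpr("a and b")
        assert evaluate_gpr(rule, {"a": 1}) == 0

    @given(st.dictionaries(st.sampled_from(list("abcde")), st.integers(0, 1),
                           min_size=5, max_size=5),
           st.sampled_from(["a and b or c", "(a or b) and (c or d)",
                            "a and (b or c and d) or e"]))
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_evaluation_is_monotone_in_gene_states(self, states, rule_str):
        """Switching any absent gene to present can never lose a reaction."""
        rule = parse_gpr(rule_str)
        base = evaluate_gpr(rule, states)
        for g in states:
            bumped = dict(states)
            bumped[g] = 1
            assert evaluate_gpr(rule, bumped) >= base

    def test_round_trip_parse_to_string(self):
        for s in ["a and b", "a or b and c", "(a or b) and c", "x1"]:
            rule = parse_gpr(s)
            assert parse_gpr(rule.to_string()).to_string() == rule.to_string()


class TestStoichiometricMatrix:
    def test_chain_matrix_layout(self, chain3):
        # rows follow metabolite order (A, B, C), columns reaction order
        S = stoichiometric_matrix(chain3)
        expected = np.array([
            [1, -1, 0, 0],
            [0, 1, -1, 0],
            [0, 0, 1, -1],
        ], dtype=float)
        np.testing.assert_array_equal(S, expected)

    def test_exchange_columns_have_single_nonzero(self, core_model):
        S = stoichiometric_matrix(core_model)
        for j, r in enumerate(core_model.reactions):
            if r.is_exchange:
                assert np.count_nonzero(S[:, j]) == 1

    def test_internal_reaction_element_balance(self):
        """Element-count oracle: a mass-balanced internal reaction nets zero
        per element when formulas are complete."""
        mets = [
            Metabolite(id="glc", formula="C6H12O6", compartment="c"),
            Metabolite(id="pyr2", formula="C3H6O3", compartment="c"),
        ]
        rxns = [Reaction("SPLIT", stoichiometry={"glc": -1.0, "pyr2": 2.0})]
        m = MetabolicModel(id="t", metabolites=mets, reactions=rxns)
        assert elemental_imbalance(m, "SPLIT") == {}
        # and an unbalanced variant is caught
        rxns2 = [Reaction("BAD", stoichiometry={"glc": -1.0, "pyr2": 1.0})]
        m2 = MetabolicModel(id="t2", metabolites=mets, reactions=rxns2)
        assert elemental_imbalance(m2, "BAD") == {"C": -3, "H": -6, "O": -3}


class TestValidation:
    def test_duplicate_reaction_ids_rejected(self):
        mets = [Metabolite(id="A", compartment="c")]
        rxns = [Reaction("R", stoichiometry={"A": 1.0}),
                Reaction("R", stoichiometry={"A": -1.0})]
        with pytest.raises(ModelValidationError, match="duplicate reaction"):
            MetabolicModel(id="m", metabolites=mets, reactions=rxns)

    def test_undeclared_metabolite_rejected(self):
        with pytest.raises(ModelValidationError, match="undeclared"):
            MetabolicModel(id="m", metabolites=[Metabolite(id="A", compartment="c")],
                           reactions=[Reaction("R", stoichiometry={"B": 1.0})])

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ModelValidationError, match="lower_bound"):
            MetabolicModel(
                id="m", metabolites=[Metabolite(id="A", compartment="c")],
                reactions=[Reaction("R", stoichiometry={"A": 1.0},
                                    lower_bound=5.0, upper_bound=-5.0)])


class TestRoundTrips:
    @pytest.mark.parametrize("fmt,suffix", [("json", ".json"), ("sbml", ".xml")])
    def test_write_read_identity(self, core_model, tmp_path, fmt, suffix):
        path = tmp_path / f"model{suffix}"
        write_model(core_model, path, format=fmt)
        back = read_model(path, format=fmt)
        assert back.reaction_ids() == core_model.reaction_ids()
        assert back.metabolite_ids() == core_model.metabolite_ids()
        for r1 in core_model.reactions:
            r2 = back.get_reaction(r1.id)
            assert r2.stoichiometry == pytest.approx(r1.stoichiometry)
            assert (r2.lower_bound, r2.upper_bound) == (r1.lower_bound, r1.upper_bound)
            assert r2.objective_coefficient == r1.objective_coefficient
            assert r2.gpr.genes() == r1.gpr.genes()
        assert back.genes == core_model.genes

    def test_three_reaction_toy_sbml(self, tmp_path):
        """Minimal SBML: one exchange, one conversion, one biomass drain."""
        mets = [Metabolite(id="A", compartment="c"), Metabolite(id="B", compartment="c")]
        rxns = [
            Reaction("EX_A", stoichiometry={"A": 1.0}, lower_bound=0.0, upper_bound=10.0),
            Reaction("CONV", stoichiometry={"A": -1.0, "B": 1.0}, lower_bound=0.0,
                     upper_bound=1000.0, gpr=parse_gpr("g1 or g2")),
            Reaction("BIOMASS", stoichiometry={"B": -1.0}, lower_bound=0.0,
                     upper_bound=1000.0, objective_coefficient=1.0),
        ]
        model = MetabolicModel(id="toy3", metabolites=mets, reactions=rxns)
        path = tmp_path / "toy.xml"
        write_model(model, path)
        back = read_model(path)
        assert len(back.reactions) == 3
        assert len(back.metabolites) == 2
        assert back.get_reaction("CONV").gpr.genes() == {"g1", "g2"}

    def test_legacy_notes_gene_association_read(self, tmp_path):
        """Level-2 SBML with GENE_ASSOCIATION in notes parses into GPRs."""
        sbml = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level2" level="2" version="1">
 <model id="legacy">
  <listOfCompartments><compartment id="c"/></listOfCompartments>
  <listOfSpecies>
   <species id="A" compartment="c"/>
   <species id="B" compartment="c"/>
  </listOfSpecies>
  <listOfReactions>
   <reaction id="R1" reversible="false">
    <notes><body xmlns="http://www.w3.org/1999/xhtml">
      <p>GENE_ASSOCIATION: (g1 and g2) or g3</p>
      <p>SUBSYSTEM: Test pathway</p>
    </body></notes>
    <listOfReactants><speciesReference species="A"/></listOfReactants>
    <listOfProducts><speciesReference species="B"/></listOfProducts>
    <kineticLaw>
      <math xmlns="http://www.w3.org/1998/Math/MathML"><ci>FLUX_VALUE</ci></math>
      <listOfParameters>
        <parameter id="LOWER_BOUND" value="0"/>
        <parameter id="UPPER_BOUND" value="999"/>
        <parameter id="OBJECTIVE_COEFFICIENT" value="1"/>
        <parameter id="FLUX_VALUE" value="0"/>
      </listOfParameters>
    </kineticLaw>
   </reaction>
  </listOfReactions>
 </model>
</sbml>
"""
        path = tmp_path / "legacy.xml"
        path.write_text(sbml)
        model = read_model(path)
        r = model.get_reaction("R1")
        assert r.gpr.genes() == {"g1", "g2", "g3"}
        assert r.upper_bound == 999.0
        assert r.lower_bound == 0.0
        assert r.objective_coefficient == 1.0
        assert r.subsystem == "Test pathway"

    def test_default_bounds_when_absent(self, tmp_path):
        """Reversibility flag drives defaults: ±1000 reversible, [0, 1000]
        irreversible."""
        sbml = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level2" level="2" version="1">
 <model id="m"><listOfCompartments><compartment id="c"/></listOfCompartments>
  <listOfSpecies><species id="A" compartment="c"/></listOfSpecies>
  <listOfReactions>
   <reaction id="REV" reversible="true">
    <listOfReactants><speciesReference species="A"/></listOfReactants>
   </reaction>
   <reaction id="IRR" reversible="false">
    <listOfProducts><speciesReference species="A"/></listOfProducts>
   </reaction>
  </listOfReactions></model></sbml>"""
        path = tmp_path / "nobounds.xml"
        path.write_text(sbml)
        model = read_model(path)
        assert (model.get_reaction("REV").lower_bound,
                model.get_reaction("REV").upper_bound) == (-1000.0, 1000.0)
        assert (model.get_reaction("IRR").lower_bound,
                model.get_reaction("IRR").upper_bound) == (0.0, 1000.0)

    def test_malformed_json_names_line(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"id": "x", "reactions": [')
        with pytest.raises(ModelValidationError, match="line"):
            read_model(path)
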