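"""Reaction-string dialects, tabular loading, and SBML round trips."""

import warnings
from fractions import Fraction

import pytest

from conftest import G6PDH_VARIANTS, make_reaction
from metreconcile import (
    Model,
    ReactionParseError,
    export_sbml,
    import_sbml,
    load_model,
    parse_reaction_string,
    render_reaction_string,
)
from metreconcile.model import Direction, ModelError, Resolution


def coeffs(r):
    return {p.metabolite: p.coefficient for p in r.participants}


class TestParseReactionString:
    def test_compartment_prefix_and_reversible_arrow(self):
        r = parse_reaction_string("[c]: g6p + nadp < = = > 6pgl + h + nadph")
        assert coeffs(r) == {
            "g6p": -1, "nadp": -1, "6pgl": 1, "h": 1, "nadph": 1,
        }
        assert r.direction is Direction.REVERSIBLE
        assert {p.compartment for p in r.participants} == {"c"}

    def test_uppercase_forward_no_compartment(self):
        r = parse_reaction_string("G6P + NAD - > D6PGL + NADH")
        assert r.direction is Direction.FORWARD
        assert {p.compartment for p in r.participants} == {None}

    def test_integer_coefficients(self):
        r = parse_reaction_string("A + 2 B -- > C")
        assert coeffs(r) == {"A": -1, "B": -2, "C": 1}
        assert r.direction is Direction.FORWARD

    def test_unicode_arrow_and_repeated_coefficient(self):
        r = parse_reaction_string("atp + co2 + dann → adp + dtbt + 3 h + pi")
        assert coeffs(r)["h"] == 3
        assert coeffs(r)["atp"] == -1

    def test_rational_coefficient(self):
        r = parse_reaction_string("1/2 A + B -> C")
        assert coeffs(r)["A"] == Fraction(-1, 2)

    def test_bare_equals_is_forward_with_warning(self):
        with pytest.warns(UserWarning, match="bare '='"):
            r = parse_reaction_string("C01172 + C00006 = C01236 + C00005 + C00080")
        assert r.direction is Direction.FORWARD

    def test_backward_arrow_normalised(self):
        r = parse_reaction_string("A < - B")
        assert coeffs(r) == {"B": -1, "A": 1}
        assert r.direction is Direction.FORWARD

    def test_per_metabolite_compartment_suffix(self):
        r = parse_reaction_string("glc[e] -> glc[c]")
        assert {p.compartment for p in r.participants} == {"e", "c"}

    @pytest.mark.parametrize("bad", ["A B C", "A + -> B", "A + B ->", "", "A + + B -> C"])
    def test_parse_errors(self, bad):
        with pytest.raises(ReactionParseError):
            parse_reaction_string(bad)

    def test_all_nine_variants_parse(self, g6pdh_reactions):
        assert len(g6pdh_reactions) == 9
        for r in g6pdh_reactions:
            reactants = [p for p in r.participants if p.coefficient < 0]
            products = [p for p in r.participants if p.coefficient > 0]
            assert reactants and products
            assert sum(p.coefficient for p in reactants) < 0
            assert sum(p.coefficient for p in products) > 0

    def test_canonical_rendering_is_idempotent(self, g6pdh_reactions):
        for r in g6pdh_reactions:
            canon = render_reaction_string(r)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                again = parse_reaction_string(canon, reaction_id=r.id)
            assert again.participants == r.participants
            assert again.direction == r.direction
            assert render_reaction_string(again) == canon


class TestLoadModel:
    def test_auto_created_metabolites(self, tmp_path):
        rf = tmp_path / "rxns.tsv"
        rf.write_text("id\tequation\nR1\tA + B -> C\nR2\tC -> D\n")
        m = load_model(rf, name="toy")
        assert set(m.metabolites) == {"A", "B", "C", "D"}
        assert all(e.resolution is Resolution.NONE for e in m.metabolites.values())

    def test_metabolite_table_resolution_classes(self, tmp_path):
        rf = tmp_path / "rxns.tsv"
        rf.write_text("id\tequation\nR1\tglc + rgrp -> unk\n")
        mf = tmp_path / "mets.tsv"
        mf.write_text(
            "id\tnames\tformula\tcharge\tsmiles\n"
            "glc\tglucose\tC6H12O6\t0\tOCC1OC(O)C(O)C(O)C1O\n"
            "rgrp\tacyl thing\t\t\t*CC(=O)O\n"
            "unk\tmystery\t\t\t\n"
        )
        m = load_model(rf, mf, name="toy")
        assert m.metabolites["glc"].resolution is Resolution.FULL
        assert m.metabolites["rgrp"].resolution is Resolution.PARTIAL
        assert m.metabolites["unk"].resolution is Resolution.NONE

    def test_duplicate_reaction_id_rejected(self, tmp_path):
        rf = tmp_path / "rxns.tsv"
        rf.write_text("id\tequation\nR1\tA -> B\nR1\tB -> C\n")
        with pytest.raises(ModelError, match="duplicate"):
            load_model(rf)

    def test_malformed_charge_rejected(self, tmp_path):
        rf = tmp_path / "rxns.tsv"
        rf.write_text("id\tequation\nR1\tA -> B\n")
        mf = tmp_path / "mets.tsv"
        mf.write_text("id\tnames\tformula\tcharge\tsmiles\nA\ta\t\t1.5\t\n")
        with pytest.raises(ModelError, match="charge"):
            load_model(rf, mf)


def _toy_model():
    m = Model(name="toy")
    m.add_reaction(make_reaction("R1", [("a", 1), ("b", 2)], [("c", 1)], rev=True, compartment="c"))
    m.add_reaction(make_reaction("R2", [("c", 1)], [("d", 1)], compartment="c"))
    t = make_reaction("T1", [("d", 1)], [("d_e", 1)])
    t.participants = [
        p.__class__(metabolite=p.metabolite, coefficient=p.coefficient,
                    compartment="c" if p.metabolite == "d" else "e")
        for p in t.participants
    ]
    m.add_reaction(t)
    m.objective = "R2"
    m.bounds["R1"] = (-7.0, 7.0)
    return m


class TestSBML:
    def test_round_trip_preserves_everything(self):
        m = _toy_model()
        m2 = import_sbml(export_sbml(m))
        assert set(m2.reactions) == set(m.reactions)
        for rid in m.reactions:
            assert sorted(
                (p.metabolite, p.coefficient) for p in m.reactions[rid].participants
            ) == sorted(
                (p.metabolite, p.coefficient) for p in m2.reactions[rid].participants
            )
            assert m.reactions[rid].direction == m2.reactions[rid].direction
        assert m2.objective == "R2"
        assert m2.bounds["R1"] == (-7.0, 7.0)

    def test_two_compartments_exported(self):
        text = export_sbml(_toy_model())
        assert 'id="c"' in text and 'id="e"' in text

    def test_fractional_stoichiometry_survives(self):
        m = Model(name="frac")
        m.add_reaction(make_reaction("R1", [("a", Fraction(1, 3))], [("b", 1)]))
        m2 = import_sbml(export_sbml(m))
        assert m2.reactions["R1"].coefficient_of("a") == Fraction(-1, 3)

    def test_structure_and_synonyms_survive(self):
        m = Model(name="s")
        m.add_reaction(make_reaction("R1", [("glc", 1)], [("x", 1)]))
        m.metabolites["glc"].names = ["glucose", "dextrose"]
        m.metabolites["glc"].structure = "OCC1OC(O)C(O)C(O)C1O"
        m2 = import_sbml(export_sbml(m))
        assert m2.metabolites["glc"].structure == "OCC1OC(O)C(O)C(O)C1O"
        assert m2.metabolites["glc"].names == ["glucose", "dextrose"]

    def test_id_sanitisation_collision_raises(self):
        m = Model(name="bad")
        m.add_reaction(make_reaction("R1", [("a b", 1)], [("a+b", 1)]))
        with pytest.raises(ModelError, match="collision"):
            export_sbml(m)
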