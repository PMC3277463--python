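"""Imbalance arithmetic and minimal proton/water repair."""

import random
from fractions import Fraction

import pytest

from _brute import brute_force_repairs, minimal_repairs, random_reaction_and_comp
from conftest import make_reaction
from metreconcile import imbalance, parse_formula, parse_reaction_string, repair_reaction
from metreconcile.balance import (
    audit_model,
    repair_reaction_milp,
)
from metreconcile.model import Model


@pytest.fixture(scope="module")
def dethiobiotin_comp():
    return {
        "atp": parse_formula("C10H12N5O13P3", charge=-4),
        "co2": parse_formula("CO2", charge=0),
        "dann": parse_formula("C9H21N2O2", charge=1),
        "adp": parse_formula("C10H12N5O10P2", charge=-3),
        "dtbt": parse_formula("C10H17N2O3", charge=-1),
        "pi": parse_formula("HPO4", charge=-2),
        "h": parse_formula("H", charge=1),
        "DAPA": parse_formula("C9H21N2O2", charge=1),
        "ATP": parse_formula("C10H12N5O13P3", charge=-4),
        "CO2": parse_formula("CO2", charge=0),
        "ADP": parse_formula("C10H12N5O10P2", charge=-3),
        "DTBIOTIN": parse_formula("C10H17N2O3", charge=-1),
        "PI": parse_formula("HPO4", charge=-2),
    }


class TestImbalance:
    def test_printed_reference_reaction_is_balanced(self, dethiobiotin_comp):
        r = parse_reaction_string("atp + co2 + dann → adp + dtbt + 3 h + pi")
        assert imbalance(r, dethiobiotin_comp).is_zero

    def test_identity_reaction_is_zero(self):
        r = make_reaction("id", [("A", 1)], [("A2", 1)])
        comp = {"A": parse_formula("C2H4O"), "A2": parse_formula("C2H4O")}
        assert imbalance(r, comp).is_zero

    def test_deleting_proton_term_shifts_hydrogen_and_charge(self, dethiobiotin_comp):
        r = parse_reaction_string("atp + co2 + dann → adp + dtbt + pi")
        imb = imbalance(r, dethiobiotin_comp)
        assert imb.charge == -3
        assert imb.as_dict() == {"H": Fraction(-3)}

    def test_missing_composition_signalled(self):
        from metreconcile.balance import UnresolvableReaction

        r = make_reaction("r", [("A", 1)], [("B", 1)])
        with pytest.raises(UnresolvableReaction):
            imbalance(r, {"A": parse_formula("CH4")})


class TestRepairWorkedExamples:
    def test_dethiobiotin_synthase_gains_three_product_protons(self, dethiobiotin_comp):
        """The biotin-pathway reaction written without protons repairs by
        adding exactly 3 h to the products."""
        r = parse_reaction_string(
            "DAPA + ATP + CO2 ⇔ DTBIOTIN + ADP + PI", reaction_id="dapa"
        )
        res = repair_reaction(r, dethiobiotin_comp)
        assert res.status == "repaired"
        assert (res.proton_delta, res.water_delta) == (3, 0)
        assert res.repaired.coefficient_of("h") == 3

    def test_gtp_cyclohydrolase_water_coefficient_corrected(self):
        """Water written with coefficient -2 repairs to net -1, plus one
        proton to close the charge balance."""
        comp = {
            "gtp": parse_formula("C10H12N5O14P3", charge=-4),
            "h2o": parse_formula("H2O"),
            "ahdt": parse_formula("C9H12N5O13P3", charge=-4),
            "for": parse_formula("CHO2", charge=-1),
        }
        r = parse_reaction_string("gtp + 2 h2o → ahdt + for", reaction_id="gtpch")
        res = repair_reaction(r, comp)
        assert res.status == "repaired"
        assert res.water_delta == 1
        assert res.repaired.coefficient_of("h2o") == -1
        assert res.proton_delta == 1

    def test_methanogenesis_strawman_is_infeasible(self):
        comp = {"co2": parse_formula("CO2"), "ch4": parse_formula("CH4")}
        r = parse_reaction_string("co2 -> ch4", reaction_id="bad")
        assert repair_reaction(r, comp).status == "infeasible"


class TestRepairProperties:
    def test_brute_force_oracle_on_random_reactions(self):
        """On 200 random reactions the closed-form (p, w) matches exhaustive
        search over [-10, 10]^2, and whenever feasible it is unique."""
        rng = random.Random(20240917)
        n_repaired = n_infeasible = 0
        for _ in range(200):
            r, comp = random_reaction_and_comp(rng)
            feasible = brute_force_repairs(r, comp)
            res = repair_reaction(r, comp)
            if res.status in ("repaired", "already-balanced"):
                want = minimal_repairs(feasible)
                assert len(feasible) <= 1  # uniqueness: p pinned by charge, w by O
                assert want == {(res.proton_delta, res.water_delta)}
                n_repaired += 1
            else:
                assert feasible == set()
                n_infeasible += 1
        assert n_repaired > 20 and n_infeasible > 20  # both regimes exercised

    def test_milp_fallback_agrees_with_closed_form(self):
        rng = random.Random(7)
        for _ in range(40):
            r, comp = random_reaction_and_comp(rng)
            a = repair_reaction(r, comp)
            b = repair_reaction_milp(r, comp)
            assert a.status == b.status
            if a.status == "repaired":
                assert (a.proton_delta, a.water_delta) == (b.proton_delta, b.water_delta)

    def test_repair_is_idempotent(self):
        rng = random.Random(99)
        seen = 0
        for _ in range(100):
            r, comp = random_reaction_and_comp(rng)
            res = repair_reaction(r, comp)
            if res.status == "repaired":
                comp2 = dict(comp)
                comp2.setdefault("h", parse_formula("H", charge=1))
                comp2.setdefault("h2o", parse_formula("H2O"))
                again = repair_reaction(res.repaired, comp2)
                assert again.status == "already-balanced"
                assert imbalance(res.repaired, comp2).is_zero
                seen += 1
        assert seen > 10


class TestAuditModel:
    def test_counts_by_status(self):
        comp = {
            "A": parse_formula("C2H4O"),
            "B": parse_formula("C2H4O"),
            "C": parse_formula("C2H3O", charge=-1),
            "h": parse_formula("H", charge=1),
        }
        m = Model(name="t")
        m.add_reaction(make_reaction("ok", [("A", 1)], [("B", 1)]))
        m.add_reaction(make_reaction("fixme", [("A", 1)], [("C", 1)]))  # missing h
        m.add_reaction(make_reaction("nocomp", [("A", 1)], [("Z", 1)]))
        rep = audit_model(m, comp)
        assert rep.counts == {"already-balanced": 1, "repaired": 1, "unresolvable": 1}
        assert rep.repairs()["fixme"].proton_delta == 1
        assert "=>" in rep.repairs()["fixme"].detail

    def test_injected_proton_omissions_all_recovered(self):
        from metreconcile import make_synthetic_corpus

        models, truth = make_synthetic_corpus(
            11, 40, 1, error_rates={"missing-proton": 1.0}
        )
        injected = {rid for (_, rid, cls) in truth.injected_errors if cls == "missing-proton"}
        rep = audit_model(models[0])
        repaired = set(rep.repairs())
        assert repaired == injected
        assert all(
            rep.repairs()[rid].proton_delta != 0 and rep.repairs()[rid].water_delta == 0
            for rid in repaired
        )

    def test_r_group_reaction_counts_unresolvable(self):
        comp = {"A": parse_formula("C2H4O")}
        m = Model(name="t")
        m.add_reaction(make_reaction("r", [("A", 1)], [("Rgrp", 1)]))
        m.metabolites["Rgrp"].structure = "*CC(=O)O"
        rep = audit_model(m, comp)
        assert rep.counts == {"unresolvable": 1}
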