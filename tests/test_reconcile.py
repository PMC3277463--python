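"""Reaction keys, consolidation, iterative resolution, model comparison."""

import itertools
import random
from dataclasses import replace
from fractions import Fraction

import pytest

from conftest import G6PDH_VARIANTS, make_reaction
from metreconcile import (
    MetaboliteEntry,
    Model,
    compare_sources,
    consolidate_metabolites,
    iterative_resolve,
    reaction_key,
    structure_key,
)
from metreconcile.model import Participant, Resolution
from metreconcile.reconcile import UnresolvedParticipant, cofactor_classes_from_models


class TestReactionKey:
    def test_nadp_rows_collapse_to_one_strict_key(self, g6pdh_reactions, g6pdh_ids):
        keys = [reaction_key(r, g6pdh_ids).key for r in g6pdh_reactions]
        nadp_rows = [k for r, k in zip(G6PDH_VARIANTS, keys) if "NADP" in r.upper() or "C00006" in r]
        assert len(set(nadp_rows)) == 1
        assert len(nadp_rows) == 7

    def test_nad_and_f420_rows_stay_distinct_in_strict_mode(self, g6pdh_reactions, g6pdh_ids):
        keys = [reaction_key(r, g6pdh_ids).key for r in g6pdh_reactions]
        nad_key = keys[6]
        f420_key = keys[3]
        assert nad_key not in (keys[0], f420_key)
        assert f420_key != keys[0]

    def test_family_mode_unites_alternate_cofactors(self, g6pdh_reactions, g6pdh_ids):
        classes = {
            g6pdh_ids[n].key: "redox-cofactor"
            for n in ("nad", "nadh", "nadp", "nadph", "f420-2", "f420-2h2")
        }
        fkeys = {
            reaction_key(r, g6pdh_ids, mode="family", cofactor_classes=classes).key
            for r in g6pdh_reactions
        }
        assert len(fkeys) == 1

    def test_invariant_under_flip_and_permutation(self, g6pdh_reactions, g6pdh_ids):
        rng = random.Random(5)
        for r in g6pdh_reactions:
            k = reaction_key(r, g6pdh_ids).key
            assert reaction_key(r.flipped(), g6pdh_ids).key == k
            shuffled = list(r.participants)
            rng.shuffle(shuffled)
            assert reaction_key(replace(r, participants=shuffled), g6pdh_ids).key == k

    def test_scale_doubling_collapses(self, g6pdh_ids):
        a = make_reaction("a", [("g6p", 1), ("nadp", 1)], [("6pgl", 1), ("nadph", 1)])
        b = make_reaction("b", [("g6p", 2), ("nadp", 2)], [("6pgl", 2), ("nadph", 2)])
        assert reaction_key(a, g6pdh_ids).key == reaction_key(b, g6pdh_ids).key

    def test_unresolved_participant_signalled(self, g6pdh_ids):
        r = make_reaction("r", [("g6p", 1)], [("mystery", 1)])
        with pytest.raises(UnresolvedParticipant):
            reaction_key(r, g6pdh_ids)

    def test_water_difference_changes_key(self, g6pdh_ids):
        ids = dict(g6pdh_ids)
        ids["h2o"] = structure_key("O")
        a = make_reaction("a", [("g6p", 1)], [("6pgl", 1)])
        b = make_reaction("b", [("g6p", 1), ("h2o", 1)], [("6pgl", 1)])
        assert reaction_key(a, ids).key != reaction_key(b, ids).key

    def test_string_match_baseline_vs_key_match(self, g6pdh_reactions, g6pdh_ids):
        """Naive string comparison finds no duplicates among the nine
        writings; key comparison groups at least five of them."""
        raw_groups = {
            s: [t for t in G6PDH_VARIANTS if t == s] for s in G6PDH_VARIANTS
        }
        assert all(len(v) == 1 for v in raw_groups.values())
        keys = [reaction_key(r, g6pdh_ids).key for r in g6pdh_reactions]
        biggest = max(keys.count(k) for k in keys)
        assert biggest >= 5

    def test_cofactor_classes_discovered_from_names(self):
        m = Model(name="m")
        m.add_reaction(make_reaction("r", [("x", 1), ("nad", 1)], [("y", 1), ("nadh", 1)]))
        for mid, smi in [("x", "CCO"), ("y", "CC=O"), ("nad", "CCC(=O)N"), ("nadh", "CCC(O)N")]:
            m.metabolites[mid].structure = smi
        classes = cofactor_classes_from_models([m])
        assert set(classes.values()) == {"redox-cofactor"}
        assert len(classes) == 2


def _model_with(name, mets):
    """mets: dict id -> (name, smiles or None)."""
    m = Model(name=name)
    for mid, (mname, smi) in mets.items():
        e = MetaboliteEntry(id=mid, names=[mname], structure=smi)
        from metreconcile import resolution_class

        e.resolution = resolution_class(e)
        m.metabolites[mid] = e
    return m


class TestConsolidation:
    def test_same_structure_different_names_merge(self):
        a = _model_with("A", {"glc": ("glucose", "OCC1OC(O)C(O)C(O)C1O")})
        b = _model_with("B", {"dex": ("dextrose", "OCC1OC(O)C(O)C(O)C1O")})
        cmap = consolidate_metabolites([a, b])
        groups = [g for g in cmap.groups.values() if len(g) == 2]
        assert groups == [[("A", "glc"), ("B", "dex")]]

    def test_enantiomers_one_connectivity_group_two_stereo_subgroups(self):
        a = _model_with("A", {"lala": ("L-alanine", "N[C@@H](C)C(=O)O")})
        b = _model_with("B", {"dala": ("D-alanine", "N[C@H](C)C(=O)O")})
        cmap = consolidate_metabolites([a, b])
        (conn_key,) = [k for k, g in cmap.groups.items() if len(g) == 2]
        assert len(cmap.stereo_subgroups[conn_key]) == 2

    def test_shared_name_different_structures_not_merged(self):
        # one abbreviation, two different molecules: structure wins over name
        a = _model_with("A", {"AMP": ("AMP", "Nc1ncnc2c1ncn2C1OC(COP(=O)([O-])[O-])C(O)C1O")})
        b = _model_with("B", {"AMP": ("AMP", "CC1(C)SC2C(NC(=O)C(N)c3ccccc3)C(=O)N2C1C(=O)O")})
        cmap = consolidate_metabolites([a, b])
        assert all(len(g) == 1 for g in cmap.groups.values())
        assert len(cmap.groups) == 2

    def test_structureless_entries_never_merge(self):
        a = _model_with("A", {"x": ("mystery", None)})
        b = _model_with("B", {"x": ("mystery", None)})
        cmap = consolidate_metabolites([a, b])
        assert cmap.groups == {}
        assert set(cmap.unmerged) == {("A", "x"), ("B", "x")}

    def test_merging_never_unites_different_connectivity_keys(self):
        models = [
            _model_with(f"M{i}", {f"m{j}": (f"met{j}", smi) for j, smi in enumerate(
                ["CCO", "CC=O", "OCC(O)CO", "N[C@@H](C)C(=O)O", "N[C@H](C)C(=O)O"]
            )})
            for i in range(3)
        ]
        cmap = consolidate_metabolites(models)
        for key, members in cmap.groups.items():
            for mname, mid in members:
                model = next(m for m in models if m.name == mname)
                assert structure_key(model.metabolites[mid].structure).key == key


DAPA_SMILES = {
    "atp": "ATPSTANDIN", "co2": "O=C=O", "dann": "CC(N)CCCCCC(N)C(=O)[O-]",
    "adp": "ADPSTANDIN", "dtbt": "CC1NC(=O)NC1CCCCC(=O)[O-]",
    "pi": "OP(=O)([O-])[O-]", "h": "[H+]",
}
# replace placeholder strings by small real SMILES stand-ins
DAPA_SMILES["atp"] = "OC(COP(=O)([O-])OP(=O)([O-])OP(=O)([O-])[O-])C1OC(n2ccnc2)C(O)C1O"
DAPA_SMILES["adp"] = "OC(COP(=O)([O-])OP(=O)([O-])[O-])C1OC(n2ccnc2)C(O)C1O"


def _dapa_corpus():
    resolved = Model(name="ecoli-like")
    resolved.add_reaction(
        make_reaction(
            "dtbsyn",
            [("atp", 1), ("co2", 1), ("dann", 1)],
            [("adp", 1), ("dtbt", 1), ("h", 3), ("pi", 1)],
        )
    )
    for mid, smi in DAPA_SMILES.items():
        resolved.metabolites[mid].structure = smi
        resolved.metabolites[mid].resolution = Resolution.FULL

    query = Model(name="cglut-like")
    query.add_reaction(
        make_reaction(
            "DTBSYN",
            [("DAPA", 1), ("ATP", 1), ("CO2", 1)],
            [("DTBIOTIN", 1), ("ADP", 1), ("PI", 1)],
            rev=True,
        )
    )
    for mid, canonical in [
        ("ATP", "atp"), ("CO2", "co2"), ("DTBIOTIN", "dtbt"), ("ADP", "adp"), ("PI", "pi"),
    ]:
        query.metabolites[mid].structure = DAPA_SMILES[canonical]
        query.metabolites[mid].resolution = Resolution.FULL
    # DAPA: name only
    return resolved, query


class TestIterativeResolve:
    def test_dapa_assigned_dann_structure_in_first_pass(self):
        resolved, query = _dapa_corpus()
        log = iterative_resolve([resolved, query])
        (entry,) = log.assignments
        assert (entry.model, entry.metabolite) == ("cglut-like", "DAPA")
        assert entry.pass_number == 1
        assert entry.assigned_key == structure_key(DAPA_SMILES["dann"]).key
        assert query.metabolites["DAPA"].resolution is Resolution.FULL

    def test_fully_resolved_corpus_logs_nothing(self):
        resolved, _ = _dapa_corpus()
        log = iterative_resolve([resolved])
        assert log.assignments == [] and log.passes == 1

    def test_chained_resolution_needs_three_passes(self):
        """X1's resolution enables X2's, which enables X3's."""
        smi = {"a": "CCO", "b": "CC=O", "c": "CCC=O", "d": "CCCC=O",
               "x1": "OCC(O)CO", "x2": "OCC(O)C(O)CO", "x3": "OCC(O)C(O)C(O)CO"}
        ref = Model(name="ref")
        ref.add_reaction(make_reaction("r1", [("a", 1)], [("x1", 1), ("b", 1)]))
        ref.add_reaction(make_reaction("r2", [("x1", 1)], [("x2", 1), ("c", 1)]))
        ref.add_reaction(make_reaction("r3", [("x2", 1)], [("x3", 1), ("d", 1)]))
        for mid, s in smi.items():
            ref.metabolites[mid].structure = s
            ref.metabolites[mid].resolution = Resolution.FULL
        q = Model(name="query")
        q.add_reaction(make_reaction("q1", [("a", 1)], [("X1", 1), ("b", 1)]))
        q.add_reaction(make_reaction("q2", [("X1", 1)], [("X2", 1), ("c", 1)]))
        q.add_reaction(make_reaction("q3", [("X2", 1)], [("X3", 1), ("d", 1)]))
        for mid in ("a", "b", "c", "d"):
            q.metabolites[mid].structure = smi[mid]
            q.metabolites[mid].resolution = Resolution.FULL
        log = iterative_resolve([ref, q])
        by_pass = {e.metabolite: e.pass_number for e in log.assignments}
        assert by_pass == {"X1": 1, "X2": 2, "X3": 3}

    def test_ambiguous_slot_yields_suggestions_not_assignment(self):
        ref = Model(name="ref")
        ref.add_reaction(make_reaction("r1", [("a", 1)], [("p", 1)]))
        ref.add_reaction(make_reaction("r2", [("a", 1)], [("q", 1)]))
        for mid, s in [("a", "CCO"), ("p", "CC=O"), ("q", "CCC=O")]:
            ref.metabolites[mid].structure = s
            ref.metabolites[mid].resolution = Resolution.FULL
        qm = Model(name="query")
        qm.add_reaction(make_reaction("u", [("a", 1)], [("unknown", 1)]))
        qm.metabolites["a"].structure = "CCO"
        qm.metabolites["a"].resolution = Resolution.FULL
        log = iterative_resolve([ref, qm])
        assert log.assignments == []
        assert ("query", "unknown") in log.suggestions
        assert qm.metabolites["unknown"].structure is None

    def test_resolution_is_monotone_and_terminates(self):
        resolved, query = _dapa_corpus()
        log = iterative_resolve([resolved, query], max_passes=50)
        passes = [e.pass_number for e in log.assignments]
        assert passes == sorted(passes)
        assert log.passes <= 1 + len(query.metabolites)


class TestCompareSources:
    def test_model_vs_itself_fully_shared(self):
        a = _model_with("A", {"glc": ("glucose", "OCC1OC(O)C(O)C(O)C1O"),
                              "pyr": ("pyruvate", "CC(=O)C(=O)[O-]")})
        b = _model_with("B", dict(a.metabolites and {
            "g": ("glucose", "OCC1OC(O)C(O)C(O)C1O"),
            "p": ("pyruvate", "CC(=O)C(=O)[O-]"),
        }))
        table = compare_sources([a, b], level="metabolite")
        assert table.count("A", "B") == 2
        assert table.count("A", exact=True) == 0

    def test_planted_shared_reactions_counted(self, g6pdh_ids):
        smiles = {"s1": "CCO", "s2": "CC=O", "s3": "CCC=O", "s4": "CCCC=O"}
        shared = [make_reaction("shared1", [("s1", 1)], [("s2", 1)]),
                  make_reaction("shared2", [("s2", 1)], [("s3", 1)])]
        a = Model(name="A")
        b = Model(name="B")
        for r in shared:
            a.add_reaction(replace(r, id=f"A_{r.id}", participants=list(r.participants)))
            b.add_reaction(replace(r.flipped(), id=f"B_{r.id}", participants=list(r.flipped().participants)))
        b.add_reaction(make_reaction("only_b", [("s3", 1)], [("s4", 1)]))
        for m in (a, b):
            for mid, e in m.metabolites.items():
                e.structure = smiles[mid]
                e.resolution = Resolution.FULL
        table = compare_sources([a, b], level="reaction")
        assert table.count("A", "B") == 2
        assert table.count("B", exact=True) == 1

    def test_partial_entries_excluded_and_tallied(self):
        a = _model_with("A", {"glc": ("glucose", "OCC1OC(O)C(O)C(O)C1O"),
                              "acyl": ("an acyl", "*CC(=O)O")})
        b = _model_with("B", {"glc": ("glucose", "OCC1OC(O)C(O)C(O)C1O")})
        table = compare_sources([a, b], level="metabolite")
        assert table.excluded == {"A": 1, "B": 0}

    def test_needs_two_models(self):
        a = _model_with("A", {"glc": ("glucose", "OCC1OC(O)C(O)C(O)C1O")})
        with pytest.raises(ValueError):
            compare_sources([a])
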