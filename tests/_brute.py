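"""Independent brute-force oracles used by property and acceptance tests.

These deliberately share no code with the implementation: the repair
oracle enumerates all (p, w) on a grid, and the path oracle enumerates
simple paths on the raw digraph with networkx.
"""

from __future__ import annotations

import itertools
import random
from fractions import Fraction

import networkx as nx

from metreconcile.balance import imbalance
from metreconcile.chem_struct import ElementVector
from metreconcile.model import Direction, Participant, ReactionEntry


def brute_force_repairs(r, comp, bound: int = 10):
    """All (p, w) in [-bound, bound]^2 that exactly balance the reaction,
    as a set, by direct re-summation of element and charge totals."""
    imb = imbalance(r, comp)
    d = imb.as_dict()
    feasible = set()
    for p, w in itertools.product(range(-bound, bound + 1), repeat=2):
        ok = imb.charge + p == 0
        for sym in set(d) | {"H", "O"}:
            total = d.get(sym, Fraction(0))
            if sym == "H":
                total += p + 2 * w
            elif sym == "O":
                total += w
            ok = ok and total == 0
        if ok:
            feasible.add((p, w))
    return feasible


def minimal_repairs(feasible):
    if not feasible:
        return set()
    best = min(abs(p) + abs(w) for p, w in feasible)
    return {(p, w) for p, w in feasible if abs(p) + abs(w) == best}


def random_reaction_and_comp(rng: random.Random):
    """A random small reaction with compositions; roughly half are derived
    from a balanced construction perturbed by proton/water edits, the rest
    are arbitrary (usually irreparable)."""
    comp = {}
    n_react = rng.randint(1, 3)
    species = []
    for i in range(n_react):
        ev = {
            "C": rng.randint(0, 4),
            "H": rng.randint(0, 8),
            "O": rng.randint(0, 4),
            "N": rng.randint(0, 2),
        }
        charge = rng.randint(-2, 1)
        mid = f"s{i}"
        comp[mid] = ElementVector.from_dict(
            {k: v for k, v in ev.items() if v}, charge=charge
        )
        species.append((mid, rng.randint(1, 2)))

    if rng.random() < 0.5:
        # balanced by construction: single product = sum of reactants
        total: dict[str, Fraction] = {}
        charge = 0
        for mid, c in species:
            for sym, n in comp[mid].counts:
                total[sym] = total.get(sym, Fraction(0)) + n * c
            charge += comp[mid].charge * c
        comp["prod"] = ElementVector.from_dict(total or {"C": 1}, charge=charge)
        lhs = species
        rhs = [("prod", 1)]
        # perturb with explicit h/h2o terms the repair must undo
        comp["h"] = ElementVector.from_dict({"H": 1}, charge=1)
        comp["h2o"] = ElementVector.from_dict({"H": 2, "O": 1})
        extra = []
        if rng.random() < 0.7:
            extra.append(("h", rng.randint(1, 3), rng.choice([-1, 1])))
        if rng.random() < 0.5:
            extra.append(("h2o", rng.randint(1, 2), rng.choice([-1, 1])))
        parts = [
            Participant(metabolite=m, coefficient=Fraction(-c)) for m, c in lhs
        ] + [Participant(metabolite=m, coefficient=Fraction(c)) for m, c in rhs]
        for mid, c, sign in extra:
            parts.append(Participant(metabolite=mid, coefficient=Fraction(sign * c)))
    else:
        ev = {
            "C": rng.randint(0, 4),
            "H": rng.randint(0, 8),
            "O": rng.randint(0, 4),
            "N": rng.randint(0, 2),
        }
        comp["prod"] = ElementVector.from_dict(
            {k: v for k, v in ev.items() if v} or {"C": 1},
            charge=rng.randint(-2, 1),
        )
        parts = [
            Participant(metabolite=m, coefficient=Fraction(-c)) for m, c in species
        ] + [Participant(metabolite="prod", coefficient=Fraction(1))]
    r = ReactionEntry(id="rnd", participants=parts)
    return r, comp


def brute_force_paths(graph: nx.DiGraph, source, target, budget, reaction_of):
    """All simple source->target node paths with <= budget reactions and no
    repeated underlying reaction, via networkx simple-path enumeration."""
    if source not in graph or target not in graph:
        return []
    out = []
    for nodes in nx.all_simple_paths(graph, source, target, cutoff=2 * budget):
        rxns = [reaction_of(n) for n in nodes[1::2]]
        if len(set(rxns)) != len(rxns):
            continue
        if len(rxns) <= budget:
            out.append(tuple(nodes))
    return out


def random_reaction_set(rng: random.Random, n_rxns: int):
    """Random reaction set over <= 8 metabolites for oracle comparison."""
    mets = [f"m{i}" for i in range(rng.randint(4, 8))]
    rxns = []
    for i in range(n_rxns):
        subs = rng.sample(mets, rng.randint(1, 2))
        prods = rng.sample([m for m in mets if m not in subs], rng.randint(1, 2))
        parts = [Participant(metabolite=m, coefficient=Fraction(-1)) for m in subs] + [
            Participant(metabolite=m, coefficient=Fraction(1)) for m in prods
        ]
        rxns.append(
            ReactionEntry(
                id=f"r{i}",
                participants=parts,
                direction=Direction.REVERSIBLE
                if rng.random() < 0.3
                else Direction.FORWARD,
            )
        )
    return rxns, mets
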