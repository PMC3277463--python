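"""Pathway prospecting: exhaustive minimal-path enumeration between
metabolites on a bipartite metabolite-reaction graph.

A standardized reaction corpus becomes a directed bipartite graph
(substrate -> reaction -> product arcs; a reversible reaction contributes
two orientation nodes).  Currency metabolites (H⁺, H₂O, ATP/ADP, NAD(P)(H),
CO₂, Pi by default) carry no arcs — otherwise nearly everything is two
steps from everything via ATP.  Paths are connective only: no
stoichiometric feasibility is enforced, which is exactly what gives the
enumeration its scaling.

:func:`enumerate_min_paths` returns *all* paths of reaction-length at most
L* + slack, where L* is the minimum length; enumeration is BFS
layer-by-layer with backtracking over predecessor maps, and output order
is deterministic (length ascending, then lexicographic by reaction ids).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx

from .model import Direction, ReactionEntry

#: Ubiquitous cofactors excluded from path searches by default.
DEFAULT_CURRENCY = frozenset(
    {"h", "h+", "h2o", "atp", "adp", "pi", "ppi", "nad", "nadh", "nadp", "nadph", "co2"}
)


@dataclass
class RxnGraph:
    """Directed bipartite graph: metabolite nodes and reaction-orientation
    nodes (``rid`` forward, ``rid~rev`` for the mirrored orientation)."""

    graph: nx.DiGraph
    excluded: frozenset[str]

    @staticmethod
    def reaction_of(node: str) -> str:
        """Underlying reaction id of an orientation node."""
        return node[:-4] if node.endswith("~rev") else node

    def metabolite_nodes(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d["kind"] == "metabolite"}


def build_graph(
    reactions: Iterable[ReactionEntry],
    currency: frozenset[str] = DEFAULT_CURRENCY,
    keys: Optional[dict[str, str]] = None,
) -> RxnGraph:
    """Build the bipartite graph from reactions.

    ``keys`` optionally maps metabolite ids to canonical keys so that
    reconciled corpora connect across sources; by default ids are used
    verbatim.  Reactions with only-currency sides contribute no arcs for
    that side; a reversible reaction adds a mirrored ``~rev`` node.
    """
    g = nx.DiGraph()
    ident = (lambda m: keys.get(m, m)) if keys else (lambda m: m)

    def add_orient(node: str, subs: list[str], prods: list[str]) -> None:
        g.add_node(node, kind="reaction")
        for s in subs:
            g.add_node(s, kind="metabolite")
            g.add_edge(s, node)
        for p in prods:
            g.add_node(p, kind="metabolite")
            g.add_edge(node, p)

    for r in reactions:
        subs = sorted(
            {ident(p.metabolite) for p in r.reactants}
            - {c.lower() for c in currency} - set(currency)
        )
        prods = sorted(
            {ident(p.metabolite) for p in r.products}
            - {c.lower() for c in currency} - set(currency)
        )
        # currency filter applies case-insensitively on raw ids too
        subs = [m for m in subs if m.lower() not in currency]
        prods = [m for m in prods if m.lower() not in currency]
        add_orient(r.id, subs, prods)
        if r.direction is Direction.REVERSIBLE:
            add_orient(f"{r.id}~rev", prods, subs)
    return RxnGraph(graph=g, excluded=frozenset(currency))


@dataclass(frozen=True)
class Path:
    """Alternating metabolite, reaction, metabolite, ... sequence."""

    nodes: tuple[str, ...]

    @property
    def length(self) -> int:
        """Number of reaction steps."""
        return (len(self.nodes) - 1) // 2

    @property
    def reactions(self) -> tuple[str, ...]:
        return tuple(RxnGraph.reaction_of(n) for n in self.nodes[1::2])

    @property
    def metabolites(self) -> tuple[str, ...]:
        return self.nodes[0::2]


@dataclass
class PathEnumeration:
    paths: list[Path] = field(default_factory=list)
    reachable: bool = True
    truncated: bool = False
    min_length: Optional[int] = None


def enumerate_min_paths(
    g: RxnGraph,
    source: str,
    target: str,
    slack: int = 0,
    cap: int = 10000,
) -> PathEnumeration:
    """All simple source->target paths within ``slack`` of minimal length.

    A path may not repeat a reaction (in either orientation) nor revisit a
    metabolite.  Output is deterministic: ascending length, then
    lexicographic by the reaction-id sequence.  If more than ``cap`` paths
    exist the list is truncated and flagged.
    """
    graph = g.graph
    if source not in graph or target not in graph:
        return PathEnumeration(paths=[], reachable=False)

    # reaction-length distance-to-target for pruning (metabolite nodes only)
    dist_to_target: dict[str, int] = {target: 0}
    frontier = [target]
    while frontier:
        nxt = []
        for met in frontier:
            for rnode in graph.predecessors(met):
                for sub in graph.predecessors(rnode):
                    if sub not in dist_to_target:
                        dist_to_target[sub] = dist_to_target[met] + 1
                        nxt.append(sub)
        frontier = nxt
    if source not in dist_to_target:
        return PathEnumeration(paths=[], reachable=False)

    lstar = dist_to_target[source]
    budget = lstar + slack
    out: list[Path] = []
    truncated = False

    def dfs(met: str, trail: list[str], used_rxns: set[str], used_mets: set[str], depth: int):
        nonlocal truncated
        if truncated:
            return
        if met == target:
            out.append(Path(nodes=tuple(trail)))
            if len(out) > cap:
                truncated = True
            return
        if depth >= budget or dist_to_target.get(met, budget + 1) > budget - depth:
            return
        for rnode in sorted(graph.successors(met)):
            rid = RxnGraph.reaction_of(rnode)
            if rid in used_rxns:
                continue
            for prod in sorted(graph.successors(rnode)):
                if prod in used_mets:
                    continue
                trail.extend([rnode, prod])
                used_rxns.add(rid)
                used_mets.add(prod)
                dfs(prod, trail, used_rxns, used_mets, depth + 1)
                used_mets.discard(prod)
                used_rxns.discard(rid)
                del trail[-2:]

    dfs(source, [source], set(), {source}, 0)
    out.sort(key=lambda p: (p.length, p.reactions))
    if truncated:
        out = out[:cap]
    return PathEnumeration(
        paths=out, reachable=True, truncated=truncated, min_length=lstar
    )
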