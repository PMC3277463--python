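"""Cross-source reconciliation: duplicate consolidation, canonical reaction
keys, iterative context-based resolution, and model comparison.

Naive string comparison recognises almost no shared reactions across
models (different names, arrows, cofactor spellings, proton conventions).
Reconciliation instead compares *structure-level* canonical keys:

* metabolites join on connectivity-level SMILES keys;
* reactions join on a :class:`ReactionKey` built from the sorted multiset
  of (participant key, |coefficient|, side class), with direction
  suppressed, compartments simplified to internal/transport, and free
  protons excluded — so representations that differ only in direction,
  participant order or protonation collapse.

Unresolved metabolites are then resolved *by context*: a reaction with
exactly one unknown participant is matched against fully resolved
reactions sharing the remaining participant multiset; a unique match
pins the unknown's structure.  Passes repeat until a fixed point, since
each resolution can unlock further matches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Optional

from . import chem_struct
from .balance import PROTON_IDS
from .lex_phonetic import MatchSuggestion, normalize_name
from .model import MetaboliteEntry, Model, ReactionEntry, Resolution

PROTON_KEY = chem_struct.structure_key("[H+]").key

#: Default cofactor families collapsed in ``family`` mode, as common-name
#: aliases (matched against metabolite names case-insensitively).  All the
#: default families share one class token: family grouping ignores which
#: redox cofactor an organism's enzyme happens to use, so NAD(H), NADP(H)
#: and F420(H2) variants of a transformation land on the same family key.
#: Configure distinct tokens for finer-grained families.
DEFAULT_COFACTOR_FAMILIES: dict[str, frozenset[str]] = {
    "redox-cofactor": frozenset(
        {"nad", "nad+", "nadh", "c00003", "c00004",
         "nadp", "nadp+", "nadph", "c00006", "c00005",
         "f420", "f420-2", "f420h2", "f420-2h2"}
    ),
}


class UnresolvedParticipant(Exception):
    """A reaction participant has no connectivity key."""


def metabolite_keys(model: Model) -> dict[str, chem_struct.StructureKey]:
    """Connectivity keys for every structured, wildcard-free metabolite."""
    keys = {}
    for mid, entry in model.metabolites.items():
        if entry.structure:
            try:
                k = chem_struct.structure_key(entry.structure, "connectivity")
            except chem_struct.StructureError:
                continue
            if not k.wildcard:
                keys[mid] = k
    return keys


def _is_proton(mid: str, key: Optional[str]) -> bool:
    return key == PROTON_KEY or mid.lower() in PROTON_IDS


def _scale_normalize(coeffs: list[Fraction]) -> list[Fraction]:
    """Divide out a global scale so doubled stoichiometries compare equal."""
    if not coeffs:
        return coeffs
    lcm = 1
    for c in coeffs:
        lcm = lcm * c.denominator // math.gcd(lcm, c.denominator)
    ints = [int(c * lcm) for c in coeffs]
    g = 0
    for v in ints:
        g = math.gcd(g, abs(v))
    return [Fraction(v, g) for v in ints] if g else coeffs


@dataclass(frozen=True)
class ReactionKey:
    """Canonical, direction- and order-invariant reaction identity string."""

    key: str
    mode: str = "strict"
    compartment_class: str = "internal"  # internal | transport


def _participant_tokens(
    r: ReactionEntry,
    ids: dict[str, chem_struct.StructureKey],
    mode: str,
    cofactor_classes: Optional[dict[str, str]],
) -> list[tuple[str, Fraction]]:
    """(token, signed scale-normalised coefficient) per non-proton slot."""
    toks: list[tuple[str, Fraction]] = []
    coeffs: list[Fraction] = []
    for p in r.participants:
        sk = ids.get(p.metabolite)
        key = sk.key if sk else None
        if _is_proton(p.metabolite, key):
            continue
        if key is None:
            raise UnresolvedParticipant(
                f"reaction {r.id!r}: no connectivity key for {p.metabolite!r}"
            )
        if mode == "family" and cofactor_classes and key in cofactor_classes:
            key = cofactor_classes[key]
        toks.append((key, p.coefficient))
        coeffs.append(p.coefficient)
    if not toks:
        raise UnresolvedParticipant(f"reaction {r.id!r}: only protons present")
    norm = _scale_normalize(coeffs)
    return [(k, c) for (k, _), c in zip(toks, norm)]


def _sided_signature(tokens: list[tuple[str, Fraction]]) -> str:
    """Direction-invariant signature of signed participant tokens."""
    lhs = tuple(sorted((k, str(-c)) for k, c in tokens if c < 0))
    rhs = tuple(sorted((k, str(c)) for k, c in tokens if c > 0))
    side0, side1 = sorted([lhs, rhs])
    fmt = lambda side: ",".join(f"{k}:{c}" for k, c in side)  # noqa: E731
    return f"{{{fmt(side0)}}}<>{{{fmt(side1)}}}"


def cofactor_classes_from_models(
    models: Iterable[Model],
    families: dict[str, frozenset[str]] = DEFAULT_COFACTOR_FAMILIES,
) -> dict[str, str]:
    """Map connectivity keys of known cofactors to a family class token.

    Families are configured as common-name alias sets; every structured
    metabolite whose normalised name hits an alias contributes its key.
    """
    classes: dict[str, str] = {}
    for m in models:
        keys = metabolite_keys(m)
        for mid, entry in m.metabolites.items():
            if mid not in keys:
                continue
            names = {mid.lower()} | {n.lower() for n in entry.names}
            names |= {normalize_name(n).render() for n in entry.names if n}
            for token, aliases in families.items():
                if names & aliases:
                    classes[keys[mid].key] = token
    return classes


def reaction_key(
    r: ReactionEntry,
    ids: dict[str, chem_struct.StructureKey],
    mode: str = "strict",
    cofactor_classes: Optional[dict[str, str]] = None,
) -> ReactionKey:
    """Canonical reaction identity key.

    ``strict`` keeps cofactors distinct; ``family`` additionally collapses
    configured cofactor pairs (NAD(H)/NADP(H)/F420) to a class token so
    alternate-cofactor variants of one transformation group together.
    Raises :class:`UnresolvedParticipant` if any non-proton participant
    lacks a key.
    """
    if mode not in ("strict", "family"):
        raise ValueError(f"unknown mode {mode!r}")
    tokens = _participant_tokens(r, ids, mode, cofactor_classes)
    comp_class = "transport" if len(r.compartments) > 1 else "internal"
    return ReactionKey(
        key=f"{comp_class}|{_sided_signature(tokens)}", mode=mode,
        compartment_class=comp_class,
    )


# ---------------------------------------------------------------------------
# Metabolite consolidation


@dataclass
class ConsolidationMap:
    """Partition of (model, metabolite) entries into identity groups."""

    groups: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    representatives: dict[str, tuple[str, str]] = field(default_factory=dict)
    stereo_subgroups: dict[str, dict[str, list[tuple[str, str]]]] = field(default_factory=dict)
    unmerged: list[tuple[str, str]] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)

    def group_of(self, model: str, mid: str) -> Optional[str]:
        for key, members in self.groups.items():
            if (model, mid) in members:
                return key
        return None


def consolidate_metabolites(sources: list[Model]) -> ConsolidationMap:
    """Group metabolite entries across sources by connectivity key.

    Entries whose stereo keys conflict within a connectivity group are kept
    in distinct stereo subgroups (flagged, never merged at stereo level).
    Structure-less entries are never merged — a shared name is not identity
    evidence (the same name can denote different molecules).
    """
    cmap = ConsolidationMap()
    for m in sources:
        for mid, entry in m.metabolites.items():
            if not entry.structure:
                cmap.unmerged.append((m.name, mid))
                continue
            try:
                conn = chem_struct.structure_key(entry.structure, "connectivity")
                stereo = chem_struct.structure_key(entry.structure, "stereo")
            except chem_struct.StructureError:
                cmap.unmerged.append((m.name, mid))
                continue
            if conn.wildcard:
                cmap.unmerged.append((m.name, mid))
                continue
            member = (m.name, mid)
            cmap.groups.setdefault(conn.key, []).append(member)
            cmap.stereo_subgroups.setdefault(conn.key, {}).setdefault(
                stereo.key, []
            ).append(member)
            if len(cmap.groups[conn.key]) > 1:
                cmap.provenance.append(
                    f"merge {member} into group {conn.key} "
                    f"(with {cmap.groups[conn.key][0]})"
                )
    for key, members in cmap.groups.items():
        cmap.representatives[key] = min(members)
    return cmap


# ---------------------------------------------------------------------------
# Iterative context-based resolution


@dataclass
class ResolutionLogEntry:
    pass_number: int
    model: str
    metabolite: str
    assigned_structure: str
    assigned_key: str
    via_reaction: str


@dataclass
class ResolutionLog:
    assignments: list[ResolutionLogEntry] = field(default_factory=list)
    suggestions: dict[tuple[str, str], list[MatchSuggestion]] = field(default_factory=dict)
    conflicts: list[str] = field(default_factory=list)
    passes: int = 0

    @property
    def resolved(self) -> set[tuple[str, str]]:
        return {(e.model, e.metabolite) for e in self.assignments}


def _context_signature(
    tokens: list[tuple[Optional[str], Fraction]],
) -> tuple[str, tuple[int, str]]:
    """Signature of a reaction with one distinguished (possibly unknown) slot.

    ``tokens`` carry ``None`` as the key of the distinguished slot.  The
    full participant list is scale-normalised, then the orientation (the
    whole reaction may be written flipped) is canonicalised by choosing the
    lexicographically smaller rendering.  Returns (signature-of-context,
    (slot side, slot coefficient)) in the canonical orientation.
    """
    coeffs = _scale_normalize([c for _, c in tokens])
    tokens = [(k, c) for (k, _), c in zip(tokens, coeffs)]

    def render(tks):
        ctx = tuple(sorted((k, str(c)) for k, c in tks if k is not None))
        slot = next((c for k, c in tks if k is None))
        return ctx, (1 if slot > 0 else -1, str(abs(slot)))

    fwd = render(tokens)
    rev = render([(k, -c) for k, c in tokens])
    return min(fwd, rev)


def _reaction_tokens_with_slot(
    r: ReactionEntry,
    keys: dict[str, chem_struct.StructureKey],
    slot_metabolite: str,
) -> Optional[list[tuple[Optional[str], Fraction]]]:
    """Tokens with the slot metabolite's key replaced by None.

    Free protons are excluded (their presence varies by convention); any
    other unresolved participant makes the context unusable -> None.
    """
    toks: list[tuple[Optional[str], Fraction]] = []
    for p in r.participants:
        sk = keys.get(p.metabolite)
        key = sk.key if sk else None
        if p.metabolite == slot_metabolite:
            toks.append((None, p.coefficient))
            continue
        if _is_proton(p.metabolite, key):
            continue
        if key is None:
            return None
        toks.append((key, p.coefficient))
    if sum(1 for k, _ in toks if k is None) != 1:
        return None
    return toks


AcceptedMapping = dict[tuple[str, str], str]  # (model, metabolite id) -> SMILES


def iterative_resolve(
    corpus: list[Model],
    accepted: Optional[AcceptedMapping] = None,
    max_passes: int = 50,
    suggestion_k: int = 5,
) -> ResolutionLog:
    """Resolve structure-less metabolites by reaction-context matching.

    Curator-accepted mappings (if any) are applied first.  Then, repeatedly:
    every reaction with exactly one unresolved participant is matched
    against the index of fully resolved reactions sharing its remaining
    participant multiset (direction suppressed, coefficients compared up to
    a global scale, free protons ignored).  A unique candidate structure is
    assigned; ambiguous slots yield curator suggestions instead.  A later
    pass contradicting an earlier assignment is logged as a conflict, never
    silently overwritten.  Assignments mutate the corpus entries in place.
    """
    log = ResolutionLog()
    if accepted:
        for (mname, mid), smiles in accepted.items():
            for m in corpus:
                if m.name == mname and mid in m.metabolites:
                    entry = m.metabolites[mid]
                    entry.structure = smiles
                    entry.resolution = chem_struct.resolution_class(entry)

    assigned_keys: dict[tuple[str, str], str] = {}
    for pass_no in range(1, max_passes + 1):
        log.passes = pass_no
        keys = {m.name: metabolite_keys(m) for m in corpus}

        # index: context signature -> {candidate key: example (smiles, rxn)}
        index: dict[tuple, dict[str, tuple[str, str]]] = {}
        for m in corpus:
            mkeys = keys[m.name]
            for r in m.reactions.values():
                parts = [p.metabolite for p in r.participants]
                if not all(
                    p in mkeys or _is_proton(p, None) for p in parts
                ):
                    continue
                for p in parts:
                    if _is_proton(p, mkeys[p].key if p in mkeys else None):
                        continue
                    toks = _reaction_tokens_with_slot(r, mkeys, p)
                    if toks is None:
                        continue
                    sig = _context_signature(toks)
                    slotkey = mkeys[p].key
                    index.setdefault(sig, {}).setdefault(
                        slotkey, (m.metabolites[p].structure, f"{m.name}:{r.id}")
                    )

        progress = False
        for m in corpus:
            mkeys = keys[m.name]
            for r in m.reactions.values():
                unresolved = [
                    p.metabolite
                    for p in r.participants
                    if p.metabolite not in mkeys
                    and not _is_proton(p.metabolite, None)
                ]
                if len(unresolved) != 1:
                    continue
                target = unresolved[0]
                toks = _reaction_tokens_with_slot(r, mkeys, target)
                if toks is None:
                    continue
                sig = _context_signature(toks)
                candidates = index.get(sig, {})
                # a partially specified entry (R-group/wildcard) is a class,
                # not an unknown: it only ever receives suggestions
                partial = m.metabolites[target].resolution is Resolution.PARTIAL
                if len(candidates) == 1 and not partial:
                    (ckey, (smiles, via)) = next(iter(candidates.items()))
                    prev = assigned_keys.get((m.name, target))
                    if prev is not None and prev != ckey:
                        log.conflicts.append(
                            f"{m.name}:{target}: pass {pass_no} proposes {ckey} "
                            f"but {prev} was assigned earlier"
                        )
                        continue
                    if prev == ckey:
                        continue
                    entry = m.metabolites[target]
                    entry.structure = smiles
                    entry.resolution = chem_struct.resolution_class(entry)
                    assigned_keys[(m.name, target)] = ckey
                    log.assignments.append(
                        ResolutionLogEntry(
                            pass_number=pass_no,
                            model=m.name,
                            metabolite=target,
                            assigned_structure=smiles,
                            assigned_key=ckey,
                            via_reaction=via,
                        )
                    )
                    progress = True
                elif candidates:
                    sugg = [
                        MatchSuggestion(
                            candidate=via, score=Fraction(1, 2),
                            evidence="reaction-context", rank=i + 1,
                        )
                        for i, (ck, (sm, via)) in enumerate(
                            sorted(candidates.items())[:suggestion_k]
                        )
                    ]
                    log.suggestions[(m.name, target)] = sugg
        if not progress:
            break
    return log


# ---------------------------------------------------------------------------
# Source comparison


@dataclass
class OverlapTable:
    """Venn-style overlap of models over canonical keys."""

    level: str
    membership: dict[str, frozenset[str]] = field(default_factory=dict)
    excluded: dict[str, int] = field(default_factory=dict)

    def count(self, *models: str, exact: bool = False) -> int:
        """Keys present in all the given models (exactly those, if exact)."""
        want = frozenset(models)
        if exact:
            return sum(1 for v in self.membership.values() if v == want)
        return sum(1 for v in self.membership.values() if want <= v)

    def shared_all(self) -> int:
        all_models = frozenset().union(*self.membership.values()) if self.membership else frozenset()
        return sum(1 for v in self.membership.values() if v == all_models)

    def to_dict(self) -> dict:
        regions: dict[str, int] = {}
        for v in self.membership.values():
            tag = "&".join(sorted(v))
            regions[tag] = regions.get(tag, 0) + 1
        return {"level": self.level, "regions": regions, "excluded": self.excluded}


def compare_sources(
    sources: list[Model],
    level: str = "metabolite",
    mode: str = "strict",
    cofactor_classes: Optional[dict[str, str]] = None,
) -> OverlapTable:
    """Compare >= 2 models on standardized keys, compartments and
    reversibility suppressed.

    Metabolite level compares connectivity keys of fully resolved entries;
    reaction level compares strict (or family) reaction keys of reactions
    whose non-proton participants are all resolved.  Entries with partial
    or no resolution are excluded from the comparison and tallied
    separately per model.
    """
    if len(sources) < 2:
        raise ValueError("compare_sources needs at least two models")
    table = OverlapTable(level=level)
    for m in sources:
        keys = metabolite_keys(m)
        excluded = 0
        if level == "metabolite":
            for mid, entry in m.metabolites.items():
                if mid in keys and entry.resolution is Resolution.FULL:
                    table.membership[keys[mid].key] = table.membership.get(
                        keys[mid].key, frozenset()
                    ) | {m.name}
                else:
                    excluded += 1
        elif level == "reaction":
            for r in m.reactions.values():
                try:
                    rk = reaction_key(r, keys, mode=mode, cofactor_classes=cofactor_classes)
                except UnresolvedParticipant:
                    excluded += 1
                    continue
                table.membership[rk.key] = table.membership.get(
                    rk.key, frozenset()
                ) | {m.name}
        else:
            raise ValueError(f"unknown comparison level {level!r}")
        table.excluded[m.name] = excluded
    return table
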