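"""Parsing of reaction-string dialects, tabular model loading, and SBML I/O.

Published genome-scale models write the same reaction many ways: different
arrow glyphs (``< = = >``, ``-- >``, ``<->``, ``->``, ``=``, ``⇔``, ``→``),
compartment prefixes (``[c]:``, ``[c]``, or none), and naming conventions.
This module parses all of those dialects into a single
:class:`~metreconcile.model.ReactionEntry` representation and serialises a
canonical dialect back out.

The arrow grammar is whitespace-tolerant: sources embed spaces inside
arrows, so ``< = = >`` and ``<==>`` are the same token.  Participant lists
are split on ``+`` at top level only (a ``+`` must stand alone between
whitespace, so names like ``f420-2`` survive).
"""

from __future__ import annotations

import re
import warnings
from fractions import Fraction
from typing import Optional

import libsbml

from .model import (
    Direction,
    MetaboliteEntry,
    Model,
    ModelError,
    Participant,
    ReactionEntry,
    Resolution,
)
from . import chem_struct


class ReactionParseError(ValueError):
    """Raised when a reaction string has no recognisable arrow or grammar."""


def _spaced(literal: str) -> str:
    """Regex for a multi-char arrow with optional whitespace between glyphs."""
    return r"\s*".join(re.escape(ch) for ch in literal)


# Ordered longest-first so "< = = >" wins over "< = >" wins over "=".
_ARROWS: list[tuple[str, Direction, bool]] = [
    ("<==>", Direction.REVERSIBLE, False),
    ("<=>", Direction.REVERSIBLE, False),
    ("<->", Direction.REVERSIBLE, False),
    ("<--", Direction.BACKWARD, False),
    ("<-", Direction.BACKWARD, False),
    ("-->", Direction.FORWARD, False),
    ("->", Direction.FORWARD, False),
    ("⇔", Direction.REVERSIBLE, False),
    ("→", Direction.FORWARD, False),
    ("=", Direction.FORWARD, True),  # bare KEGG "=": forward with a warning
]

_ARROW_RE = re.compile(
    "|".join(f"(?P<a{i}>(?<!\\S){_spaced(lit)}(?!\\S))" for i, (lit, _, _) in enumerate(_ARROWS))
)

_PREFIX_RE = re.compile(r"^\s*\[(?P<tag>[A-Za-z0-9]+)\]\s*:?\s*")
_SUFFIX_RE = re.compile(r"^(?P<name>.+?)\[(?P<tag>[A-Za-z0-9]+)\]$")
_COEFF_RE = re.compile(r"^\(?(?P<num>\d+(?:\.\d+)?(?:/\d+)?)\)?$")


def _parse_side(text: str, sign: int, compartment: Optional[str], raw: str) -> list[Participant]:
    tokens = re.split(r"(?:(?<=\s)|^)\+(?:(?=\s)|$)", text)
    participants: list[Participant] = []
    for tok in tokens:
        tok = tok.strip()
        if not tok:
            raise ReactionParseError(f"dangling '+' in reaction string {raw!r}")
        words = tok.split()
        coeff = Fraction(1)
        if len(words) > 1:
            m = _COEFF_RE.match(words[0])
            if m:
                num = m.group("num")
                coeff = Fraction(num) if "/" in num else Fraction(str(num))
                words = words[1:]
        name = " ".join(words)
        comp = compartment
        sm = _SUFFIX_RE.match(name)
        if sm:
            name, comp = sm.group("name"), sm.group("tag")
        participants.append(Participant(metabolite=name, coefficient=sign * coeff, compartment=comp))
    return participants


def parse_reaction_string(
    text: str,
    dialect: str = "auto",
    reaction_id: Optional[str] = None,
    source: Optional[str] = None,
) -> ReactionEntry:
    """Parse one reaction string in any of the supported dialects.

    Reactants get negative coefficients, products positive (default
    magnitude 1).  Bidirectional arrows yield ``REVERSIBLE``; a bare ``=``
    is stored as ``FORWARD`` with a warning, since KEGG-style equations do
    not pin a direction.  A ``[c]:``/``[c]`` prefix tags every participant;
    per-metabolite ``name[e]`` suffixes override it.
    """
    if not text or not text.strip():
        raise ReactionParseError("empty reaction string")
    raw = text
    work = text.strip()

    compartment = None
    pm = _PREFIX_RE.match(work)
    if pm:
        compartment = pm.group("tag")
        work = work[pm.end():]

    am = _ARROW_RE.search(work)
    if am is None:
        raise ReactionParseError(f"no recognizable reaction arrow in {raw!r}")
    idx = int(am.lastgroup[1:])
    _, direction, warn = _ARROWS[idx]
    if warn and dialect == "auto":
        warnings.warn(
            f"bare '=' arrow in {raw!r}: direction stored as forward", stacklevel=2
        )
    lhs, rhs = work[: am.start()], work[am.end():]
    if not lhs.strip() or not rhs.strip():
        raise ReactionParseError(f"missing reactants or products in {raw!r}")
    if direction is Direction.BACKWARD:
        # normalise: swap sides so participants keep reactant<0/product>0
        lhs, rhs = rhs, lhs
        direction = Direction.FORWARD

    participants = _parse_side(lhs, -1, compartment, raw) + _parse_side(rhs, +1, compartment, raw)
    return ReactionEntry(
        id=reaction_id or raw.strip(),
        participants=participants,
        direction=direction,
        source=source,
    )


def _fmt_coeff(c: Fraction) -> str:
    mag = abs(c)
    if mag == 1:
        return ""
    return (str(mag.numerator) if mag.denominator == 1 else str(mag)) + " "


def render_reaction_string(r: ReactionEntry) -> str:
    """Serialise in the canonical dialect: ``[c]: a + 2 b <=> c``.

    Parsing the rendered string again yields the same participants and
    direction (idempotent canonical form).  The compartment prefix is used
    only when all participants share one tag; otherwise per-metabolite
    suffixes are written.
    """
    comps = {p.compartment for p in r.participants}
    shared = comps.pop() if len(comps) == 1 else None

    def term(p: Participant) -> str:
        name = p.metabolite
        if shared is None and p.compartment:
            name = f"{name}[{p.compartment}]"
        return f"{_fmt_coeff(p.coefficient)}{name}"

    lhs = " + ".join(term(p) for p in r.reactants)
    rhs = " + ".join(term(p) for p in r.products)
    arrow = "<=>" if r.direction is Direction.REVERSIBLE else "->"
    prefix = f"[{shared}]: " if shared else ""
    return f"{prefix}{lhs} {arrow} {rhs}"


# ---------------------------------------------------------------------------
# Tabular loading


def load_model(
    reaction_table,
    metabolite_table=None,
    name: str = "model",
    dialect: str = "auto",
) -> Model:
    """Load a model from tab-separated tables.

    Reaction file columns: ``id``, ``equation``, optional ``ec``/``genes``.
    Metabolite file columns: ``id``, ``names`` (``|``-separated),
    ``formula``, ``charge``, ``smiles``.  Participants without a metabolite
    row are auto-created with resolution ``none``; rows with a SMILES are
    classified ``full``/``partial`` from the structure.
    """
    import pandas as pd

    model = Model(name=name)
    if metabolite_table is not None:
        met_df = pd.read_csv(metabolite_table, sep="\t", dtype=str).fillna("")
        for _, row in met_df.iterrows():
            charge: Optional[int] = None
            if row.get("charge", ""):
                ctext = str(row["charge"]).strip()
                try:
                    charge = int(ctext)
                except ValueError:
                    raise ModelError(f"malformed charge {ctext!r} for metabolite {row['id']!r}")
            entry = MetaboliteEntry(
                id=row["id"],
                names=[n for n in str(row.get("names", "")).split("|") if n] or [row["id"]],
                formula=row.get("formula") or None,
                charge=charge,
                structure=row.get("smiles") or None,
                source=name,
            )
            entry.resolution = chem_struct.resolution_class(entry)
            model.metabolites[entry.id] = entry

    rxn_df = pd.read_csv(reaction_table, sep="\t", dtype=str).fillna("")
    for _, row in rxn_df.iterrows():
        r = parse_reaction_string(row["equation"], dialect=dialect, reaction_id=row["id"], source=name)
        r.ec = row.get("ec") or None
        r.genes = row.get("genes") or None
        model.add_reaction(r)
    model.validate()
    return model


# ---------------------------------------------------------------------------
# SBML export / import (Level 3 Version 1 + fbc for objective and bounds)

_SID_RE = re.compile(r"[^A-Za-z0-9_]")


def _sid(raw: str, taken: dict[str, str], prefix: str) -> str:
    """Deterministic SId sanitisation with collision check."""
    s = _SID_RE.sub("_", raw)
    if not s or not (s[0].isalpha() or s[0] == "_"):
        s = "_" + s
    s = prefix + s
    if s in taken and taken[s] != raw:
        raise ModelError(f"SBML id collision: {raw!r} and {taken[s]!r} both map to {s!r}")
    taken[s] = raw
    return s


_DEFAULT_BOUND = 1000.0


def export_sbml(model: Model, path=None) -> str:
    """Write the model as SBML L3V1 with the fbc extension.

    Round-trip safe with :func:`import_sbml` for stoichiometry, direction,
    compartments, bounds and objective.  Metabolite/reaction ids are
    sanitised deterministically; colliding sanitisations raise.
    """
    model.validate()
    doc = libsbml.SBMLDocument(libsbml.SBMLNamespaces(3, 1, "fbc", 2))
    doc.setPackageRequired("fbc", False)
    sb = doc.createModel()
    sb.setId(_SID_RE.sub("_", model.name) or "model")
    sb.setName(model.name)
    mplug = sb.getPlugin("fbc")
    mplug.setStrict(False)

    comps = sorted(
        {p.compartment or "c" for r in model.reactions.values() for p in r.participants}
        | {m.compartment for m in model.metabolites.values() if m.compartment}
    )
    for ctag in comps or ["c"]:
        c = sb.createCompartment()
        c.setId(ctag)
        c.setConstant(True)

    taken: dict[str, str] = {}
    met_sid: dict[str, str] = {}
    used = {
        p.metabolite for r in model.reactions.values() for p in r.participants
    } | set(model.metabolites)
    for mid in sorted(used):
        entry = model.metabolites.get(mid)
        sid = _sid(mid, taken, "M_")
        met_sid[mid] = sid
        sp = sb.createSpecies()
        sp.setId(sid)
        sp.setName((entry.names[0] if entry and entry.names else mid))
        comp = (entry.compartment if entry else None) or next(
            (p.compartment for r in model.reactions.values() for p in r.participants
             if p.metabolite == mid and p.compartment),
            None,
        )
        sp.setCompartment(comp or "c")
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        if entry is not None:
            fplug = sp.getPlugin("fbc")
            if entry.charge is not None:
                fplug.setCharge(entry.charge)
            if entry.formula:
                try:
                    fplug.setChemicalFormula(
                        chem_struct.parse_formula(entry.formula).hill()
                    )
                except chem_struct.FormulaError:
                    pass
            note = {}
            if entry.structure:
                note["smiles"] = entry.structure
            if len(entry.names) > 1:
                note["names"] = "|".join(entry.names)
            if note:
                body = "".join(
                    f"<p>{k.upper()}: {v}</p>" for k, v in sorted(note.items())
                )
                sp.setNotes(
                    f'<body xmlns="http://www.w3.org/1999/xhtml">{body}</body>'
                )

    # flux bound parameters
    def _param(value: float, cache: dict[float, str]) -> str:
        if value not in cache:
            pid = f"fb_{len(cache)}"
            par = sb.createParameter()
            par.setId(pid)
            par.setValue(value)
            par.setConstant(True)
            cache[value] = pid
        return cache[value]

    pcache: dict[float, str] = {}
    rxn_sid: dict[str, str] = {}
    rtaken: dict[str, str] = {}
    for rid in sorted(model.reactions):
        r = model.reactions[rid]
        sid = _sid(rid, rtaken, "R_")
        rxn_sid[rid] = sid
        rx = sb.createReaction()
        rx.setId(sid)
        rx.setName(rid)
        rx.setReversible(r.direction is Direction.REVERSIBLE)
        rx.setFast(False)
        if r.genes:
            rx.setNotes(
                f'<body xmlns="http://www.w3.org/1999/xhtml"><p>GENES: {r.genes}</p></body>'
            )
        for p in r.participants:
            ref = rx.createReactant() if p.coefficient < 0 else rx.createProduct()
            ref.setSpecies(met_sid[p.metabolite])
            ref.setStoichiometry(float(abs(p.coefficient)))
            ref.setConstant(True)
        lb, ub = model.bounds.get(
            rid,
            (-_DEFAULT_BOUND, _DEFAULT_BOUND)
            if r.direction is Direction.REVERSIBLE
            else (0.0, _DEFAULT_BOUND),
        )
        rplug = rx.getPlugin("fbc")
        rplug.setLowerFluxBound(_param(float(lb), pcache))
        rplug.setUpperFluxBound(_param(float(ub), pcache))

    if model.objective is not None:
        obj = mplug.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        fo = obj.createFluxObjective()
        fo.setReaction(rxn_sid[model.objective])
        fo.setCoefficient(1.0)
        mplug.setActiveObjectiveId("obj")

    text = libsbml.writeSBMLToString(doc)
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text


_NOTE_RE = re.compile(r"<p>\s*([A-Z]+)\s*:\s*(.*?)\s*</p>", re.DOTALL)


def _notes_dict(node) -> dict[str, str]:
    if not node.isSetNotes():
        return {}
    return {k.lower(): v for k, v in _NOTE_RE.findall(node.getNotesString())}


def _frac(x: float) -> Fraction:
    return Fraction(x).limit_denominator(10**6)


def import_sbml(text_or_path: str) -> Model:
    """Read an SBML document (string or path) back into a :class:`Model`."""
    if "<sbml" in text_or_path:
        doc = libsbml.readSBMLFromString(text_or_path)
    else:
        doc = libsbml.readSBMLFromFile(text_or_path)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR):
        raise ModelError(doc.getErrorLog().toString())
    sb = doc.getModel()
    model = Model(name=sb.getName() or sb.getId())

    for i in range(sb.getNumSpecies()):
        sp = sb.getSpecies(i)
        mid = sp.getId()
        mid = mid[2:] if mid.startswith("M_") else mid
        fplug = sp.getPlugin("fbc")
        notes = _notes_dict(sp)
        names = notes.get("names", "").split("|") if "names" in notes else []
        entry = MetaboliteEntry(
            id=mid,
            names=names or [sp.getName() or mid],
            formula=(fplug.getChemicalFormula() or None) if fplug else None,
            charge=(fplug.getCharge() if fplug and fplug.isSetCharge() else None),
            structure=notes.get("smiles"),
            compartment=sp.getCompartment() or None,
        )
        entry.resolution = (
            chem_struct.resolution_class(entry) if entry.structure else Resolution.NONE
        )
        model.metabolites[mid] = entry

    params = {
        sb.getParameter(i).getId(): sb.getParameter(i).getValue()
        for i in range(sb.getNumParameters())
    }
    for i in range(sb.getNumReactions()):
        rx = sb.getReaction(i)
        rid = rx.getName() or rx.getId()
        participants = []
        for j in range(rx.getNumReactants()):
            ref = rx.getReactant(j)
            mid = ref.getSpecies()
            mid = mid[2:] if mid.startswith("M_") else mid
            participants.append(
                Participant(
                    metabolite=mid,
                    coefficient=-_frac(ref.getStoichiometry()),
                    compartment=model.metabolites[mid].compartment,
                )
            )
        for j in range(rx.getNumProducts()):
            ref = rx.getProduct(j)
            mid = ref.getSpecies()
            mid = mid[2:] if mid.startswith("M_") else mid
            participants.append(
                Participant(
                    metabolite=mid,
                    coefficient=_frac(ref.getStoichiometry()),
                    compartment=model.metabolites[mid].compartment,
                )
            )
        entry = ReactionEntry(
            id=rid,
            participants=participants,
            direction=Direction.REVERSIBLE if rx.getReversible() else Direction.FORWARD,
            genes=_notes_dict(rx).get("genes"),
            source=model.name,
        )
        model.reactions[rid] = entry
        rplug = rx.getPlugin("fbc")
        if rplug is not None and rplug.isSetLowerFluxBound():
            model.bounds[rid] = (
                params.get(rplug.getLowerFluxBound(), -_DEFAULT_BOUND),
                params.get(rplug.getUpperFluxBound(), _DEFAULT_BOUND),
            )

    mplug = sb.getPlugin("fbc")
    if mplug is not None and mplug.getNumObjectives():
        obj = mplug.getObjective(0)
        if obj.getNumFluxObjectives():
            rsid = obj.getFluxObjective(0).getReaction()
            for i in range(sb.getNumReactions()):
                if sb.getReaction(i).getId() == rsid:
                    model.objective = sb.getReaction(i).getName() or rsid
                    break
    model.validate()
    return model
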