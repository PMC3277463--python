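"""Elemental/charge imbalance detection and minimal proton/water repair.

Most balancing errors in published models are a missed proton (charge off
by the proton count) or a wrong water coefficient (oxygen off).  The repair
therefore searches over integer additions of H⁺ and H₂O only, minimising
|p| + |w| subject to every element and the net charge balancing exactly:

    for every element e:  Δ_e + p·[e=H] + 2w·[e=H] + w·[e=O] = 0
    charge:               Δ_charge + p = 0

With this vocabulary the feasible point is unique — p is pinned by the
charge equation and w by the oxygen equation — so the closed form is used
by default; an integer-LP fallback (scipy HiGHS) sits behind the same
interface for future repair vocabularies.  Any reaction needing more than
H⁺/H₂O edits is reported infeasible and routed to curation: silently
rewriting other coefficients could change the reaction's meaning.

Sign convention: positive deltas add species to the *product* side
(negative deltas to the reactant side); additions merge into existing
h/h2o participants, cancelling and flipping sides as needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Callable, Optional

from .chem_struct import ElementVector
from .model import Model, Participant, ReactionEntry

#: ids conventionally used for the free proton and water species
PROTON_IDS = frozenset({"h", "h+", "proton", "H", "C00080"})
WATER_IDS = frozenset({"h2o", "water", "H2O", "C00001"})

Composition = dict[str, ElementVector]


class UnresolvableReaction(Exception):
    """A participant lacks an elemental composition; repair is undefined."""


@dataclass(frozen=True)
class Imbalance:
    """Per-element and charge surplus of products over reactants."""

    elements: tuple[tuple[str, Fraction], ...]
    charge: Fraction

    @property
    def is_zero(self) -> bool:
        return self.charge == 0 and all(v == 0 for _, v in self.elements)

    def as_dict(self) -> dict[str, Fraction]:
        return dict(self.elements)


def imbalance(r: ReactionEntry, comp: Composition) -> Imbalance:
    """Signed element and charge surplus ``Σ_i s_i · composition(i)``.

    Zero everywhere iff the reaction conserves mass and charge.  Raises
    :class:`UnresolvableReaction` when a participant has no composition.
    """
    deltas: dict[str, Fraction] = {}
    charge = Fraction(0)
    for p in r.participants:
        ev = comp.get(p.metabolite)
        if ev is None:
            raise UnresolvableReaction(
                f"reaction {r.id!r}: no composition for {p.metabolite!r}"
            )
        for sym, n in ev.counts:
            deltas[sym] = deltas.get(sym, Fraction(0)) + p.coefficient * n
        charge += p.coefficient * ev.charge
    items = tuple(sorted((s, v) for s, v in deltas.items() if v != 0))
    return Imbalance(elements=items, charge=charge)


@dataclass
class RepairResult:
    status: str  # already-balanced | repaired | infeasible | unresolvable
    proton_delta: int = 0  # positive: protons added to products
    water_delta: int = 0  # same convention
    repaired: Optional[ReactionEntry] = None
    detail: str = ""


def _solve_closed_form(imb: Imbalance) -> Optional[tuple[int, int]]:
    """The unique (p, w) candidate, or None if no integer repair exists."""
    d = imb.as_dict()
    p = -imb.charge
    w = -d.get("O", Fraction(0))
    if p.denominator != 1 or w.denominator != 1:
        return None
    if d.get("H", Fraction(0)) + p + 2 * w != 0:
        return None
    if any(sym not in ("H", "O") and v != 0 for sym, v in d.items()):
        return None
    return int(p), int(w)


def _solve_milp(imb: Imbalance) -> Optional[tuple[int, int]]:
    """Integer LP over the same {H+, H2O} vocabulary (HiGHS backend).

    min |p|+|w|  s.t. element/charge balance; kept behind the same
    interface so richer vocabularies can be swapped in.
    """
    import numpy as np
    from scipy.optimize import Bounds, LinearConstraint, milp

    d = imb.as_dict()
    if any(sym not in ("H", "O") and v != 0 for sym, v in d.items()):
        return None
    # variables: p+, p-, w+, w-  (split signs to linearise |.|)
    c = np.ones(4)
    # H: (p+ - p-) + 2(w+ - w-) = -dH ; O: (w+ - w-) = -dO ; charge: p+ - p- = -dq
    A = np.array([[1, -1, 2, -2], [0, 0, 1, -1], [1, -1, 0, 0]], dtype=float)
    b = -np.array([float(d.get("H", 0)), float(d.get("O", 0)), float(imb.charge)])
    res = milp(
        c=c,
        constraints=LinearConstraint(A, b, b),
        integrality=np.ones(4),
        bounds=Bounds(0, np.inf),
    )
    if not res.success:
        return None
    x = np.round(res.x).astype(int)
    return int(x[0] - x[1]), int(x[2] - x[3])


def _merge_species(
    r: ReactionEntry, ids: frozenset[str], delta: int, default_id: str
) -> list[Participant]:
    """Add ``delta`` (product-side positive) of a species, merging/cancelling."""
    participants = list(r.participants)
    hit = next((i for i, p in enumerate(participants) if p.metabolite in ids), None)
    if hit is None:
        comp_tags = sorted(r.compartments)
        comp = comp_tags[0] if comp_tags else None
        if len(comp_tags) > 1:
            import warnings

            warnings.warn(
                f"reaction {r.id!r}: spans compartments {comp_tags}; "
                f"adding {default_id} in {comp!r}",
                stacklevel=3,
            )
        participants.append(
            Participant(metabolite=default_id, coefficient=Fraction(delta), compartment=comp)
        )
        return participants
    p = participants[hit]
    new_coeff = p.coefficient + delta
    if new_coeff == 0:
        participants.pop(hit)
    else:
        participants[hit] = replace(p, coefficient=new_coeff)
    return participants


def repair_reaction(
    r: ReactionEntry,
    comp: Composition,
    solver: Callable[[Imbalance], Optional[tuple[int, int]]] = _solve_closed_form,
) -> RepairResult:
    """Repair a reaction by the minimal integer proton/water adjustment.

    Returns status ``already-balanced``, ``repaired`` (with the corrected
    reaction attached), ``infeasible`` (needs edits beyond H⁺/H₂O), or
    ``unresolvable`` (a participant lacks a composition).
    """
    try:
        imb = imbalance(r, comp)
    except UnresolvableReaction as exc:
        return RepairResult(status="unresolvable", detail=str(exc))
    if imb.is_zero:
        return RepairResult(status="already-balanced", repaired=r)
    sol = solver(imb)
    if sol is None:
        return RepairResult(
            status="infeasible",
            detail=f"no H+/H2O repair balances {imb.as_dict()} charge {imb.charge}",
        )
    p_delta, w_delta = sol
    participants = list(r.participants)
    work = replace(r, participants=participants)
    if p_delta:
        work = replace(work, participants=_merge_species(work, PROTON_IDS, p_delta, "h"))
    if w_delta:
        work = replace(work, participants=_merge_species(work, WATER_IDS, w_delta, "h2o"))
    comp2 = dict(comp)
    comp2.setdefault("h", ElementVector.from_dict({"H": 1}, charge=1))
    comp2.setdefault("h2o", ElementVector.from_dict({"H": 2, "O": 1}, charge=0))
    check = imbalance(work, comp2)
    if not check.is_zero:  # defensive: solver and merge must agree
        return RepairResult(status="infeasible", detail=f"residual imbalance {check}")
    return RepairResult(
        status="repaired", proton_delta=p_delta, water_delta=w_delta, repaired=work
    )


repair_reaction_milp = lambda r, comp: repair_reaction(r, comp, solver=_solve_milp)  # noqa: E731


@dataclass
class BalanceReport:
    """Per-reaction audit of a whole model."""

    counts: dict[str, int] = field(default_factory=dict)
    results: dict[str, RepairResult] = field(default_factory=dict)

    @property
    def n_imbalanced(self) -> int:
        return sum(
            n for s, n in self.counts.items() if s not in ("already-balanced",)
        )

    def repairs(self) -> dict[str, RepairResult]:
        return {rid: r for rid, r in self.results.items() if r.status == "repaired"}


def compositions_from_model(m: Model) -> Composition:
    """Element vectors for every fully-specified metabolite of a model.

    Prefers the declared formula+charge; falls back to deriving counts from
    the structure.  Metabolites with neither are simply absent (reactions
    touching them audit as unresolvable).
    """
    from . import chem_struct

    comp: Composition = {}
    for mid, entry in m.metabolites.items():
        if entry.formula:
            try:
                comp[mid] = chem_struct.parse_formula(
                    entry.formula, charge=entry.charge
                )
                continue
            except chem_struct.FormulaError:
                pass
        if entry.structure:
            try:
                if not chem_struct.has_wildcard(entry.structure):
                    comp[mid] = chem_struct.element_vector_from_structure(entry.structure)
            except chem_struct.StructureError:
                pass
    return comp


def audit_model(
    m: Model,
    comp: Optional[Composition] = None,
    skip: frozenset[str] = frozenset(),
) -> BalanceReport:
    """Audit every reaction of a model: balanced / repaired / infeasible /
    unresolvable, with the repaired stoichiometry attached per repair.

    ``skip`` names reactions exempt from balancing — exchange/demand
    pseudo-reactions are one-sided by design and must not be "repaired".
    """
    from .model_io import render_reaction_string

    if comp is None:
        comp = compositions_from_model(m)
    report = BalanceReport()
    for rid, r in m.reactions.items():
        if rid in skip or rid.startswith("EX_"):
            report.counts["skipped"] = report.counts.get("skipped", 0) + 1
            continue
        res = repair_reaction(r, comp)
        if res.status == "repaired":
            res.detail = (
                f"{render_reaction_string(r)}  =>  {render_reaction_string(res.repaired)}"
            )
        report.results[rid] = res
        report.counts[res.status] = report.counts.get(res.status, 0) + 1
    return report


def apply_repairs(m: Model, report: BalanceReport) -> Model:
    """A copy of the model with every repaired reaction substituted."""
    out = Model(
        name=f"{m.name}-rebalanced",
        metabolites=dict(m.metabolites),
        objective=m.objective,
        bounds=dict(m.bounds),
    )
    for rid, r in m.reactions.items():
        res = report.results.get(rid)
        fixed = res.repaired if res and res.status == "repaired" else r
        out.add_reaction(replace(fixed, id=rid), auto_metabolites=True)
    return out
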