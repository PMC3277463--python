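"""Core domain model: metabolites, reactions, and models.

A :class:`Model` is a source-scoped collection of :class:`MetaboliteEntry`
and :class:`ReactionEntry` records, optionally with flux bounds and an
objective reaction for flux balance analysis.  Stoichiometric coefficients
are exact rationals (:class:`fractions.Fraction`): balancing arithmetic and
scale-normalisation must not accumulate float error.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Iterable, Optional


class Direction(enum.Enum):
    """Reaction directionality as declared by the source."""

    REVERSIBLE = "reversible"
    FORWARD = "forward"
    BACKWARD = "backward"


class Resolution(enum.Enum):
    """How completely a metabolite's chemical identity is specified.

    ``FULL``: a wildcard-free structure is attached.  ``PARTIAL``: structure
    or formula present but containing generic parts (R-groups, ``(X)n``
    repeats, compound-class names).  ``NONE``: name only.
    """

    FULL = "full"
    PARTIAL = "partial"
    NONE = "none"


class ModelError(ValueError):
    """Raised when a model or entry violates a structural invariant."""


@dataclass(frozen=True)
class Participant:
    """One metabolite slot in a reaction.

    ``coefficient`` is signed: negative for reactants, positive for
    products.  ``compartment`` is the tag of this participant (may differ
    across participants in transport reactions).
    """

    metabolite: str
    coefficient: Fraction
    compartment: Optional[str] = None

    def __post_init__(self) -> None:
        if not isinstance(self.coefficient, Fraction):
            object.__setattr__(self, "coefficient", Fraction(self.coefficient))
        if self.coefficient == 0:
            raise ModelError(f"zero coefficient for participant {self.metabolite!r}")

    @property
    def side(self) -> int:
        """-1 for reactant, +1 for product."""
        return -1 if self.coefficient < 0 else 1


@dataclass
class ReactionEntry:
    """A source-scoped reaction: signed participants plus annotations."""

    id: str
    participants: list[Participant]
    direction: Direction = Direction.FORWARD
    ec: Optional[str] = None
    source: Optional[str] = None
    genes: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.participants:
            raise ModelError(f"reaction {self.id!r} has no participants")
        for side in (-1, 1):
            seen: set[str] = set()
            for p in self.participants:
                if p.side != side:
                    continue
                if p.metabolite in seen:
                    raise ModelError(
                        f"reaction {self.id!r}: metabolite {p.metabolite!r} "
                        "appears more than once on one side"
                    )
                seen.add(p.metabolite)

    @property
    def reactants(self) -> list[Participant]:
        return [p for p in self.participants if p.coefficient < 0]

    @property
    def products(self) -> list[Participant]:
        return [p for p in self.participants if p.coefficient > 0]

    @property
    def compartments(self) -> frozenset[str]:
        return frozenset(p.compartment for p in self.participants if p.compartment)

    def flipped(self) -> "ReactionEntry":
        """The same reaction written in the opposite direction."""
        flip = {
            Direction.FORWARD: Direction.BACKWARD,
            Direction.BACKWARD: Direction.FORWARD,
            Direction.REVERSIBLE: Direction.REVERSIBLE,
        }
        return replace(
            self,
            participants=[replace(p, coefficient=-p.coefficient) for p in self.participants],
            direction=flip[self.direction],
        )

    def coefficient_of(self, metabolite: str) -> Fraction:
        """Net signed coefficient of ``metabolite`` (0 if absent)."""
        return sum(
            (p.coefficient for p in self.participants if p.metabolite == metabolite),
            Fraction(0),
        )


@dataclass
class MetaboliteEntry:
    """A source-scoped metabolite record.

    At least one of ``names``/``structure`` must be present.  ``structure``
    is SMILES text; ``resolution`` classifies how much identity it pins down
    (see :class:`Resolution`).
    """

    id: str
    names: list[str] = field(default_factory=list)
    formula: Optional[str] = None
    charge: Optional[int] = None
    structure: Optional[str] = None
    compartment: Optional[str] = None
    resolution: Resolution = Resolution.NONE
    source: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.names and self.structure is None:
            raise ModelError(
                f"metabolite {self.id!r}: at least one of names/structure required"
            )
        if self.charge is not None and not isinstance(self.charge, int):
            raise ModelError(f"metabolite {self.id!r}: charge must be an integer")


@dataclass
class Model:
    """A named collection of metabolites and reactions."""

    name: str
    metabolites: dict[str, MetaboliteEntry] = field(default_factory=dict)
    reactions: dict[str, ReactionEntry] = field(default_factory=dict)
    objective: Optional[str] = None
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def validate(self) -> None:
        for r in self.reactions.values():
            for p in r.participants:
                if p.metabolite not in self.metabolites:
                    raise ModelError(
                        f"reaction {r.id!r} references unknown metabolite "
                        f"{p.metabolite!r}"
                    )
        if self.objective is not None and self.objective not in self.reactions:
            raise ModelError(f"objective {self.objective!r} is not a reaction id")

    def add_reaction(self, r: ReactionEntry, auto_metabolites: bool = True) -> None:
        if r.id in self.reactions:
            raise ModelError(f"duplicate reaction id {r.id!r}")
        if auto_metabolites:
            for p in r.participants:
                if p.metabolite not in self.metabolites:
                    self.metabolites[p.metabolite] = MetaboliteEntry(
                        id=p.metabolite,
                        names=[p.metabolite],
                        compartment=p.compartment,
                        source=self.name,
                    )
        self.reactions[r.id] = r

    # -- JSON round trip (the on-disk model format used by the CLI) --------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "metabolites": [
                {
                    "id": m.id,
                    "names": m.names,
                    "formula": m.formula,
                    "charge": m.charge,
                    "structure": m.structure,
                    "compartment": m.compartment,
                    "resolution": m.resolution.value,
                    "source": m.source,
                }
                for m in self.metabolites.values()
            ],
            "reactions": [
                {
                    "id": r.id,
                    "participants": [
                        {
                            "metabolite": p.metabolite,
                            "coefficient": str(p.coefficient),
                            "compartment": p.compartment,
                        }
                        for p in r.participants
                    ],
                    "direction": r.direction.value,
                    "ec": r.ec,
                    "source": r.source,
                    "genes": r.genes,
                }
                for r in self.reactions.values()
            ],
            "objective": self.objective,
            "bounds": {k: list(v) for k, v in self.bounds.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Model":
        m = cls(name=d["name"], objective=d.get("objective"))
        for md in d.get("metabolites", []):
            m.metabolites[md["id"]] = MetaboliteEntry(
                id=md["id"],
                names=list(md.get("names") or []),
                formula=md.get("formula"),
                charge=md.get("charge"),
                structure=md.get("structure"),
                compartment=md.get("compartment"),
                resolution=Resolution(md.get("resolution", "none")),
                source=md.get("source"),
            )
        for rd in d.get("reactions", []):
            m.reactions[rd["id"]] = ReactionEntry(
                id=rd["id"],
                participants=[
                    Participant(
                        metabolite=pd["metabolite"],
                        coefficient=Fraction(pd["coefficient"]),
                        compartment=pd.get("compartment"),
                    )
                    for pd in rd["participants"]
                ],
                direction=Direction(rd.get("direction", "forward")),
                ec=rd.get("ec"),
                source=rd.get("source"),
                genes=rd.get("genes"),
            )
        m.bounds = {k: (float(v[0]), float(v[1])) for k, v in d.get("bounds", {}).items()}
        return m

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "Model":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def models_by_name(models: Iterable[Model]) -> dict[str, Model]:
    return {m.name: m for m in models}
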