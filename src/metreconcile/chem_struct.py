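"""Formula arithmetic, canonical structure keys, and resolution classes.

Metabolite identity across sources is established structurally, at two
levels of detail:

* ``connectivity`` — canonical SMILES with stereo marks stripped; two
  descriptors of the same constitution compare equal regardless of
  chirality annotations.  This is the join key for cross-source matching,
  since many models omit stereo-specificity.
* ``stereo`` — canonical isomeric SMILES; distinguishes L-/D- forms.

Canonicalisation is delegated to RDKit; keys carry a backend+version tag so
corpora built with different canonicalisers refuse silent mixing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from fractions import Fraction
from typing import Optional

import rdkit
from rdkit import Chem, RDLogger

from .model import MetaboliteEntry, Resolution

RDLogger.DisableLog("rdApp.*")

BACKEND_TAG = f"rdkit-{rdkit.__version__}"

_PERIODIC = Chem.GetPeriodicTable()


def _atomic_number(sym: str) -> int:
    try:
        return _PERIODIC.GetAtomicNumber(sym)
    except Exception:
        return 0

#: Compound-class phrases that signal partial identity ("an amino acid"),
#: extensible by callers.
GENERIC_CLASS_NAMES = frozenset(
    {
        "an amino acid",
        "amino acid",
        "electron acceptor",
        "electron donor",
        "a protein",
        "an alcohol",
        "acyl carrier protein",
    }
)


class FormulaError(ValueError):
    """Raised for malformed chemical formulas."""


class StructureError(ValueError):
    """Raised for unparseable structure descriptors."""


@dataclass(frozen=True)
class ElementVector:
    """Element -> count map plus integer charge; the currency of balancing.

    Counts are non-negative rationals (polymer-averaged formulas may be
    fractional); arithmetic on deltas uses plain dict math in `balance`.
    """

    counts: tuple[tuple[str, Fraction], ...]
    charge: int = 0

    @classmethod
    def from_dict(cls, counts: dict[str, Fraction | int], charge: int = 0) -> "ElementVector":
        items = []
        for sym, n in counts.items():
            if _atomic_number(sym) == 0 and sym != "*":
                raise FormulaError(f"unknown element symbol {sym!r}")
            n = Fraction(n)
            if n < 0:
                raise FormulaError(f"negative count for {sym!r}")
            if n > 0:
                items.append((sym, n))
        return cls(counts=tuple(sorted(items)), charge=int(charge))

    def as_dict(self) -> dict[str, Fraction]:
        return dict(self.counts)

    def __getitem__(self, sym: str) -> Fraction:
        return dict(self.counts).get(sym, Fraction(0))

    def scaled(self, k: Fraction) -> dict[str, Fraction]:
        return {s: n * k for s, n in self.counts}

    def hill(self) -> str:
        """Hill-order formula string (C, H, then alphabetical)."""
        d = self.as_dict()
        order = [s for s in ("C", "H") if s in d] + sorted(s for s in d if s not in ("C", "H"))
        parts = []
        for s in order:
            n = d[s]
            parts.append(s if n == 1 else f"{s}{n}")
        return "".join(parts)


_TOKEN = re.compile(r"([A-Z][a-z]?|\(|\)|\d+)")
_CHARGE_TAIL = re.compile(r"^(?P<body>.*?)(?P<sign>[+-])(?P<mag>\d*)$")


def parse_formula(text: str, charge: Optional[int] = None) -> ElementVector:
    """Parse a Hill-style formula such as ``C9H21N2O2`` into an ElementVector.

    A trailing sign term (``HPO4-2``, ``H+``) sets the charge unless an
    explicit ``charge`` argument is given.  Parentheses with integer
    multipliers are supported to depth 2.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula")
    text = text.strip()
    parsed_charge = 0
    m = _CHARGE_TAIL.match(text)
    if m and m.group("body"):
        parsed_charge = int(m.group("mag") or 1) * (1 if m.group("sign") == "+" else -1)
        text = m.group("body")
    if charge is not None:
        parsed_charge = charge

    pos = 0
    tokens = []
    for tok in _TOKEN.finditer(text):
        if tok.start() != pos:
            raise FormulaError(f"unparseable formula fragment {text[pos:tok.start()]!r} in {text!r}")
        tokens.append(tok.group(0))
        pos = tok.end()
    if pos != len(text):
        raise FormulaError(f"unparseable formula fragment {text[pos:]!r} in {text!r}")

    # recursive-descent over a flat token list; stack depth limited to 2
    stack: list[dict[str, Fraction]] = [{}]
    i = 0
    while i < len(tokens):
        t = tokens[i]
        if t == "(":
            if len(stack) > 2:
                raise FormulaError("parentheses nested beyond depth 2")
            stack.append({})
            i += 1
        elif t == ")":
            if len(stack) == 1:
                raise FormulaError("unbalanced ')' in formula")
            group = stack.pop()
            mult = 1
            if i + 1 < len(tokens) and tokens[i + 1].isdigit():
                mult = int(tokens[i + 1])
                i += 1
            for s, n in group.items():
                stack[-1][s] = stack[-1].get(s, Fraction(0)) + n * mult
            i += 1
        elif t.isdigit():
            raise FormulaError(f"stray number {t!r} in formula {text!r}")
        else:
            if _atomic_number(t) == 0:
                raise FormulaError(f"unknown element symbol {t!r} in {text!r}")
            n = 1
            if i + 1 < len(tokens) and tokens[i + 1].isdigit():
                n = int(tokens[i + 1])
                i += 1
            stack[-1][t] = stack[-1].get(t, Fraction(0)) + n
            i += 1
    if len(stack) != 1:
        raise FormulaError(f"unbalanced '(' in formula {text!r}")
    if not stack[0]:
        raise FormulaError(f"formula {text!r} contains no elements")
    return ElementVector.from_dict(stack[0], charge=parsed_charge)


@dataclass(frozen=True)
class StructureKey:
    """Canonical identity string at connectivity or stereo level."""

    level: str  # "connectivity" | "stereo"
    key: str
    wildcard: bool = False
    backend: str = BACKEND_TAG

    def __post_init__(self):
        if self.level not in ("connectivity", "stereo"):
            raise ValueError(f"unknown key level {self.level!r}")


def _mol_from_smiles(descriptor: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(descriptor)
    if mol is None:
        raise StructureError(f"unparseable structure descriptor {descriptor!r}")
    return mol


def has_wildcard(descriptor: str) -> bool:
    """True if the SMILES contains a generic atom (``*``, R-group stand-in)."""
    mol = _mol_from_smiles(descriptor)
    return any(a.GetAtomicNum() == 0 for a in mol.GetAtoms())


def structure_key(descriptor: str, level: str = "connectivity") -> StructureKey:
    """Canonical structure key for a SMILES descriptor.

    ``stereo`` keys preserve chirality and double-bond geometry;
    ``connectivity`` keys strip them, so L- and D- forms coincide.
    """
    mol = _mol_from_smiles(descriptor)
    wildcard = any(a.GetAtomicNum() == 0 for a in mol.GetAtoms())
    if level == "stereo":
        key = Chem.MolToSmiles(mol, isomericSmiles=True, canonical=True)
    elif level == "connectivity":
        key = Chem.MolToSmiles(mol, isomericSmiles=False, canonical=True)
    else:
        raise ValueError(f"unknown key level {level!r}")
    return StructureKey(level=level, key=key, wildcard=wildcard)


def element_vector_from_structure(descriptor: str) -> ElementVector:
    """Element counts (including implicit hydrogens) and formal charge."""
    mol = _mol_from_smiles(descriptor)
    counts: dict[str, Fraction] = {}
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 0:
            continue
        sym = atom.GetSymbol()
        counts[sym] = counts.get(sym, Fraction(0)) + 1
        h = atom.GetTotalNumHs()
        if h:
            counts["H"] = counts.get("H", Fraction(0)) + h
    return ElementVector.from_dict(counts, charge=Chem.GetFormalCharge(mol))


_REPEAT_UNIT = re.compile(r"\(\s*[A-Za-z0-9]+\s*\)\s*n\b", re.IGNORECASE)


def formula_has_wildcard(formula: str) -> bool:
    return "R" in re.findall(r"[A-Z][a-z]?", formula) or "*" in formula or bool(
        _REPEAT_UNIT.search(formula)
    )


def resolution_class(
    m: MetaboliteEntry, generic_names: frozenset[str] = GENERIC_CLASS_NAMES
) -> Resolution:
    """Classify how completely a metabolite's identity is specified.

    ``FULL`` requires a wildcard-free structure that, when a formula is also
    given, agrees with it elementally.  R-groups, ``(X)n`` repeats and
    compound-class names yield ``PARTIAL``; a bare name yields ``NONE``.
    """
    named_generic = any(n.strip().lower() in generic_names for n in m.names)
    if m.structure is not None:
        try:
            wildcard = has_wildcard(m.structure)
        except StructureError:
            return Resolution.NONE
        if wildcard:
            return Resolution.PARTIAL
        if m.formula and not formula_has_wildcard(m.formula):
            try:
                ev = parse_formula(m.formula)
            except FormulaError:
                return Resolution.PARTIAL
            if element_vector_from_structure(m.structure).counts != ev.counts:
                # structure/formula conflict: flagged, not silently resolved
                return Resolution.PARTIAL
        if named_generic:
            return Resolution.PARTIAL
        return Resolution.FULL
    if m.formula and formula_has_wildcard(m.formula):
        return Resolution.PARTIAL
    if named_generic:
        # class name with no structure at all: no identity to pin down
        return Resolution.NONE
    return Resolution.NONE


def classify(m: MetaboliteEntry) -> MetaboliteEntry:
    """Return ``m`` with its resolution field recomputed."""
    m.resolution = resolution_class(m)
    return m
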