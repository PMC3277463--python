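"""Seeded synthetic corpora with injected inconsistencies and ground truth.

Real model collections cannot be shipped or downloaded here, so every
stage of the toolkit is exercised on generated corpora instead.  The
generator builds one "true" network of structurally coherent synthetic
molecules — homologous polyol chains and phosphate/amine-tagged variants
whose formulas are additive in a repeat unit, so group-transfer,
condensation and dissociation reactions are elementally and charge
balanced *by construction* — then derives per-model views with
independently injected errors from the classes seen in published models:

``missing-proton``      a free H⁺ term deleted from a reaction
``wrong-water-coeff``   a water stoichiometric coefficient off by one
``name-variant``        renamed (``-ate``/``-ic acid`` swap or a spelling
                        variant) and the structure reference dropped
``case-variant``        name upper-cased, structure dropped
``stereo-prefix``       ``L-`` prefixed, structure dropped
``id-style-swap``       the source-local abbreviation restyled
``duplicate-entry``     a second entry for the same structure
``r-group-masking``     the structure replaced by an R-group version

Every corruption is recorded in a :class:`GroundTruth` that maps each
(model, metabolite) back to its true connectivity key, so recovery rates
are measurable.  Replaying a seed reproduces the corpus exactly.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Optional

from . import chem_struct
from .model import (
    Direction,
    MetaboliteEntry,
    Model,
    Participant,
    ReactionEntry,
)

ERROR_CLASSES = (
    "missing-proton",
    "wrong-water-coeff",
    "name-variant",
    "case-variant",
    "stereo-prefix",
    "id-style-swap",
    "duplicate-entry",
    "r-group-masking",
)

#: A realistic mix: most balancing errors are missed protons; naming
#: variants are the dominant identity problem.
DEFAULT_ERROR_RATES = {
    "missing-proton": 0.2,
    "wrong-water-coeff": 0.05,
    "name-variant": 0.2,
    "case-variant": 0.1,
    "stereo-prefix": 0.1,
    "id-style-swap": 0.1,
    "duplicate-entry": 0.05,
    "r-group-masking": 0.05,
}

_PREFIX = ["meth", "eth", "prop", "but", "pent", "hex", "hept", "oct", "non", "dec"]


@dataclass
class GroundTruth:
    """Maps corrupted entries back to true identities."""

    true_identity: dict[tuple[str, str], str] = field(default_factory=dict)
    injected_errors: list[tuple[str, str, str]] = field(default_factory=list)  # (model, id, class)
    seed: int = 0

    def errors_of_class(self, cls: str) -> list[tuple[str, str, str]]:
        return [e for e in self.injected_errors if e[2] == cls]


def _polyol(n: int) -> str:
    return "O" + "CC(O)" * n


def _diolate(n: int) -> str:
    return "[O-]" + "CC(O)" * n


def _phospho(n: int) -> str:
    return "[O-]P(=O)(O)O" + "CC(O)" * n


def _amine(n: int) -> str:
    return "N" + "CC(O)" * n


def _make_metabolite(mid: str, name: str, smiles: str) -> MetaboliteEntry:
    ev = chem_struct.element_vector_from_structure(smiles)
    entry = MetaboliteEntry(
        id=mid,
        names=[name],
        formula=ev.hill(),
        charge=ev.charge,
        structure=smiles,
        compartment="c",
    )
    entry.resolution = chem_struct.resolution_class(entry)
    return entry


def _true_network(rng: random.Random, n_reactions: int) -> Model:
    """One balanced network over the synthetic molecule families."""
    nmax = 8
    mets: dict[str, MetaboliteEntry] = {}

    def polyol(n):  # noqa: ANN001
        mid = f"pol{n}"
        if mid not in mets:
            mets[mid] = _make_metabolite(mid, f"{_PREFIX[n - 1]}anediol", _polyol(n))
        return mid

    def diolate(n):
        mid = f"dlt{n}"
        if mid not in mets:
            mets[mid] = _make_metabolite(mid, f"{_PREFIX[n - 1]}anediolate", _diolate(n))
        return mid

    def phospho(n):
        mid = f"php{n}"
        if mid not in mets:
            mets[mid] = _make_metabolite(mid, f"{_PREFIX[n - 1]}ylphosphate", _phospho(n))
        return mid

    def amine(n):
        mid = f"amn{n}"
        if mid not in mets:
            mets[mid] = _make_metabolite(mid, f"{_PREFIX[n - 1]}ylamine", _amine(n))
        return mid

    mets["h"] = _make_metabolite("h", "proton", "[H+]")
    mets["h2o"] = _make_metabolite("h2o", "water", "O")

    def participants(lhs: list[tuple[str, int]], rhs: list[tuple[str, int]]):
        return [
            Participant(metabolite=m, coefficient=Fraction(-c), compartment="c")
            for m, c in lhs
        ] + [
            Participant(metabolite=m, coefficient=Fraction(c), compartment="c")
            for m, c in rhs
        ]

    seen: set[tuple] = set()
    reactions: list[ReactionEntry] = []
    attempts = 0
    while len(reactions) < n_reactions and attempts < n_reactions * 200:
        attempts += 1
        template = rng.choice(["transfer", "condense", "dissociate", "pswap", "aswap"])
        if template == "transfer":
            m_, n_ = rng.randint(1, nmax - 1), rng.randint(2, nmax)
            if m_ == n_ or m_ + 1 == n_ - 1 or m_ == n_ - 1:  # no duplicate slots
                continue
            sig = ("t", m_, n_)
            lhs = [(polyol(m_), 1), (polyol(n_), 1)]
            rhs = [(polyol(m_ + 1), 1), (polyol(n_ - 1), 1)]
        elif template == "condense":
            m_, n_ = rng.randint(1, 4), rng.randint(1, 4)
            sig = ("c", min(m_, n_), max(m_, n_))
            lhs = [(polyol(m_), 1), (polyol(n_), 1)] if m_ != n_ else [(polyol(m_), 2)]
            rhs = [(polyol(m_ + n_), 1), ("h2o", 1)]
        elif template == "dissociate":
            n_ = rng.randint(1, nmax)
            sig = ("d", n_)
            lhs = [(polyol(n_), 1)]
            rhs = [(diolate(n_), 1), ("h", 1)]
        elif template == "pswap":
            m_, n_ = rng.randint(1, nmax), rng.randint(1, nmax)
            if m_ == n_:
                continue
            sig = ("p", m_, n_)
            lhs = [(phospho(m_), 1), (polyol(n_), 1)]
            rhs = [(polyol(m_), 1), (phospho(n_), 1)]
        else:
            m_, n_ = rng.randint(1, nmax), rng.randint(1, nmax)
            if m_ == n_:
                continue
            sig = ("a", m_, n_)
            lhs = [(amine(m_), 1), (polyol(n_), 1)]
            rhs = [(polyol(m_), 1), (amine(n_), 1)]
        if sig in seen:
            continue
        seen.add(sig)
        rid = f"R{len(reactions) + 1:03d}"
        reactions.append(
            ReactionEntry(
                id=rid,
                participants=participants(lhs, rhs),
                direction=rng.choice([Direction.FORWARD, Direction.REVERSIBLE]),
                source="true",
            )
        )
    if len(reactions) < n_reactions:
        raise ValueError(
            f"could only construct {len(reactions)} distinct reactions "
            f"(requested {n_reactions}); template space exhausted"
        )
    model = Model(name="true")
    model.metabolites = mets
    for r in reactions:
        model.add_reaction(r, auto_metabolites=False)
    model.validate()
    return model


def _copy_model(true: Model, name: str) -> Model:
    m = Model(name=name)
    for mid, e in true.metabolites.items():
        m.metabolites[mid] = replace(e, names=list(e.names), source=name)
    for rid, r in true.reactions.items():
        m.reactions[rid] = replace(
            r, participants=list(r.participants), source=name
        )
    return m


def _name_variant(name: str, rng: random.Random) -> str:
    if name.endswith("ate"):
        return name[:-3] + "ic acid"
    if "o" in name[1:]:
        i = name.index("o", 1)  # coumarate/cumarate-style spelling variant
        return name[: i + 1] + "u" + name[i + 1 :]
    i = rng.randrange(1, len(name))
    return name[:i] + name[i] + name[i:]  # doubled letter


def _mask_structure(smiles: str) -> str:
    # replace the leading terminal group with a generic R atom
    for head in ("[O-]P(=O)(O)O", "[O-]", "O", "N"):
        if smiles.startswith(head):
            return "*" + smiles[len(head):]
    return "*" + smiles


def make_synthetic_corpus(
    seed: int,
    n_reactions: int = 50,
    n_models: int = 3,
    error_rates: Optional[dict[str, float]] = None,
) -> tuple[list[Model], GroundTruth]:
    """Build ``n_models`` views of one true network with injected errors.

    ``error_rates`` maps error class to an independent per-opportunity
    probability (defaults to :data:`DEFAULT_ERROR_RATES`).  Deterministic:
    the same seed replays the identical corpus.
    """
    if n_reactions < 5:
        raise ValueError("n_reactions must be >= 5")
    rates = dict(DEFAULT_ERROR_RATES)
    if error_rates is not None:
        rates = {c: 0.0 for c in ERROR_CLASSES} | dict(error_rates)
    unknown = set(rates) - set(ERROR_CLASSES)
    if unknown:
        raise ValueError(f"unknown error classes {sorted(unknown)}")
    if any(not 0 <= v <= 1 for v in rates.values()):
        raise ValueError("error rates must be in [0, 1]")

    rng = random.Random(seed)
    true = _true_network(rng, n_reactions)
    true_keys = {
        mid: chem_struct.structure_key(e.structure, "connectivity").key
        for mid, e in true.metabolites.items()
    }

    truth = GroundTruth(seed=seed)
    models: list[Model] = []
    rename_maps: dict[str, dict[str, str]] = {}
    for i in range(n_models):
        mname = f"model{i + 1}"
        m = _copy_model(true, mname)

        # reaction-level errors
        for rid in sorted(m.reactions):
            r = m.reactions[rid]
            if r.coefficient_of("h") != 0 and rng.random() < rates["missing-proton"]:
                r.participants = [p for p in r.participants if p.metabolite != "h"]
                truth.injected_errors.append((mname, rid, "missing-proton"))
            w = r.coefficient_of("h2o")
            if w != 0 and rng.random() < rates["wrong-water-coeff"]:
                bump = 1 if w > 0 else -1
                r.participants = [
                    replace(p, coefficient=p.coefficient + bump)
                    if p.metabolite == "h2o"
                    else p
                    for p in r.participants
                ]
                truth.injected_errors.append((mname, rid, "wrong-water-coeff"))

        # metabolite-level errors (never on the proton/water bookkeeping ids)
        for mid in sorted(m.metabolites):
            if mid in ("h", "h2o"):
                continue
            entry = m.metabolites[mid]
            cls = None
            roll = rng.random()
            acc = 0.0
            for candidate in ("name-variant", "case-variant", "stereo-prefix",
                              "r-group-masking"):
                acc += rates[candidate]
                if roll < acc:
                    cls = candidate
                    break
            # naming variants also sever the structure reference: the
            # corrupted view knows the metabolite only by its (odd) name
            if cls == "name-variant":
                entry.names = [_name_variant(entry.names[0], rng)]
                entry.structure = None
                entry.resolution = chem_struct.resolution_class(entry)
            elif cls == "case-variant":
                entry.names = [entry.names[0].upper()]
                entry.structure = None
                entry.resolution = chem_struct.resolution_class(entry)
            elif cls == "stereo-prefix":
                entry.names = ["L-" + entry.names[0]]
                entry.structure = None
                entry.resolution = chem_struct.resolution_class(entry)
            elif cls == "r-group-masking":
                entry.structure = _mask_structure(entry.structure)
                entry.formula = None
                entry.resolution = chem_struct.resolution_class(entry)
            if cls:
                truth.injected_errors.append((mname, mid, cls))

            if rng.random() < rates["duplicate-entry"]:
                dup = replace(entry, id=f"{mid}__dup", names=list(entry.names))
                m.metabolites[dup.id] = dup
                truth.true_identity[(mname, dup.id)] = true_keys[mid]
                truth.injected_errors.append((mname, dup.id, "duplicate-entry"))

        # id restyling last so the error list refers to original ids
        renames: dict[str, str] = {}
        for mid in sorted(true.metabolites):
            if mid in ("h", "h2o") or mid not in m.metabolites:
                continue
            if rng.random() < rates["id-style-swap"]:
                renames[mid] = f"MET_{mid.upper()}"
                truth.injected_errors.append((mname, mid, "id-style-swap"))
        if renames:
            truth.injected_errors = [
                (mn, renames.get(eid, eid), cls) if mn == mname else (mn, eid, cls)
                for (mn, eid, cls) in truth.injected_errors
            ]
        for old, new in renames.items():
            entry = m.metabolites.pop(old)
            m.metabolites[new] = replace(entry, id=new)
            for r in m.reactions.values():
                r.participants = [
                    replace(p, metabolite=new) if p.metabolite == old else p
                    for p in r.participants
                ]

        for mid in m.metabolites:
            orig = renames and {v: k for k, v in renames.items()}.get(mid) or (
                mid[:-5] if mid.endswith("__dup") else mid
            )
            if orig in true_keys:
                truth.true_identity[(mname, mid)] = true_keys[orig]
        m.validate()
        rename_maps[mname] = renames
        models.append(m)

    # Every metabolite keeps a structured view in at least one model —
    # emulating that some source always carries an explicit structure link.
    # Without an anchor anywhere, an identity is unrecoverable in principle.
    for orig, true_entry in true.metabolites.items():
        if true_entry.structure is None:
            continue
        views = [
            (m, rename_maps[m.name].get(orig, orig)) for m in models
        ]
        views = [(m, mid) for m, mid in views if mid in m.metabolites]
        from .model import Resolution as _R

        if views and not any(
            m.metabolites[mid].resolution is _R.FULL for m, mid in views
        ):
            anchors = [(m, mid) for m, mid in views if m.metabolites[mid].structure is None]
            if not anchors:
                continue  # only masked views exist; stays unrecoverable by design
            m, mid = anchors[0]
            m.metabolites[mid].structure = true_entry.structure
            m.metabolites[mid].resolution = chem_struct.resolution_class(
                m.metabolites[mid]
            )

    from .model import Resolution

    if not any(
        e.resolution is Resolution.FULL
        for m in models
        for e in m.metabolites.values()
    ):
        raise ValueError("error rates left no resolvable metabolite in any model")
    return models, truth


# ---------------------------------------------------------------------------
# Recovery scoring


def score_recovery(
    corpus: list[Model],
    truth: GroundTruth,
    classes: tuple[str, ...] = ("name-variant", "case-variant", "stereo-prefix"),
) -> dict:
    """Fraction of structure-masking injections whose identity is recovered.

    Runs consolidation-free recovery exactly as a curator workflow would:
    reaction-context resolution first (auto-assignable), then lexical and
    phonetic suggestion for whatever remains, counting a top-ranked
    suggestion whose candidate has the true connectivity key as a
    recovered mapping (suggestions are never applied to the corpus).
    """
    from . import reconcile as rc
    from .lex_phonetic import suggest_matches
    from .model import Resolution

    targets = [
        (mname, mid)
        for (mname, mid, cls) in truth.injected_errors
        if cls in classes
    ]
    log = rc.iterative_resolve(corpus)
    assigned = {
        (e.model, e.metabolite): e.assigned_key for e in log.assignments
    }

    key_of_entry: dict[str, str] = {}
    pool = []
    for m in corpus:
        keys = rc.metabolite_keys(m)
        for mid, entry in m.metabolites.items():
            if entry.resolution is Resolution.FULL and mid in keys:
                pool.append(entry)
                key_of_entry.setdefault(mid, keys[mid].key)

    recovered = 0
    misses = []
    for mname, mid in targets:
        want = truth.true_identity[(mname, mid)]
        got = assigned.get((mname, mid))
        if got == want:
            recovered += 1
            continue
        model = next(m for m in corpus if m.name == mname)
        entry = model.metabolites[mid]
        if entry.resolution is Resolution.FULL:
            # resolved by accepted mapping or already carried the structure
            k = rc.metabolite_keys(model).get(mid)
            if k and k.key == want:
                recovered += 1
                continue
        sugg = suggest_matches(entry, pool, k=5) if entry.resolution is not Resolution.FULL else []
        if sugg and key_of_entry.get(sugg[0].candidate) == want:
            recovered += 1
        else:
            misses.append((mname, mid))
    return {
        "n_targets": len(targets),
        "n_recovered": recovered,
        "rate": (recovered / len(targets)) if targets else 1.0,
        "misses": misses,
        "passes": log.passes,
    }


# ---------------------------------------------------------------------------
# FBA proton-cost fixture


def make_proton_cost_model() -> tuple[Model, dict]:
    """A small model whose published energy reaction omits protons.

    The conversion reaction truly releases two protons per substrate;
    the published version drops them.  Proton efflux is capacity-limited
    (bounded exchange), so once the repair reinstates the protons the
    conversion — and with it the objective — is throttled.  Compositions
    are synthetic, chosen so the proton/water repair is forced to add
    exactly ``2 h`` to the products.
    """
    m = Model(name="proton-cost-published")

    def met(mid, name, formula, charge, comp="c"):
        e = MetaboliteEntry(
            id=mid, names=[name], formula=formula, charge=charge, compartment=comp
        )
        m.metabolites[mid] = e

    met("A_e", "substrate (external)", "C3H8O", 0, comp="e")
    met("A_c", "substrate", "C3H8O", 0)
    met("B", "product", "C3H6O", -2)
    met("h", "proton", "H", 1)

    def rxn(rid, parts, direction=Direction.FORWARD):
        m.reactions[rid] = ReactionEntry(
            id=rid,
            participants=[
                Participant(metabolite=mid, coefficient=Fraction(c), compartment=m.metabolites[mid].compartment)
                for mid, c in parts
            ],
            direction=direction,
            source=m.name,
        )

    rxn("EX_A", [("A_e", -1)], Direction.REVERSIBLE)
    rxn("T_A", [("A_e", -1), ("A_c", 1)])
    rxn("CONV", [("A_c", -1), ("B", 1)])  # published: the 2 h products are missing
    rxn("EX_B", [("B", -1)])
    rxn("EX_h", [("h", -1)])

    m.objective = "EX_B"
    m.bounds = {
        "EX_A": (-10.0, 0.0),  # uptake up to 10
        "EX_h": (0.0, 10.0),  # limited proton secretion capacity
    }
    m.validate()
    comp = {
        "A_e": chem_struct.parse_formula("C3H8O", charge=0),
        "A_c": chem_struct.parse_formula("C3H8O", charge=0),
        "B": chem_struct.parse_formula("C3H6O", charge=-2),
        "h": chem_struct.parse_formula("H", charge=1),
    }
    return m, comp
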