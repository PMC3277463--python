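"""Shared fixtures: reference reaction strings, stand-in structures, helpers."""

from __future__ import annotations

from fractions import Fraction

import pytest

from metreconcile import parse_reaction_string, structure_key
from metreconcile.model import Direction, Participant, ReactionEntry

# The nine published writings of glucose-6-phosphate dehydrogenase across
# model dialects: three compartment-prefix forms, an F420-using variant,
# uppercase-name forms, an NAD-using variant, and two KEGG-identifier forms.
G6PDH_VARIANTS = [
    "[c]: g6p + nadp < = = > 6pgl + h + nadph",
    "[c]: g6p + nadp -- > 6pgl + h + nadph",
    "[c]g6p + nadp < = = > 6pgl + h + nadph",
    "[c]: f420-2 + g6p -- > 6pgl + f420-2h2",
    "G6P + NADP < - > D6PGL + NADPH",
    "G6P + NADP - > D6PGL + NADPH",
    "G6P + NAD - > D6PGL + NADH",
    "C01172 + C00006 = C01236 + C00005 + C00080",
    "C00092 + C00006 < = > C01236 + C00005 + C00080",
]

# Stand-in structures (synthetic; only their identity/distinctness matters).
# g6p/6pgl use the real sugar-phosphate skeletons; cofactors use small
# distinct oxidised/reduced surrogate pairs.
STANDIN_SMILES = {
    "g6p": "OCC1OC(O)C(O)C(O)C1OP(=O)([O-])[O-]",
    "6pgl": "O=C1OC(COP(=O)([O-])[O-])C(O)C(O)C1O",
    "nadp": "CC(=O)NCC(=O)O",
    "nadph": "CC(O)NCC(=O)O",
    "nad": "CCC(=O)N",
    "nadh": "CCC(O)N",
    "f420-2": "OC(=O)CCC(=O)O",
    "f420-2h2": "OC(=O)CCC(O)O",
    "h": "[H+]",
}

SYNONYMS = {
    "G6P": "g6p", "C00092": "g6p", "C01172": "g6p",
    "NADP": "nadp", "C00006": "nadp",
    "D6PGL": "6pgl", "C01236": "6pgl",
    "NADPH": "nadph", "C00005": "nadph",
    "C00080": "h", "NAD": "nad", "NADH": "nadh",
}


@pytest.fixture(scope="session")
def g6pdh_ids():
    """metabolite name -> connectivity StructureKey for the variant table."""
    ids = {name: structure_key(smi) for name, smi in STANDIN_SMILES.items()}
    for alias, canonical in SYNONYMS.items():
        ids[alias] = ids[canonical]
    return ids


@pytest.fixture(scope="session")
def g6pdh_reactions():
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return [
            parse_reaction_string(s, reaction_id=f"row{i + 1}")
            for i, s in enumerate(G6PDH_VARIANTS)
        ]


def make_reaction(rid, lhs, rhs, rev=False, compartment=None):
    """Reaction from (metabolite, coefficient) lists; coefficients positive."""
    parts = [
        Participant(metabolite=m, coefficient=Fraction(-c), compartment=compartment)
        for m, c in lhs
    ] + [
        Participant(metabolite=m, coefficient=Fraction(c), compartment=compartment)
        for m, c in rhs
    ]
    return ReactionEntry(
        id=rid,
        participants=parts,
        direction=Direction.REVERSIBLE if rev else Direction.FORWARD,
    )
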