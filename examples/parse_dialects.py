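"""Parse one reaction written nine ways and collapse the variants.

Published genome-scale models write glucose-6-phosphate dehydrogenase in
at least nine dialects (different arrows, compartment prefixes, naming
conventions, cofactors).  Raw string comparison sees nine distinct
reactions; structure-level reaction keys see three chemistries (NADP-,
NAD- and F420-using), and family mode sees one transformation.
"""

import warnings

from metreconcile import parse_reaction_string, render_reaction_string, structure_key
from metreconcile.reconcile import reaction_key

VARIANTS = [
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

# Stand-in structures: identity matters, chemistry does not.
SMILES = {
    "g6p": "OCC1OC(O)C(O)C(O)C1OP(=O)([O-])[O-]",
    "6pgl": "O=C1OC(COP(=O)([O-])[O-])C(O)C(O)C1O",
    "nadp": "CC(=O)NCC(=O)O", "nadph": "CC(O)NCC(=O)O",
    "nad": "CCC(=O)N", "nadh": "CCC(O)N",
    "f420-2": "OC(=O)CCC(=O)O", "f420-2h2": "OC(=O)CCC(O)O",
    "h": "[H+]",
}
SYNONYMS = {
    "G6P": "g6p", "C00092": "g6p", "C01172": "g6p", "NADP": "nadp",
    "C00006": "nadp", "D6PGL": "6pgl", "C01236": "6pgl", "NADPH": "nadph",
    "C00005": "nadph", "C00080": "h", "NAD": "nad", "NADH": "nadh",
}

ids = {name: structure_key(smi) for name, smi in SMILES.items()}
ids.update({alias: ids[c] for alias, c in SYNONYMS.items()})

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    reactions = [parse_reaction_string(s, reaction_id=f"row{i}") for i, s in enumerate(VARIANTS)]

print("canonical renderings:")
for r in reactions:
    print("  ", render_reaction_string(r))

strict = [reaction_key(r, ids).key for r in reactions]
fam_classes = {
    ids[n].key: "redox-cofactor"
    for n in ("nad", "nadh", "nadp", "nadph", "f420-2", "f420-2h2")
}
family = [
    reaction_key(r, ids, mode="family", cofactor_classes=fam_classes).key
    for r in reactions
]

print(f"\nraw strings:      {len(set(VARIANTS))} distinct")
print(f"strict keys:      {len(set(strict))} distinct  (NADP rows collapse; NAD and F420 stay apart)")
print(f"family keys:      {len(set(family))} distinct  (cofactor choice ignored)")
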