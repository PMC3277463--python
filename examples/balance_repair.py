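"""Repair two published balancing errors by minimal proton/water edits.

Each repair solves for the unique integer (protons, waters) addition that
zeroes every element and the net charge; anything needing other edits is
reported infeasible and left to a curator.
"""

from metreconcile import parse_formula, parse_reaction_string, repair_reaction
from metreconcile.model_io import render_reaction_string

# 1. Dethiobiotin synthase written without its protons.
comp = {
    "DAPA": parse_formula("C9H21N2O2", charge=1),
    "ATP": parse_formula("C10H12N5O13P3", charge=-4),
    "CO2": parse_formula("CO2", charge=0),
    "DTBIOTIN": parse_formula("C10H17N2O3", charge=-1),
    "ADP": parse_formula("C10H12N5O10P2", charge=-3),
    "PI": parse_formula("HPO4", charge=-2),
}
r = parse_reaction_string("DAPA + ATP + CO2 ⇔ DTBIOTIN + ADP + PI", reaction_id="dtbs")
res = repair_reaction(r, comp)
print("dethiobiotin synthase:")
print("  before:", render_reaction_string(r))
print("  after: ", render_reaction_string(res.repaired))
print(f"  proton_delta={res.proton_delta} (3 h restored on the product side)")

# 2. GTP cyclohydrolase I with water erroneously at coefficient -2.
comp2 = {
    "gtp": parse_formula("C10H12N5O14P3", charge=-4),
    "h2o": parse_formula("H2O"),
    "ahdt": parse_formula("C9H12N5O13P3", charge=-4),
    "for": parse_formula("CHO2", charge=-1),
}
r2 = parse_reaction_string("gtp + 2 h2o → ahdt + for", reaction_id="gtpch")
res2 = repair_reaction(r2, comp2)
print("\nGTP cyclohydrolase I:")
print("  before:", render_reaction_string(r2))
print("  after: ", render_reaction_string(res2.repaired))
print(f"  net water coefficient {res2.repaired.coefficient_of('h2o')} "
      f"(was -2), plus {res2.proton_delta} proton to close the charge")

# 3. A reaction no proton/water edit can fix.
r3 = parse_reaction_string("co2 -> ch4", reaction_id="bad")
res3 = repair_reaction(r3, {"co2": parse_formula("CO2"), "ch4": parse_formula("CH4")})
print(f"\nco2 -> ch4: status {res3.status} (needs more than H+/H2O; goes to curation)")
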