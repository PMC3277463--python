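# metreconcile

Reconciliation, balancing and comparison of genome-scale metabolic models.

Metabolic reconstructions and reaction databases describe the same
chemistry in incompatible ways: the same metabolite carries different
names across sources (and sometimes within one), reactions are written in
different arrow/compartment dialects, many entries are elementally or
charge unbalanced, and some metabolites are only partially specified
(R-groups, "an amino acid").  Left unaddressed, this makes model merging,
cross-model comparison and pathway prospecting unreliable: naive string
comparison recognises almost no genuinely shared reactions between
published models.

`metreconcile` is a toolkit for putting heterogeneous model collections on
a standardized footing:

* **model_io** — parse reaction strings in the dialects used by published
  models (`< = = >`, `-- >`, `->`, `=`, `⇔`, `→`; `[c]:`/`[c]` compartment
  prefixes), load tabular models, and round-trip SBML L3V1 + fbc.
* **chem_struct** — exact formula arithmetic (`ElementVector`), canonical
  structure keys at *connectivity* (stereo-stripped) and *stereo* levels
  via RDKit, and resolution classes (full / partial / none).
* **lex_phonetic** — name normalisation (stereo-token and locant
  suppression, `-ic acid` ≡ `-ate`) and a metaphone-class phonetic encoder
  for curator-facing match suggestions.  Suggestions are never
  auto-applied.
* **balance** — imbalance detection and minimal proton/water repair.
* **reconcile** — duplicate consolidation by structure key, canonical
  direction-invariant reaction keys (strict and cofactor-family modes),
  iterative reaction-context resolution of structure-less metabolites, and
  Venn-style source comparison.
* **prospect** — bipartite metabolite–reaction graphs with currency
  metabolites excluded, and exhaustive enumeration of all minimal (or
  near-minimal) source→target pathways.
* **fba** — flux balance analysis (`max c·v` s.t. `S·v = 0`,
  `lb ≤ v ≤ ub`) to audit models before vs. after repair.
* **fixtures** — a seeded generator of synthetic model corpora with
  injected inconsistencies and ground truth, so every stage is testable
  without any database downloads.

## The balancing repair

For a reaction with signed stoichiometry s_i and per-metabolite element
vectors, the imbalance is Δ_e = Σ_i s_i·n_{i,e} per element e and
Δ_q = Σ_i s_i·q_i for charge.  The repair searches integers p (protons)
and w (waters), added to the product side when positive, minimising
|p| + |w| subject to

    Δ_H + p + 2w = 0        Δ_O + w = 0
    Δ_q + p     = 0         Δ_e     = 0   for every other element e

With this vocabulary the feasible point is unique (p is pinned by charge,
w by oxygen), so a closed form is used, with an integer-LP fallback
(HiGHS) behind the same interface.  Reactions needing any other edit are
reported *infeasible* and routed to curation rather than silently
rewritten; reactions containing a metabolite without full composition are
*unresolvable*.

## Worked example

```bash
python examples/balance_repair.py
```

prints

```
dethiobiotin synthase:
  before: DAPA + ATP + CO2 <=> DTBIOTIN + ADP + PI
  after:  DAPA + ATP + CO2 <=> DTBIOTIN + ADP + PI + 3 h
  proton_delta=3 (3 h restored on the product side)

GTP cyclohydrolase I:
  before: gtp + 2 h2o -> ahdt + for
  after:  gtp + h2o -> ahdt + for + h
  net water coefficient -1 (was -2), plus 1 proton to close the charge

co2 -> ch4: status infeasible (needs more than H+/H2O; goes to curation)
```

The first reaction, written without protons, is three hydrogens and three
charges short on the product side; the unique minimal repair restores the
`3 h` term.  The second had water at coefficient −2 instead of −1: the
repair cancels one water and adds a proton to close the charge balance.
The third cannot be fixed by protons and water at all, so it is flagged
for a curator instead of being altered.

The other scripts in `examples/` each demonstrate one capability — dialect
parsing and key collapse, corpus reconciliation with recovery scoring,
model comparison, pathway enumeration, and the FBA audit — and print a
line explaining what their numbers mean.  A thin CLI (`metreconcile
ingest|balance|suggest|compare|prospect|fba|fixtures|export-sbml`) wraps
the same functions for shell use.

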