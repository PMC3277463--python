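# Methods

## Scope and model of the problem

The toolkit standardizes collections of stoichiometric metabolic models.
Each source model is a set of metabolite entries (names, optional formula,
integer charge, optional SMILES structure, compartment) and reaction
entries (signed rational stoichiometry, direction, compartments, EC/gene
annotations).  Standardization has four parts: establishing metabolite
identity across sources, canonicalising reactions so genuinely shared
chemistry compares equal, repairing elemental/charge imbalances, and
auditing the functional consequences with flux balance analysis.
Protonation states and charges are taken as inputs (or from a pluggable
backend); no pKa/microspecies computation is performed, and fractional
input charges are rejected rather than rounded.

## Structure keys

Metabolite identity is structural.  Two key levels are computed with
RDKit canonical SMILES:

* **connectivity** — isomeric marks stripped; L- and D- forms coincide.
  This is the join key everywhere, because many models omit
  stereo-specificity.
* **stereo** — chirality and double-bond geometry preserved; used to flag
  stereo-conflicting subgroups inside a connectivity group, which are
  reported but never merged.

Keys are idempotent fixed points of canonicalisation and carry a
backend+version tag (`rdkit-<version>`) so corpora canonicalised by
different toolkits cannot be mixed silently.  A structure containing a
wildcard atom (`*`) yields a valid key flagged `wildcard`; such entries
classify as *partial* and are excluded from comparisons and from
automatic resolution — an R-group structure denotes a class of molecules,
not an unknown single molecule.  When both a formula and a structure are
given and disagree elementally, the entry is flagged (classified partial)
rather than adjudicated: the sources themselves do not say which wins.

## Reaction keys

A reaction's key is built from the multiset of (connectivity key,
|coefficient|, side) of its participants with: direction suppressed (the
two sides are ordered canonically, so a reaction equals its flipped
copy), compartments simplified to internal vs. transport, coefficients
normalised up to a global scale (a doubled stoichiometry compares equal),
and **free protons excluded** — proton conventions vary by source and
protonation differences should not hide shared chemistry.  Water is
retained: a water-coefficient difference changes the chemistry (see the
cyclohydrolase repair) and must stay visible.

`strict` mode keeps cofactors distinct.  `family` mode additionally maps
configured cofactor structure keys to a class token before keying; the
default configuration maps NAD(H), NADP(H) and F420(H2) to one shared
token, so alternate-cofactor variants of one transformation land on the
same family key.  Finer families (one token per redox pair) are a
configuration away.

## Balancing repair

Imbalance is the signed sum Δ of element vectors and charges over
participants.  The repair vocabulary is fixed to {H⁺, H₂O} with integer
deltas (positive = added to products), minimising |p|+|w| subject to
exact element and charge balance.  Because the charge equation pins p and
the oxygen equation pins w, the feasible point is unique; the closed-form
candidate is checked against the hydrogen equation and all other
elements.  An integer LP over the same vocabulary (scipy/HiGHS, signs
split to linearise the objective) sits behind the same interface for
future vocabularies (e.g. adding e⁻) and is asserted equivalent in tests.
Repairs merge into existing h/h2o participants, cancelling coefficients
and flipping sides as needed; in multi-compartment reactions the species
is added to the lexicographically first compartment with a warning.
Anything else — wrong non-water coefficients, missing carbon — is
*infeasible* by design and routed to curation, because silently editing
other coefficients can change what the reaction means.  Exchange
pseudo-reactions (`EX_` prefix or an explicit skip set) are exempt from
auditing: they are one-sided by construction.

## Name normalisation and phonetic matching

For metabolites with no structure, names are the only evidence.
Normalisation case-folds, spells out Greek letters, splits on punctuation,
rewrites `<stem>ic acid` → `<stem>ate` before stopword removal (so "acid"
never survives), and suppresses stereo tokens (cis/trans/L/D/alpha/...),
bare numerals and locant groups, and configured non-chemistry stopwords.
Comparison is token-multiset based, with a hyphenation-fusion fallback
(sorted tokens concatenated) because sources disagree on whether
substituent names are fused or hyphen-separated.

The phonetic encoder is a compact metaphone-class code written for this
package: Latinate digraph collapses (PH→F, soft C/G), consonant-class
mapping, vowel suppression after the initial position, run collapsing,
digits preserved (they distinguish e.g. F420 species).  Suggestions score
1 for exact normalised equality, otherwise the fraction of tokens with
matching phonetic codes; ties break by evidence priority then candidate
id, so rankings are deterministic.  **Suggestions are never applied to a
model**: reconciliation only changes a model through reaction-context
assignment or an explicit accepted-mapping input (the curator stand-in).
The suggestion count `k=5` and score floor `0.5` are configuration
defaults, not calibrated quantities.

## Iterative context resolution

A reaction with exactly one structure-less participant is matched against
an index of fully resolved reactions sharing the remaining participant
multiset — direction suppressed, coefficients compared up to global
scale, free protons ignored.  A unique candidate structure is assigned;
multiple candidates yield curator suggestions; a later pass contradicting
an earlier assignment is logged as a conflict and not applied.  Passes
repeat to a fixed point, since each assignment can unlock further
single-unknown reactions; the resolved set grows monotonically, bounding
passes by the number of unresolved entries.

## Pathway prospecting

The corpus becomes a directed bipartite graph with substrate→reaction and
reaction→product arcs; reversible reactions contribute a mirrored
orientation node.  Currency metabolites (default: h, h+, h2o, atp, adp,
pi, ppi, nad(h), nadp(h), co2; overridable) carry no arcs — otherwise
nearly everything is two steps from everything via ATP.  Enumeration
returns **all** simple paths of reaction length ≤ L*+slack (L* the BFS
minimum), forbidding repeated reactions in either orientation and
revisited metabolites, pruned by distance-to-target, capped with an
explicit truncation flag, and ordered deterministically (length, then
reaction-id sequence).  Paths are connective only — no stoichiometric
feasibility is enforced; that trade is what makes exhaustive enumeration
scale, and it means returned routes are candidates for curation, not
guaranteed operable pathways.

## Flux balance analysis

`max c·v` subject to `S·v = 0` and box bounds, solved with scipy's HiGHS
interface; default bounds (−1000, 1000) for reversible and (0, 1000) for
irreversible reactions; mass-balance tolerance 1e−6 at reported optima.
Stoichiometry stays rational in the model; floats appear only in the
solver.  The objective value is deterministic (flux vectors may be
degenerate).  `standardization_delta` reports the relative objective
change (after − before)/before between a published model and its repaired
version, flagging a zero baseline as undefined.  The test suite
cross-checks the solver against cobrapy on an exported SBML of the same
model.

## Synthetic corpus generator

Real model collections are not shipped; the generator builds corpora in
which every result is checkable against ground truth.  The "true" network
is drawn from homologous families of synthetic molecules (polyol chains
`O(CC(O))n` plus phosphate-, amine- and deprotonated-tagged variants)
whose element vectors are additive in the repeat unit, so the five
reaction templates — unit transfer, condensation (releases water),
dissociation (releases a proton), phosphate swap, amine swap — are
elementally and charge balanced *by construction*.  Formulas and charges
are derived from the SMILES, never stated independently.

Per-model views then receive independent error injections: missing
protons, off-by-one water coefficients, name variants (`-ate`/`-ic acid`
swaps and coumarate/cumarate-style spelling changes), case variants,
stereo prefixes, id restyling, duplicate entries, and R-group masking.
Naming-class corruptions also sever the entry's structure link — the
corrupted view knows the metabolite only by its odd name, which is what
makes recovery non-trivial.  One generator constraint is deliberate:
every metabolite keeps a fully structured view in at least one model,
emulating the real situation in which some source always carries an
explicit structure-database link.  Without any anchor an identity is
unrecoverable in principle, and recovery rates would measure coin flips
of the injection pattern rather than the reconciliation machinery.
Replaying a seed reproduces the corpus exactly.

Recovery scoring counts an injected naming corruption as recovered if
reaction-context resolution assigns the true connectivity key, or the
top-ranked lexical/phonetic suggestion points at an entry carrying the
true key (a curator stand-in accepting rank-1 suggestions); suggestions
still never modify the corpus.  What passing recovery tests show is that
the structural/contextual/lexical machinery closes the loop on these
error classes at these rates *on this generator*; real corpora add
error modes the generator does not emulate (shared names for different
molecules at scale, genuinely absent reactions, inconsistent compartment
semantics), which is why suggestion channels remain curator-facing.

The FBA audit fixture is a five-reaction model whose conversion step
truly releases two protons that the "published" version omits;
compositions are chosen so the repair is forced to add exactly `2 h`, and
proton efflux is capacity-limited (bounded exchange), so the repaired
model's optimum drops from 10 to 5 (delta −50%).  The direction of the
effect — repairs tighten — is the point; its magnitude is a property of
the fixture's bounds.

## Problem sizes and numerical choices

Default experiment sizes are chosen to exercise every code path at desk
scale: corpora of 50 reactions × 3 models for recovery baselines, 200
random reactions against the brute-force repair oracle over
(p, w) ∈ [−10, 10]², 100 random graphs of ≤ 12 reactions against
brute-force path enumeration.  All randomised tests are seeded;
hypothesis-based properties are derandomised.  Balancing and
scale-normalisation arithmetic is exact (`fractions.Fraction`); SBML
round trips recover rational coefficients via denominator-limited
conversion (up to 10⁶).

## Known limitations

* No live database retrieval; inputs are local tables, SBML, or the
  generator.
* Protonation/pKa computation is out of scope; charges are inputs.
* Conserved-moiety stoichiometric-consistency analysis is not performed —
  the balance audit is elemental/charge only.
* Gene–protein–reaction strings are carried through verbatim, not
  reconciled.
* Compartment simplification is two-valued (internal vs. transport);
  original tags are retained on participants but organelle-specific logic
  is absent.
* Pathway enumeration ignores stoichiometric feasibility, yield and
  thermodynamics by design.
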