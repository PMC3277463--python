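"""Reconcile a synthetic three-model corpus with injected naming errors.

The generator corrupts half of the metabolite names (spelling variants,
``-ate``/``-ic acid`` swaps) and severs those entries' structure links.
Consolidation groups the structured entries by connectivity key; iterative
reaction-context matching plus lexical/phonetic suggestion then recovers
the corrupted identities, scored against the generator's ground truth.
"""

from metreconcile import (
    consolidate_metabolites,
    iterative_resolve,
    make_synthetic_corpus,
    score_recovery,
)

models, truth = make_synthetic_corpus(seed=1, n_reactions=50, n_models=3,
                                      error_rates={"name-variant": 0.5})
print("corpus:", ", ".join(f"{m.name} ({len(m.reactions)} rxns)" for m in models))
print("injected name variants:", len(truth.errors_of_class("name-variant")))

cmap = consolidate_metabolites(models)
multi = sum(1 for g in cmap.groups.values() if len(g) > 1)
print(f"consolidation: {len(cmap.groups)} identity groups, {multi} spanning several models")

log = iterative_resolve(models)
print(f"context resolution: {len(log.assignments)} assignments over {log.passes} passes")
for e in log.assignments[:3]:
    print(f"   pass {e.pass_number}: {e.model}:{e.metabolite} <- {e.via_reaction}")

res = score_recovery(models, truth)
print(f"recovery: {res['n_recovered']}/{res['n_targets']} injected mappings "
      f"({100 * res['rate']:.1f}%) — context assignments plus top-ranked "
      "curator suggestions matching the true structure key")
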