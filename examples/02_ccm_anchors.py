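"""Recompute the desk-checkable anchors on the central-carbon fixture.

Loads the bundled 51-reaction universe and its ten single-carbon-source
environments, then computes the always-essential reactions and the minimal
viable metabolism sizes by mixed-integer programming. Runs in under a
minute on one CPU.
"""

from fluxspace import (
    Genotype,
    essential_reactions,
    load_ccm,
    minimal_viable_size,
    phenotype,
    solve_fba,
)

u, panel = load_ccm()
print(f"universe: {u.N} internal reactions, {len(panel)} environments, "
      f"hash {u.model_hash()}")

full = Genotype.full(u.N)
print("\nfull-universe phenotype:", phenotype(u, full, panel).bits())

ess = essential_reactions(u, panel)
print(f"\nalways-essential reactions ({len(ess)}):",
      sorted(u.internal_reaction_ids[i] for i in ess))

for label, sources in [("glucose", ["glucose"]),
                       ("acetate", ["acetate"]),
                       ("all ten", list(panel.names))]:
    envs = list(panel.subset(sources))
    n_min, witness = minimal_viable_size(u, envs)
    ok = all(solve_fba(u, witness, e).viable for e in envs)
    print(f"n_min({label}) = {n_min}  witness verified: {ok}")
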