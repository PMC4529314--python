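"""Walk through the core concepts on a four-reaction toy universe.

The universe has internal reactions r1: A->B, r2: B->P, r3: A->C,
r4: C->B, with P the sole biomass precursor and two environments supplying
A or C. Small enough to enumerate by hand, so every printed number can be
checked on paper.
"""

from fluxspace import (
    Criterion,
    Genotype,
    GenotypeNetwork,
    disconnected_reactions,
    enumerate_bruteforce,
    novel_phenotypes,
    phenotype,
    size_histogram,
    solve_fba,
    toy_a,
)

u, panel = toy_a()
eA = panel[panel.index_of("A-inlet")]

print("== viability of single genotypes ==")
for bits in ([0, 1], [0], [1, 2, 3]):
    g = Genotype.from_bits(bits, u.N)
    names = [u.internal_reaction_ids[i] for i in bits]
    r = solve_fba(u, g, eA)
    print(f"{{{', '.join(names)}}} on A: biomass={r.biomass_rate:.2f} viable={r.viable}")

print("\n== phenotype vectors (A, C) ==")
for bits in ([0, 1], [0, 1, 3], [0, 1, 2, 3]):
    g = Genotype.from_bits(bits, u.N)
    print(f"n={g.size} mask={g.to_hex()}: {phenotype(u, g, panel).bits()}")

print("\n== exhaustive enumeration: viable on at least A ==")
gs = enumerate_bruteforce(u, panel, Criterion.at_least("A-inlet"))
hist = size_histogram(gs)
print(f"members={len(gs)} counts by size={hist.counts} n_min={hist.n_min}")

print("\n== the size-3 genotype network ==")
net = GenotypeNetwork.from_genotype_set(gs, 3)
print(f"members={len(net)} edges={net.edge_count()} "
      f"components={len(net.connected_components())} diameter={net.diameter()}")

print("\n== disconnected reactions ==")
for bits in ([0, 1, 2], [0, 1, 3]):
    g = Genotype.from_bits(bits, u.N)
    dis = {u.internal_reaction_ids[i] for i in disconnected_reactions(u, g, eA)}
    print(f"{[u.internal_reaction_ids[i] for i in bits]} on A: disconnected={dis or '{}'}")

print("\n== neighborhood innovation ==")
s = novel_phenotypes(u, Genotype.from_bits([0, 1], u.N), panel)
print(f"focal {s.genotype.to_hex()} phenotype={s.focal_phenotype.bits()} "
      f"novel phenotypes={sorted(p.bits() for p in s.novel_phenotypes)} "
      f"({s.n_neighbors} neighbors)")
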