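import itertools

import numpy as np
import pytest

from fluxspace import (
    ComponentSummary,
    Criterion,
    Genotype,
    GenotypeNetwork,
    blocked_at_max_distance,
    cofactor_pair_filter,
    connectivity_inheritance,
    diameter_estimate,
    enumerate_bruteforce,
    genotype_distance,
    max_distance_pairs,
    max_swap_distance,
    min_inter_network_distance,
    size_histogram,
    swap_neighbors,
)


def test_swap_neighbors_space():
    g = Genotype.from_bits([0, 1], 4)
    nbs = {n.bits() for n in swap_neighbors(g)}
    assert nbs == {(0, 2), (0, 3), (1, 2), (1, 3)}
    assert all(n.bit_count() == 2 for n in (Genotype.from_bits(b, 4).mask for b in nbs))


def test_max_swap_distance():
    assert max_swap_distance(25, 51) == 25
    assert max_swap_distance(40, 51) == 11
    assert max_swap_distance(3, 8) == 3


def _all_pairs_adjacency(masks):
    adj = {m: set() for m in masks}
    for a, b in itertools.combinations(masks, 2):
        if (a ^ b).bit_count() == 2:
            adj[a].add(b)
            adj[b].add(a)
    return adj


def test_indexed_neighbors_equal_all_pairs_scan(layered_viable):
    gs = layered_viable
    for n, members in gs.by_size().items():
        masks = [g.mask for g in members]
        net = GenotypeNetwork.from_masks(masks, n, gs.n_bits)
        ref = _all_pairs_adjacency(masks)
        for m in masks:
            assert set(net.neighbors(m)) == ref[m]


def test_toy_size3_network(toy):
    u, panel = toy
    gs = enumerate_bruteforce(u, panel, Criterion.at_least("A-inlet"))
    net = GenotypeNetwork.from_genotype_set(gs, 3)
    g123 = Genotype.from_bits([0, 1, 2], 4).mask
    nbs = net.neighbors(g123)
    assert {Genotype(m, 4).bits() for m in nbs} == {(0, 1, 3), (1, 2, 3)}
    cs = ComponentSummary.from_network(net)
    assert cs.n_components == 1 and cs.r_giant == 1.0
    assert net.diameter() == 1  # triangle
    assert net.edge_count() == 3


def test_size_mismatch_rejected():
    with pytest.raises(ValueError):
        GenotypeNetwork.from_masks([0b11, 0b111], 2, 4)


def _adjacency_matrix_components(masks):
    """Reference implementation: BFS over a precomputed adjacency mapping."""
    adj = _all_pairs_adjacency(masks)
    seen, comps = set(), []
    for start in sorted(masks):
        if start in seen:
            continue
        comp, frontier = {start}, [start]
        while frontier:
            m = frontier.pop()
            for nb in adj[m]:
                if nb not in comp:
                    comp.add(nb)
                    frontier.append(nb)
        seen |= comp
        comps.append(comp)
    return sorted(sorted(c) for c in comps)


def test_streaming_bfs_equals_adjacency_bfs(layered_viable):
    gs = layered_viable
    for n in size_histogram(gs).counts:
        net = GenotypeNetwork.from_genotype_set(gs, n)
        ours = sorted(sorted(c) for c in net.connected_components())
        assert ours == _adjacency_matrix_components(list(net.masks))


def test_two_distant_members():
    net = GenotypeNetwork.from_masks([0b0011, 0b1100], 2, 4)
    cs = ComponentSummary.from_network(net)
    assert cs.n_components == 2 and cs.r_giant == 0.5


def test_diameter_bound_and_sampled(layered_viable):
    gs = layered_viable
    rng = np.random.default_rng(0)
    for n in size_histogram(gs).counts:
        net = GenotypeNetwork.from_genotype_set(gs, n)
        d = net.diameter()
        assert d <= max_swap_distance(n, gs.n_bits)
        assert net.sampled_diameter(50, rng) <= d
        de = diameter_estimate(net)
        assert de.mode == "exact" and de.value == d
        small = diameter_estimate(net, sample_cap=1 if len(net) > 1 else 0)
        assert small.value <= d


def test_path_between_members(toy):
    u, panel = toy
    gs = enumerate_bruteforce(u, panel, Criterion.at_least("A-inlet"))
    net = GenotypeNetwork.from_genotype_set(gs, 3)
    masks = sorted(net.masks)
    p = net.path(masks[0], masks[-1])
    assert p[0] == masks[0] and p[-1] == masks[-1]
    for a, b in zip(p, p[1:]):
        assert (a ^ b).bit_count() == 2


def test_connectivity_inheritance(layered_viable):
    gs = layered_viable
    sizes = sorted(size_histogram(gs).counts)
    for n, n1 in zip(sizes, sizes[1:]):
        net_n = GenotypeNetwork.from_genotype_set(gs, n)
        net_n1 = GenotypeNetwork.from_genotype_set(gs, n1)
        connected, mode = connectivity_inheritance(net_n, net_n1)
        # inference must never contradict direct BFS
        assert connected == net_n1.is_connected()
    with pytest.raises(ValueError):
        connectivity_inheritance(net_n, net_n)


def test_connectivity_inheritance_refuses_without_superset():
    # size-3 member 0b10101 contains no size-2 member: fall back to BFS
    net2 = GenotypeNetwork.from_masks([0b00011], 2, 5)
    net3 = GenotypeNetwork.from_masks([0b10101], 3, 5)
    connected, mode = connectivity_inheritance(net2, net3)
    assert mode == "bfs" and connected


def test_max_distance_pairs(layered_viable):
    gs = layered_viable
    n = sorted(size_histogram(gs).counts)[1]
    net = GenotypeNetwork.from_genotype_set(gs, n)
    d, pairs = max_distance_pairs(net)
    assert d == net.diameter()
    comp = net.connected_components()[0]
    nb = gs.n_bits
    for a, b in pairs:
        assert genotype_distance(Genotype(a, nb), Genotype(b, nb)) == d
    # completeness: every giant-component pair at distance d is reported
    expected = sum(
        1
        for x, y in itertools.combinations(sorted(comp), 2)
        if (x ^ y).bit_count() // 2 == d
    )
    assert len(pairs) == expected


def test_cofactor_pair_filter(toy):
    import dataclasses

    u, _ = toy
    # declare r1/r3 as an isoform pair on a copy of the universe
    u2 = dataclasses.replace(u, cofactor_pairs=(("r1", "r3"),))
    a = Genotype.from_bits([0, 1], 4).mask  # uses r1, not r3
    b = Genotype.from_bits([1, 2], 4).mask  # uses r3, not r1
    c = Genotype.from_bits([1, 3], 4).mask  # neither isoform
    pct, kept = cofactor_pair_filter([(a, b), (a, c)], u2)
    assert pct == 50.0 and kept == [(a, c)]
    pct_all, _ = cofactor_pair_filter([(a, c)], u2)
    assert pct_all == 100.0
    pct_none, kept_none = cofactor_pair_filter([(a, b)], u2)
    assert pct_none == 0.0 and kept_none == []


def test_blocked_at_max_distance(toy):
    u, panel = toy
    eA = panel[panel.index_of("A-inlet")]
    g123 = Genotype.from_bits([0, 1, 2], 4).mask  # r3 blocked
    g124 = Genotype.from_bits([0, 1, 3], 4).mask  # r4 blocked
    g234 = Genotype.from_bits([1, 2, 3], 4).mask  # none blocked
    assert blocked_at_max_distance([(g123, g124)], u, eA) == 2
    assert blocked_at_max_distance([(g123, g124), (g234, g234)], u, eA) == 0
    with pytest.raises(ValueError):
        blocked_at_max_distance([], u, eA)


def test_min_inter_network_distance():
    a = [Genotype.from_bits([0, 1, 2], 6).mask]
    b = [Genotype.from_bits([0, 1, 3], 6).mask]
    d, (wa, wb) = min_inter_network_distance(a, b, 6)
    assert d == 1 and (wa, wb) == (a[0], b[0])
    d0, _ = min_inter_network_distance(a, a, 6)
    assert d0 == 0
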