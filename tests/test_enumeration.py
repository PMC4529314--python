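import math

import pytest

from fluxspace import (
    Criterion,
    Genotype,
    GenotypeSet,
    SyntheticUniverseSpec,
    binomial_prediction,
    disconnected_fraction,
    enumerate_bruteforce,
    enumerate_divide_merge,
    make_layered_universe,
    phenotype_table,
    size_histogram,
    solve_fba,
    v_at_least,
    v_exclusively,
)


def test_criterion_parse_and_str():
    c = Criterion.parse("at-least:glucose+lactate")
    assert c.kind == "at_least" and c.sources == ("glucose", "lactate")
    assert Criterion.parse(str(c)) == c
    assert Criterion.parse("excl:acetate").kind == "exclusively"
    with pytest.raises(ValueError):
        Criterion.parse("sometimes:glucose")
    with pytest.raises(ValueError):
        Criterion("maybe", ())


def test_bruteforce_toy_members(toy):
    u, panel = toy
    gs = enumerate_bruteforce(u, panel, Criterion.at_least("A-inlet"))
    expected = {
        frozenset({0, 1}),
        frozenset({0, 1, 2}),
        frozenset({0, 1, 3}),
        frozenset({1, 2, 3}),
        frozenset({0, 1, 2, 3}),
    }
    assert {frozenset(g.bits()) for g in gs.members} == expected
    hist = size_histogram(gs)
    assert hist.counts == {2: 1, 3: 3, 4: 1}
    assert hist.n_min == 2
    assert hist.total == len(gs) == sum(hist.counts.values())
    assert hist.fraction(3) == pytest.approx(3 / 4)


def test_bruteforce_guard(ccm):
    u, panel = ccm
    with pytest.raises(ValueError, match="refused"):
        enumerate_bruteforce(u, panel, Criterion.at_least("glucose"))


def test_exclusive_empty_is_inviable_complement(toy):
    u, panel = toy
    inviable = enumerate_bruteforce(u, panel, Criterion.exclusively())
    any_viable_a = enumerate_bruteforce(u, panel, Criterion.at_least("A-inlet"))
    any_viable_c = enumerate_bruteforce(u, panel, Criterion.at_least("C-inlet"))
    assert len(inviable) == 16 - len(any_viable_a.masks() | any_viable_c.masks())


def test_divide_merge_equals_bruteforce_toy_all_criteria(toy):
    u, panel = toy
    criteria = [
        Criterion.at_least("A-inlet"),
        Criterion.at_least("C-inlet"),
        Criterion.at_least("A-inlet", "C-inlet"),
        Criterion.exclusively("A-inlet"),
        Criterion.exclusively("C-inlet"),
        Criterion.exclusively(),
    ]
    for crit in criteria:
        bf = enumerate_bruteforce(u, panel, crit)
        for blocks in (2, 3, 4):
            dm = enumerate_divide_merge(u, panel, crit, blocks=blocks)
            assert dm.masks() == bf.masks(), (crit, blocks)


def test_divide_merge_prunes(layered, layered_viable):
    u, panel, _ = layered
    dm = enumerate_divide_merge(u, panel, Criterion.at_least(panel[0].name), blocks=3)
    assert dm.masks() == layered_viable.masks()
    assert dm.stats["fba_tests"] < 2**u.N  # monotone pruning pays off
    assert dm.stats["pruned_patterns"] > 0


def test_divide_merge_inviable_criterion_empty(toy):
    from fluxspace import Environment, EnvironmentPanel

    u, panel = toy
    # an environment supplying nothing: even the full universe is inviable
    closed = EnvironmentPanel(list(panel) + [Environment("closed", "EX_A", {"EX_A": 0.0})])
    gs = enumerate_divide_merge(u, closed, Criterion.at_least("closed"))
    assert len(gs) == 0
    # unknown source names are rejected outright
    with pytest.raises(ValueError):
        enumerate_divide_merge(u, panel, Criterion.at_least("no-such-source"))


def test_members_satisfy_criterion_spot_check(layered, layered_viable):
    u, panel, _ = layered
    crit = layered_viable.criterion
    env = panel[panel.index_of(crit.sources[0])]
    step = max(1, len(layered_viable) // 10)
    for g in layered_viable.members[::step]:
        assert solve_fba(u, g, env).viable
    assert len(set(layered_viable.members)) == len(layered_viable)  # unique


def test_genotype_set_save_load(tmp_path, layered_viable):
    path = tmp_path / "set.txt"
    layered_viable.save(path)
    back = GenotypeSet.load(path)
    assert back.masks() == layered_viable.masks()
    assert back.criterion == layered_viable.criterion
    assert back.n_bits == layered_viable.n_bits
    assert back.universe_hash == layered_viable.universe_hash


def test_binomial_prediction():
    assert binomial_prediction(51, 23, 25) == math.comb(28, 2) == 378
    assert binomial_prediction(51, 23, 23) == 1
    assert binomial_prediction(4, 2, 3) == 2
    with pytest.raises(ValueError):
        binomial_prediction(10, 5, 4)


def test_binomial_is_lower_bound(toy, layered_viable):
    u, panel = toy
    gs = enumerate_bruteforce(u, panel, Criterion.at_least("A-inlet"))
    for hist, N in [
        (size_histogram(gs), 4),
        (size_histogram(layered_viable), layered_viable.n_bits),
    ]:
        for n, count in hist.counts.items():
            assert count >= binomial_prediction(N, hist.n_min, n)


def test_phenotype_table_independent_sources():
    # two sources with disjoint routes: no implications, all phenotypes with
    # >=1 viability realized
    u, panel, _ = make_layered_universe(
        SyntheticUniverseSpec(n_sources=2, layers=1, alternatives=1, seed=3)
    )
    sets = {
        e.name: enumerate_bruteforce(u, panel, Criterion.at_least(e.name))
        for e in panel
    }
    pt = phenotype_table(sets, panel.names)
    assert pt.implications == []
    assert pt.realized == 3  # (1,0), (0,1), (1,1)
    assert pt.forbidden_per_implication == 2 ** (len(panel) - 2)


def test_phenotype_table_implication(toy):
    u, panel = toy
    # every C-viable metabolism needs r2 and r4, which also enables... not A.
    # Build the sets and detect whatever containment holds exactly.
    sets = {
        e.name: enumerate_bruteforce(u, panel, Criterion.at_least(e.name))
        for e in panel
    }
    pt = phenotype_table(sets, panel.names)
    a, c = sets["A-inlet"].masks(), sets["C-inlet"].masks()
    assert (("C-inlet", "A-inlet") in pt.implications) == (c <= a)
    assert sum(pt.counts.values()) == len(a | c)


def test_v_sets_partition(toy):
    u, panel = toy
    sets = {
        e.name: enumerate_bruteforce(u, panel, Criterion.at_least(e.name))
        for e in panel
    }
    v_a = v_at_least(sets, ["A-inlet"])
    v_both = v_at_least(sets, ["A-inlet", "C-inlet"])
    assert v_both <= v_a
    excl_a = v_exclusively(sets, ["A-inlet"], panel.names)
    excl_c = v_exclusively(sets, ["C-inlet"], panel.names)
    excl_both = v_exclusively(sets, ["A-inlet", "C-inlet"], panel.names)
    union = sets["A-inlet"].masks() | sets["C-inlet"].masks()
    # exclusive sets partition the viable universe
    assert excl_a | excl_c | excl_both == union
    assert len(excl_a) + len(excl_c) + len(excl_both) == len(union)
    with pytest.raises(ValueError):
        v_at_least(sets, [])


def test_disconnected_fraction_toy(toy):
    u, panel = toy
    eA = panel[panel.index_of("A-inlet")]
    gs = enumerate_bruteforce(u, panel, Criterion.at_least("A-inlet"))
    per_size, overall = disconnected_fraction(gs, u, eA)
    assert per_size[3] == pytest.approx(2 / 3)
    assert per_size[2] == 0.0  # minimal metabolisms are fully connected
    assert per_size[4] == 0.0  # full network is fully connected
    assert overall == pytest.approx(2 / 5)
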