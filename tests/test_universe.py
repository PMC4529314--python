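import numpy as np
import pytest

from fluxspace import (
    Environment,
    EnvironmentPanel,
    ModelFormatError,
    ReactionRow,
    build_universe,
    environment_bounds,
    load_environments,
    load_universe,
    save_environments,
    save_universe,
)
from fluxspace.universe import format_equation, parse_equation


def test_parse_equation():
    coeffs, rev = parse_equation("2 A + B -> C")
    assert coeffs == {"A": -2.0, "B": -1.0, "C": 1.0}
    assert not rev
    coeffs, rev = parse_equation("A <-> B")
    assert rev
    # drain with empty right-hand side
    coeffs, _ = parse_equation("P ->")
    assert coeffs == {"P": -1.0}
    # metabolite ids may start with a digit (no space = no coefficient)
    coeffs, _ = parse_equation("3pg_c -> 2pg_c")
    assert coeffs == {"3pg_c": -1.0, "2pg_c": 1.0}
    with pytest.raises(ModelFormatError):
        parse_equation("A = B")
    with pytest.raises(ModelFormatError):
        parse_equation("A -> A")  # zero net stoichiometry


def test_format_parse_round_trip():
    coeffs = {"A": -2.0, "B": -1.0, "C": 1.0, "D": 0.5}
    back, _ = parse_equation(format_equation(coeffs))
    assert back == coeffs


def _toy_rows():
    return [
        ReactionRow("r1", {"A": -1.0, "B": 1.0}, False, 0.0, 1000.0, "internal"),
        ReactionRow("t1", {"A_ext": -1.0, "A": 1.0}, True, -1000.0, 1000.0, "transport"),
        ReactionRow("EX_A", {"A_ext": -1.0}, False, -10.0, 1000.0, "exchange"),
        ReactionRow("BM", {"B": -1.0}, False, 0.0, 1000.0, "biomass"),
    ]


def test_build_and_index():
    u = build_universe(_toy_rows(), ["A_ext", "A", "B"], ["B"])
    assert u.N == 1
    assert u.internal_reaction_ids == ("r1",)
    assert u.internal_bit("r1") == 0
    assert u.objective[u.biomass_idx] == 1.0
    assert u.reaction_coeffs(u.reaction_index("r1")) == {"A": -1.0, "B": 1.0}


def test_validation_errors():
    rows = _toy_rows()
    with pytest.raises(ModelFormatError, match="undeclared metabolite"):
        build_universe(rows, ["A_ext", "A"], [])  # B missing
    with pytest.raises(ModelFormatError, match="duplicate"):
        build_universe(rows + [rows[0]], ["A_ext", "A", "B"], ["B"])
    with pytest.raises(ModelFormatError, match="not consumed"):
        build_universe(rows, ["A_ext", "A", "B"], ["A"])  # A not a biomass substrate
    with pytest.raises(ModelFormatError, match="lb > ub"):
        build_universe(
            [ReactionRow("bad", {"A": -1.0, "B": 1.0}, False, 5.0, 1.0, "internal")]
            + rows[1:],
            ["A_ext", "A", "B"],
            ["B"],
        )
    with pytest.raises(ModelFormatError, match="negative lower bound"):
        build_universe(
            [ReactionRow("bad", {"A": -1.0, "B": 1.0}, False, -1.0, 1.0, "internal")]
            + rows[1:],
            ["A_ext", "A", "B"],
            ["B"],
        )
    with pytest.raises(ModelFormatError, match="biomass"):
        build_universe(rows[:-1], ["A_ext", "A", "B"], [])


def _universes_equal(a, b):
    return (
        a.metabolite_ids == b.metabolite_ids
        and a.reaction_ids == b.reaction_ids
        and a.classes == b.classes
        and a.precursor_ids == b.precursor_ids
        and a.cofactor_pairs == b.cofactor_pairs
        and np.array_equal(a.lb, b.lb)
        and np.array_equal(a.ub, b.ub)
        and np.array_equal(a.reversible, b.reversible)
        and (a.stoich != b.stoich).nnz == 0
        and a.model_hash() == b.model_hash()
    )


def test_round_trip_toy(tmp_path, toy):
    u, panel = toy
    path = tmp_path / "toy.tsv"
    save_universe(u, path)
    assert _universes_equal(load_universe(path), u)
    epath = tmp_path / "toy_envs.tsv"
    save_environments(panel, epath)
    panel2 = load_environments(epath, u)
    assert panel2.names == panel.names
    assert all(
        dict(e2.uptake_bounds) == dict(e1.uptake_bounds)
        and e2.carbon_source == e1.carbon_source
        for e1, e2 in zip(panel, panel2)
    )


def test_round_trip_ccm(tmp_path, ccm):
    u, panel = ccm
    path = tmp_path / "ccm.tsv"
    save_universe(u, path)
    assert _universes_equal(load_universe(path), u)


def test_ccm_fixture_shape(ccm):
    u, panel = ccm
    assert u.N == 51
    assert len(u.transport_idx) == 20
    assert len(panel) == 10
    assert len(u.precursor_ids) == 12
    assert len(u.cofactor_pairs) == 3
    carbons = {e.carbon_source for e in panel}
    assert len(carbons) == 10
    shared = [frozenset(e.open_exchanges) - {e.carbon_source} for e in panel]
    assert all(s == shared[0] for s in shared)  # shared nutrients identical


def test_environment_bounds(toy):
    u, panel = toy
    lb, ub = environment_bounds(u, panel[0])  # A supplied
    jA = u.reaction_index("EX_A")
    jC = u.reaction_index("EX_C")
    assert lb[jA] == -10.0
    assert lb[jC] == 0.0  # closed for uptake
    assert ub[jC] > 0  # export still possible


def test_environment_file_errors(tmp_path, toy):
    u, _ = toy
    bad = tmp_path / "envs.tsv"
    bad.write_text("environment\texchange\tbound\trole\nx\tEX_missing\t10\tcarbon\n")
    with pytest.raises(ModelFormatError, match="EX_missing"):
        load_environments(bad, u)
    bad.write_text("environment\texchange\tbound\trole\nx\tEX_A\t10\tshared\n")
    with pytest.raises(ModelFormatError, match="carbon"):
        load_environments(bad, u)


def test_panel_duplicate_names():
    e = Environment("x", "EX_A", {"EX_A": 10.0})
    with pytest.raises(ModelFormatError):
        EnvironmentPanel([e, e])
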