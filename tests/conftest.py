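import pytest

from fluxspace import (
    Criterion,
    SyntheticUniverseSpec,
    enumerate_bruteforce,
    load_ccm,
    make_layered_universe,
    toy_a,
)


@pytest.fixture(scope="session")
def toy():
    """The 4-reaction worked example: (universe, panel)."""
    return toy_a()


@pytest.fixture(scope="session")
def layered():
    """One deterministic mid-size layered universe: (universe, panel, truth)."""
    return make_layered_universe(
        SyntheticUniverseSpec(n_sources=2, layers=2, alternatives=2, seed=0)
    )


@pytest.fixture(scope="session")
def layered_viable(layered):
    """All-size viable set of the first source of the layered universe."""
    u, panel, _ = layered
    return enumerate_bruteforce(u, panel, Criterion.at_least(panel[0].name))


@pytest.fixture(scope="session")
def ccm():
    """The bundled 51-reaction central carbon metabolism fixture."""
    return load_ccm()
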