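"""Bundled datasets.

``load_ccm`` returns the curated central carbon metabolism universe shipped
as package data: 51 internal reactions (the genotype bits), always-present
transport reactions, exchange pseudo-reactions and a biomass objective,
together with a panel of ten minimal environments that differ only in the
sole carbon source (glucose, fructose, acetate, 2-oxoglutarate, fumarate,
glutamate, D-lactate, L-malate, pyruvate, succinate).

The files are produced by ``scripts/build_ccm_fixture.py`` from a published
genome-derived core model of Escherichia coli metabolism; see
``docs/methods.md`` for the curation steps.
"""

from __future__ import annotations

from importlib.resources import as_file, files

from .universe import EnvironmentPanel, ReactionUniverse, load_environments, load_universe


def load_ccm() -> tuple[ReactionUniverse, EnvironmentPanel]:
    """Load the central carbon metabolism universe and its 10-environment panel."""
    data = files("fluxspace") / "data"
    with as_file(data) as d:
        u = load_universe(d / "ccm_universe.tsv")
        panel = load_environments(d / "ccm_environments.tsv", u)
    return u, panel
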