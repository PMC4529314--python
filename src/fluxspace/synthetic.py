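"""Synthetic reaction universes with analytically known viable-set structure.

The layered generator emits directed acyclic universes of unit 1:1
conversions: each carbon source feeds a hub metabolite through parallel
branches of irreversible steps, and the hub feeds every biomass precursor.
On such universes FBA viability is provably equivalent to graph
reachability (every conversion is 1:1 and irreversible, so biomass can be
produced at the full uptake-limited rate whenever every precursor is
reachable from the supplied nutrients, and not at all otherwise).  That
makes an LP-free ground-truth oracle available for every pipeline stage.

A second generator produces mass-balanced universes with non-unit
stoichiometry for stress testing, including optional co-factor reaction
pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotypes import Genotype
from .universe import (
    Environment,
    EnvironmentPanel,
    ReactionRow,
    ReactionUniverse,
    build_universe,
)


@dataclass(frozen=True)
class SyntheticUniverseSpec:
    """Parameters of a generated universe.

    ``layers`` is the nominal branch length from a carbon source to the hub;
    individual branches draw their length from ``1..layers``.  ``alternatives``
    is the number of parallel branches per source.  ``precursor_routes``
    controls redundancy of the final hub-to-precursor steps (1 makes each of
    them essential).
    """

    n_sources: int = 1
    layers: int = 2
    alternatives: int = 2
    n_precursors: int = 1
    seed: int = 0
    mode: str = "layered_dag"
    precursor_routes: int = 1
    cross_edge_prob: float = 0.0


@dataclass
class LayeredGroundTruth:
    """Reachability structure of a layered universe.

    ``edges`` maps a substrate metabolite to ``(bit, product)`` pairs for the
    internal reactions; ``source_of`` maps environment name to the cytosolic
    carbon-source metabolite.
    """

    edges: dict[str, list[tuple[int, str]]]
    source_of: dict[str, str]
    precursors: tuple[str, ...]
    hub: str
    n_bits: int
    per_source_dist: dict[str, int] = field(default_factory=dict)

    def viable(self, g: Genotype, env_name: str) -> bool:
        """True iff every precursor is reachable from the supplied source."""
        available = {self.source_of[env_name]}
        frontier = [self.source_of[env_name]]
        while frontier:
            met = frontier.pop()
            for bit, prod in self.edges.get(met, ()):
                if g.has(bit) and prod not in available:
                    available.add(prod)
                    frontier.append(prod)
        return all(p in available for p in self.precursors)

    def n_min(self, env_names) -> int:
        """Closed-form minimal viable size for a set of required sources.

        Branch subgraphs of different sources are disjoint upstream of the
        hub, so the minimum is the sum of per-source shortest paths to the
        hub plus one terminal reaction per precursor.
        """
        return sum(self.per_source_dist[n] for n in env_names) + len(self.precursors)


def _bfs_dist(edges: dict[str, list[tuple[int, str]]], src: str, dst: str) -> int:
    from collections import deque

    q = deque([(src, 0)])
    seen = {src}
    while q:
        met, d = q.popleft()
        if met == dst:
            return d
        for _, prod in edges.get(met, ()):
            if prod not in seen:
                seen.add(prod)
                q.append((prod, d + 1))
    raise ValueError(f"hub {dst!r} unreachable from {src!r}")


def make_layered_universe(
    spec: SyntheticUniverseSpec,
) -> tuple[ReactionUniverse, EnvironmentPanel, LayeredGroundTruth]:
    """Generate a layered DAG universe, its environment panel, and ground truth."""
    if spec.mode != "layered_dag":
        raise ValueError("make_layered_universe requires mode='layered_dag'")
    rng = np.random.default_rng(spec.seed)
    mets: list[str] = []
    rows: list[ReactionRow] = []
    edges: dict[str, list[tuple[int, str]]] = {}
    internal_eqs: list[tuple[str, str]] = []  # (substrate, product) in bit order

    def add_met(m: str) -> str:
        mets.append(m)
        return m

    hub = add_met("hub")
    precursors = [add_met(f"prec{j}") for j in range(spec.n_precursors)]
    source_of: dict[str, str] = {}
    envs: list[Environment] = []

    for s in range(spec.n_sources):
        src = add_met(f"c{s}")
        add_met(f"c{s}_ext")
        source_of[f"env{s}"] = src
        layer_nodes: list[list[str]] = []
        for b in range(spec.alternatives):
            length = int(rng.integers(1, spec.layers + 1))
            prev = src
            chain: list[str] = []
            for l in range(length - 1):
                node = add_met(f"c{s}b{b}l{l}")
                internal_eqs.append((prev, node))
                chain.append(node)
                prev = node
            internal_eqs.append((prev, hub))
            layer_nodes.append(chain)
        # optional cross edges between branches of the same source
        if spec.cross_edge_prob > 0 and spec.alternatives > 1:
            for b1 in range(spec.alternatives):
                for b2 in range(spec.alternatives):
                    if b1 == b2:
                        continue
                    for n1 in layer_nodes[b1]:
                        for n2 in layer_nodes[b2]:
                            if rng.random() < spec.cross_edge_prob:
                                internal_eqs.append((n1, n2))

    for j, p in enumerate(precursors):
        for r in range(spec.precursor_routes):
            if r == 0:
                internal_eqs.append((hub, p))
            else:
                via = add_met(f"alt{j}r{r}")
                internal_eqs.append((hub, via))
                internal_eqs.append((via, p))

    for bit, (sub, prod) in enumerate(internal_eqs):
        rows.append(
            ReactionRow(f"r{bit}", {sub: -1.0, prod: 1.0}, False, 0.0, 1000.0, "internal")
        )
        edges.setdefault(sub, []).append((bit, prod))

    for s in range(spec.n_sources):
        rows.append(
            ReactionRow(
                f"t{s}", {f"c{s}_ext": -1.0, f"c{s}": 1.0}, False, 0.0, 1000.0, "transport"
            )
        )
    for s in range(spec.n_sources):
        rows.append(
            ReactionRow(f"EX_c{s}", {f"c{s}_ext": -1.0}, False, -10.0, 1000.0, "exchange")
        )
    rows.append(
        ReactionRow(
            "BIOMASS", {p: -1.0 for p in precursors}, False, 0.0, 1000.0, "biomass"
        )
    )
    u = build_universe(
        rows,
        mets,
        precursors,
        meta={"mode": "layered_dag", "seed": str(spec.seed)},
    )
    for s in range(spec.n_sources):
        envs.append(Environment(f"env{s}", f"EX_c{s}", {f"EX_c{s}": 10.0}))
    panel = EnvironmentPanel(envs)
    gt = LayeredGroundTruth(
        edges=edges,
        source_of=source_of,
        precursors=tuple(precursors),
        hub=hub,
        n_bits=len(internal_eqs),
    )
    for name, src in source_of.items():
        gt.per_source_dist[name] = _bfs_dist(edges, src, hub)
    return u, panel, gt


def reachability_oracle(u: ReactionUniverse, g: Genotype, e: Environment) -> bool:
    """LP-free viability oracle for layered (irreversible, 1:1) universes.

    Forward closure: starting from the nutrients supplied by the
    environment, fire any present reaction (transporters always present)
    whose substrates are all available; viable iff every biomass precursor
    becomes available.  Equivalent to FBA viability only on irreversible
    unit-stoichiometry DAGs, hence the mode guard.
    """
    if u.meta.get("mode") != "layered_dag":
        raise ValueError("reachability oracle is only valid for layered_dag universes")
    available: set[str] = set()
    for j in u.exchange_idx:
        rid = u.reaction_ids[j]
        if e.uptake_bounds.get(rid, 0.0) > 0:
            available.update(u.reaction_coeffs(j))
    active: list[dict[str, float]] = [
        u.reaction_coeffs(int(j)) for j in u.transport_idx
    ] + [
        u.reaction_coeffs(int(j))
        for i, j in enumerate(u.internal_idx)
        if g.has(i)
    ]
    changed = True
    while changed:
        changed = False
        for coeffs in active:
            subs = [m for m, c in coeffs.items() if c < 0]
            prods = [m for m, c in coeffs.items() if c > 0]
            if all(m in available for m in subs) and any(
                m not in available for m in prods
            ):
                available.update(prods)
                changed = True
    return all(p in available for p in u.precursor_ids)


def toy_a() -> tuple[ReactionUniverse, EnvironmentPanel]:
    """The four-reaction worked example used throughout the documentation.

    Internal reactions (bit order): r1 A->B, r2 B->P, r3 A->C, r4 C->B.
    Two environments supply A or C as sole carbon source; P is the single
    biomass precursor.  Viable on A: {r1,r2} plus any superset containing
    both, or {r2,r3,r4}; viable on C: requires r4 and r2.
    """
    rows = [
        ReactionRow("r1", {"A": -1.0, "B": 1.0}, False, 0.0, 1000.0, "internal"),
        ReactionRow("r2", {"B": -1.0, "P": 1.0}, False, 0.0, 1000.0, "internal"),
        ReactionRow("r3", {"A": -1.0, "C": 1.0}, False, 0.0, 1000.0, "internal"),
        ReactionRow("r4", {"C": -1.0, "B": 1.0}, False, 0.0, 1000.0, "internal"),
        ReactionRow("tA", {"A_ext": -1.0, "A": 1.0}, False, 0.0, 1000.0, "transport"),
        ReactionRow("tC", {"C_ext": -1.0, "C": 1.0}, False, 0.0, 1000.0, "transport"),
        ReactionRow("EX_A", {"A_ext": -1.0}, False, -10.0, 1000.0, "exchange"),
        ReactionRow("EX_C", {"C_ext": -1.0}, False, -10.0, 1000.0, "exchange"),
        ReactionRow("BIOMASS", {"P": -1.0}, False, 0.0, 1000.0, "biomass"),
    ]
    u = build_universe(
        rows,
        ["A_ext", "C_ext", "A", "B", "C", "P"],
        ["P"],
        meta={"mode": "layered_dag"},
    )
    panel = EnvironmentPanel(
        [
            Environment("A-inlet", "EX_A", {"EX_A": 10.0}),
            Environment("C-inlet", "EX_C", {"EX_C": 10.0}),
        ]
    )
    return u, panel


def make_random_massbalanced(spec: SyntheticUniverseSpec) -> ReactionUniverse:
    """Mass-balanced random universe with non-unit stoichiometry.

    Every metabolite carries an integer pseudo-mass and every generated
    reaction satisfies ``sum(coeff * mass) = 0``, padded where necessary
    with a unit-mass filler metabolite.  When ``alternatives > 1`` one chain
    step is emitted in ``alternatives`` co-factor variants, declared in
    ``cofactor_pairs``.
    """
    if spec.mode != "random_massbalanced":
        raise ValueError("make_random_massbalanced requires mode='random_massbalanced'")
    rng = np.random.default_rng(spec.seed)
    n_chain = max(2, spec.layers + 1)
    mets = ["unit", "src_ext", "src"]
    src_mass = int(rng.integers(2, 6))
    masses = {"unit": 1, "src_ext": src_mass, "src": src_mass}
    chain = ["src"]
    for i in range(1, n_chain):
        m = f"m{i}"
        mets.append(m)
        masses[m] = int(rng.integers(1, 6))
        chain.append(m)
    rows: list[ReactionRow] = []
    pairs: list[tuple[str, str]] = []
    cof_step = int(rng.integers(0, n_chain - 1)) if spec.alternatives > 1 else -1
    for i in range(n_chain - 1):
        a, b = chain[i], chain[i + 1]
        # choose substrate count so at least one product fits, pad rest as unit
        coeff_a = int(rng.integers(1, 3))
        while coeff_a * masses[a] < masses[b]:
            coeff_a += 1
        mass_in = coeff_a * masses[a]
        coeff_b = mass_in // masses[b]
        pad = mass_in - coeff_b * masses[b]
        coeffs = {a: -float(coeff_a), b: float(coeff_b)}
        if pad > 0:
            coeffs["unit"] = float(pad)
        variants = spec.alternatives if i == cof_step else 1
        cof_ids = []
        for v in range(variants):
            rid = f"s{i}" if variants == 1 else f"s{i}_cof{v}"
            c = dict(coeffs)
            if variants > 1:
                ox, red = f"cof{v}_ox", f"cof{v}_red"
                for cm in (ox, red):
                    if cm not in masses:
                        mets.append(cm)
                        masses[cm] = 1
                c[ox] = c.get(ox, 0.0) - 1.0
                c[red] = c.get(red, 0.0) + 1.0
                c_regen = {red: -1.0, ox: 1.0}
                rows.append(
                    ReactionRow(f"regen{v}_{i}", c_regen, False, 0.0, 1000.0, "internal")
                )
            rows.append(ReactionRow(rid, c, False, 0.0, 1000.0, "internal"))
            cof_ids.append(rid)
        if len(cof_ids) >= 2:
            pairs.append((cof_ids[0], cof_ids[1]))
    rows.append(
        ReactionRow("t_src", {"src_ext": -1.0, "src": 1.0}, False, 0.0, 1000.0, "transport")
    )
    rows.append(ReactionRow("EX_src", {"src_ext": -1.0}, False, -10.0, 1000.0, "exchange"))
    rows.append(ReactionRow("EX_unit", {"unit": -1.0}, False, 0.0, 1000.0, "exchange"))
    rows.append(
        ReactionRow("BIOMASS", {chain[-1]: -1.0}, False, 0.0, 1000.0, "biomass")
    )
    u = build_universe(
        rows,
        mets,
        [chain[-1]],
        cofactor_pairs=pairs,
        meta={
            "mode": "random_massbalanced",
            "seed": str(spec.seed),
            "masses": " ".join(f"{m}={masses[m]}" for m in mets),
        },
    )
    return u
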