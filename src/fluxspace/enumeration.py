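"""Exhaustive enumeration of viable genotypes.

Two engines produce identical member sets:

* :func:`enumerate_bruteforce` phenotypes all ``2**N`` genotypes (guarded to
  small N) and is the reference path;
* :func:`enumerate_divide_merge` first fixes reactions whose deletion from
  the complete universe already breaks the viability criterion (they must be
  present in every member, by monotonicity), then partitions the remaining
  free bit positions into blocks, enumerates viable sub-patterns per block
  and merges blocks pairwise.  A partial pattern is kept iff its most
  permissive completion (all unresolved bits set) is viable: deleting
  reactions from an inviable metabolism cannot restore viability, so a
  partial pattern whose permissive completion is inviable has no viable
  completion at all and the whole sub-cube can be pruned.

Viability criteria are ``at_least(S)`` (viable on every source in S) and
``exclusively(S)`` (additionally inviable on every other panel source).
Only the ``at_least`` part is monotone; the exclusive variant is obtained by
filtering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .fba import DEFAULT_THRESHOLD, PhenotypeVector, get_context, phenotype
from .genotypes import Genotype
from .universe import EnvironmentPanel, ReactionUniverse


@dataclass(frozen=True)
class Criterion:
    """Viability criterion over named panel environments."""

    kind: str  # "at_least" | "exclusively"
    sources: tuple[str, ...]

    def __post_init__(self):
        if self.kind not in ("at_least", "exclusively"):
            raise ValueError(f"unknown criterion kind {self.kind!r}")

    @classmethod
    def at_least(cls, *sources: str) -> "Criterion":
        return cls("at_least", tuple(sources))

    @classmethod
    def exclusively(cls, *sources: str) -> "Criterion":
        return cls("exclusively", tuple(sources))

    @classmethod
    def parse(cls, text: str) -> "Criterion":
        """Parse e.g. ``"at-least:glucose+lactate"`` or ``"excl:acetate"``."""
        kind, _, rest = text.partition(":")
        sources = tuple(s for s in rest.split("+") if s)
        kind = {"at-least": "at_least", "at_least": "at_least",
                "excl": "exclusively", "exclusively": "exclusively"}.get(kind)
        if kind is None:
            raise ValueError(f"cannot parse criterion {text!r}")
        return cls(kind, sources)

    def __str__(self) -> str:
        tag = "at-least" if self.kind == "at_least" else "excl"
        return f"{tag}:{'+'.join(self.sources)}"


@dataclass
class GenotypeSet:
    """Enumerated genotypes satisfying a criterion (optionally one size)."""

    universe_hash: str
    criterion: Criterion
    n_bits: int
    members: tuple[Genotype, ...]
    size: int | None = None  # None = all sizes
    stats: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def masks(self) -> frozenset[int]:
        return frozenset(g.mask for g in self.members)

    def by_size(self) -> dict[int, list[Genotype]]:
        out: dict[int, list[Genotype]] = {}
        for g in self.members:
            out.setdefault(g.size, []).append(g)
        return out

    def filter_size(self, n: int) -> "GenotypeSet":
        return GenotypeSet(
            self.universe_hash,
            self.criterion,
            self.n_bits,
            tuple(g for g in self.members if g.size == n),
            size=n,
        )

    def save(self, path) -> None:
        """One hex genotype per line, header records hash/criterion/bit count."""
        from pathlib import Path

        lines = [
            f"# universe_hash={self.universe_hash} criterion={self.criterion} n_bits={self.n_bits}"
        ]
        lines += [g.to_hex() for g in sorted(self.members)]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path) -> "GenotypeSet":
        from pathlib import Path

        lines = Path(path).read_text().splitlines()
        header = lines[0].lstrip("# ").split()
        kv = dict(item.split("=", 1) for item in header)
        n_bits = int(kv["n_bits"])
        members = tuple(Genotype.from_hex(s, n_bits) for s in lines[1:] if s.strip())
        return cls(kv["universe_hash"], Criterion.parse(kv["criterion"]), n_bits, members)


@dataclass
class EnumerationTable:
    """Per-size counts of viable genotypes under one criterion."""

    criterion: Criterion
    N: int
    counts: dict[int, int]
    total: int

    @property
    def n_min(self) -> int | None:
        sizes = [n for n, c in self.counts.items() if c > 0]
        return min(sizes) if sizes else None

    def fraction(self, n: int) -> float:
        return self.counts.get(n, 0) / math.comb(self.N, n)

    def to_frame(self):
        import pandas as pd

        rows = [
            {
                "criterion": str(self.criterion),
                "n": n,
                "count": c,
                "fraction": self.fraction(n),
            }
            for n, c in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows, columns=["criterion", "n", "count", "fraction"])


def _criterion_envs(panel: EnvironmentPanel, criterion: Criterion):
    required = [panel[panel.index_of(s)] for s in criterion.sources]
    complement = [e for e in panel if e.name not in criterion.sources]
    return required, complement


def _satisfies(ctxs_req, ctxs_comp, mask: int, exclusive: bool) -> bool:
    for ctx in ctxs_req:
        if not ctx.viable(mask):
            return False
    if exclusive:
        for ctx in ctxs_comp:
            if ctx.viable(mask):
                return False
    return True


def enumerate_bruteforce(
    u: ReactionUniverse,
    panel: EnvironmentPanel,
    criterion: Criterion,
    threshold_fraction: float = DEFAULT_THRESHOLD,
    guard: int = 20,
) -> GenotypeSet:
    """Test all ``2**N`` genotypes with FBA; exact but exponential."""
    if u.N > guard:
        raise ValueError(f"brute force refused for N={u.N} > {guard}")
    required, complement = _criterion_envs(panel, criterion)
    ctxs_req = [get_context(u, e, threshold_fraction) for e in required]
    ctxs_comp = [get_context(u, e, threshold_fraction) for e in complement]
    exclusive = criterion.kind == "exclusively"
    members = [
        Genotype(mask, u.N)
        for mask in range(1 << u.N)
        if _satisfies(ctxs_req, ctxs_comp, mask, exclusive)
    ]
    return GenotypeSet(
        u.model_hash(),
        criterion,
        u.N,
        tuple(members),
        stats={"fba_tests": (1 << u.N) * max(1, len(ctxs_req))},
    )


def _contiguous_blocks(items: Sequence[int], blocks: int) -> list[list[int]]:
    blocks = max(1, min(blocks, len(items))) if items else 0
    if blocks == 0:
        return []
    base, extra = divmod(len(items), blocks)
    out, pos = [], 0
    for b in range(blocks):
        size = base + (1 if b < extra else 0)
        out.append(list(items[pos : pos + size]))
        pos += size
    return [b for b in out if b]


def enumerate_divide_merge(
    u: ReactionUniverse,
    panel: EnvironmentPanel,
    criterion: Criterion,
    blocks: int = 5,
    threshold_fraction: float = DEFAULT_THRESHOLD,
) -> GenotypeSet:
    """Exhaustive enumeration with essentiality pre-fixing and monotone pruning.

    Identical member set to :func:`enumerate_bruteforce`, usually at a small
    fraction of the FBA tests.
    """
    required, complement = _criterion_envs(panel, criterion)
    ctxs_req = [get_context(u, e, threshold_fraction) for e in required]
    ctxs_comp = [get_context(u, e, threshold_fraction) for e in complement]
    exclusive = criterion.kind == "exclusively"
    full_mask = (1 << u.N) - 1
    stats = {"fba_tests": 0, "pruned_patterns": 0, "fixed_bits": 0}

    def monotone_ok(mask: int) -> bool:
        stats["fba_tests"] += 1
        return all(ctx.viable(mask) for ctx in ctxs_req)

    members: list[Genotype]
    if ctxs_req and not monotone_ok(full_mask):
        # nothing can satisfy an at_least criterion the full universe fails
        members = []
    else:
        # 1. fix reactions essential for the monotone part of the criterion
        essential_mask = 0
        for i in range(u.N):
            if ctxs_req and not monotone_ok(full_mask & ~(1 << i)):
                essential_mask |= 1 << i
        stats["fixed_bits"] = essential_mask.bit_count()
        free_bits = [i for i in range(u.N) if not essential_mask >> i & 1]
        partition = _contiguous_blocks(free_bits, blocks)

        def block_mask(bits: Iterable[int]) -> int:
            m = 0
            for i in bits:
                m |= 1 << i
            return m

        # 2. viable sub-patterns per block under most-permissive completion
        surviving: list[list[int]] = []
        for blk in partition:
            rest = full_mask & ~essential_mask & ~block_mask(blk)
            pats = []
            for assign in range(1 << len(blk)):
                pat = 0
                for pos, bit in enumerate(blk):
                    if assign >> pos & 1:
                        pat |= 1 << bit
                if monotone_ok(essential_mask | pat | rest):
                    pats.append(pat)
                else:
                    stats["pruned_patterns"] += 1
            surviving.append(pats)

        # 3. merge blocks pairwise left-to-right, re-testing completions
        if not partition:
            merged = [0]
        else:
            merged = surviving[0]
            resolved = block_mask(partition[0])
            for blk, pats in zip(partition[1:], surviving[1:]):
                resolved |= block_mask(blk)
                rest = full_mask & ~essential_mask & ~resolved
                nxt = []
                for a in merged:
                    for b in pats:
                        if monotone_ok(essential_mask | a | b | rest):
                            nxt.append(a | b)
                        else:
                            stats["pruned_patterns"] += 1
                merged = nxt
        members = [Genotype(essential_mask | p, u.N) for p in merged]

    if exclusive:
        members = [
            g
            for g in members
            if not any(ctx.viable(g.mask) for ctx in ctxs_comp)
        ]
    return GenotypeSet(
        u.model_hash(), criterion, u.N, tuple(sorted(members)), stats=stats
    )


def size_histogram(gs: GenotypeSet, N: int | None = None) -> EnumerationTable:
    """Exact per-size counts; ``fraction(n) = count(n) / C(N, n)``."""
    N = gs.n_bits if N is None else N
    counts: dict[int, int] = {}
    for g in gs.members:
        counts[g.size] = counts.get(g.size, 0) + 1
    return EnumerationTable(gs.criterion, N, counts, len(gs.members))


def binomial_prediction(N: int, n_min: int, n: int) -> int:
    """Number of supersets of one minimal network: C(N - n_min, n - n_min).

    A lower bound on (and qualitative predictor of) the number of viable
    size-n genotypes, since every superset of a viable genotype is viable.
    """
    if n < n_min:
        raise ValueError("n must be at least n_min")
    return math.comb(N - n_min, n - n_min)


@dataclass
class PhenotypeTable:
    """Realized phenotypes, their genotype counts, and source implications."""

    panel_names: tuple[str, ...]
    counts: dict[PhenotypeVector, int]
    implications: list[tuple[str, str]]  # (src_i, src_j): viable on i => viable on j

    @property
    def realized(self) -> int:
        return len(self.counts)

    @property
    def forbidden_per_implication(self) -> int:
        """Phenotypes excluded by one implication: with source i implying
        source j, no phenotype can set bit i and clear bit j, which rules out
        ``2**(panel-2)`` of the ``2**panel`` combinations."""
        return 2 ** (len(self.panel_names) - 2)

    def to_frame(self):
        import pandas as pd

        rows = [
            {"phenotype": "".join(map(str, p.bits())), "k": p.k, "count": c}
            for p, c in sorted(self.counts.items(), key=lambda kv: kv[0].mask)
        ]
        return pd.DataFrame(rows, columns=["phenotype", "k", "count"])


def phenotype_table(
    viable_sets: Mapping[str, GenotypeSet],
    panel_names: Sequence[str],
) -> PhenotypeTable:
    """Phenotype counts and implications from per-carbon-source viable sets.

    ``viable_sets[name]`` is the all-size ``at_least(name)`` set.  A genotype
    viable on nothing contributes to the all-zero phenotype only implicitly
    (its count is not enumerated here).
    """
    panel_names = tuple(panel_names)
    mask_sets = {name: viable_sets[name].masks() for name in panel_names}
    counts: dict[PhenotypeVector, int] = {}
    union = set().union(*mask_sets.values()) if mask_sets else set()
    for gmask in union:
        p = 0
        for i, name in enumerate(panel_names):
            if gmask in mask_sets[name]:
                p |= 1 << i
        pv = PhenotypeVector(p, len(panel_names))
        counts[pv] = counts.get(pv, 0) + 1
    implications = [
        (a, b)
        for a in panel_names
        for b in panel_names
        if a != b and mask_sets[a] <= mask_sets[b]
    ]
    return PhenotypeTable(panel_names, counts, implications)


def v_at_least(
    viable_sets: Mapping[str, GenotypeSet], sources: Iterable[str]
) -> frozenset[int]:
    """V(S): genotype masks viable on at least every source in S."""
    sources = list(sources)
    if not sources:
        raise ValueError("V(S) of an empty S is the whole genotype space")
    out = set(viable_sets[sources[0]].masks())
    for s in sources[1:]:
        out &= viable_sets[s].masks()
    return frozenset(out)


def v_exclusively(
    viable_sets: Mapping[str, GenotypeSet],
    sources: Iterable[str],
    panel_names: Sequence[str],
) -> frozenset[int]:
    """V(S) exclusive: viable on every source in S and on no other source."""
    sources = set(sources)
    out = v_at_least(viable_sets, sources)
    for other in panel_names:
        if other not in sources:
            out -= viable_sets[other].masks()
    return frozenset(out)


def disconnected_fraction(
    gs: GenotypeSet, u: ReactionUniverse, e
) -> tuple[dict[int, float], float]:
    """Fraction f_d of members with at least one disconnected reaction.

    Returns per-size fractions and the overall fraction; ``1 - f_d`` is the
    fraction of metabolisms where every reaction is connected.
    """
    from .fba import disconnected_reactions

    per_size_tot: dict[int, int] = {}
    per_size_disc: dict[int, int] = {}
    n_disc = 0
    for g in gs.members:
        per_size_tot[g.size] = per_size_tot.get(g.size, 0) + 1
        if disconnected_reactions(u, g, e):
            per_size_disc[g.size] = per_size_disc.get(g.size, 0) + 1
            n_disc += 1
    per_size = {
        n: per_size_disc.get(n, 0) / tot for n, tot in sorted(per_size_tot.items())
    }
    overall = n_disc / len(gs.members) if gs.members else float("nan")
    return per_size, overall
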