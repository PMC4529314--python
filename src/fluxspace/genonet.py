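"""Genotype networks: graphs over equal-size viable genotypes.

Vertices are genotypes of a fixed size n that satisfy a viability criterion;
two vertices are adjacent when they differ by a single reaction swap (one
reaction removed, another added), i.e. at Hamming distance 2.

Adjacency is resolved through (n-1)-subset buckets: two size-n genotypes are
swap neighbors iff they share an (n-1)-reaction subset, so each genotype is
filed under its n "remove one bit" keys and neighbor queries are bucket
unions.  This avoids the quadratic all-pairs scan.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from .genotypes import Genotype, genotype_distance


def swap_neighbors(g: Genotype) -> Iterator[Genotype]:
    """All size-preserving single-swap neighbors of g in genotype space."""
    present = g.bits()
    absent = [i for i in range(g.n_bits) if not g.has(i)]
    for i in present:
        removed = g.mask & ~(1 << i)
        for j in absent:
            yield Genotype(removed | (1 << j), g.n_bits)


def max_swap_distance(n: int, N: int) -> int:
    """Upper bound on the swap distance between size-n genotypes over N bits.

    Two genotypes of size n can disagree on at most min(n, N - n) present
    reactions, so no shortest path (and hence no network diameter) can
    exceed that.
    """
    return min(n, N - n)


@dataclass
class GenotypeNetwork:
    """Swap-adjacency graph over a set of equal-size genotype masks."""

    n_bits: int
    size: int
    masks: frozenset[int]
    _buckets: dict[int, list[int]] = field(default_factory=dict, repr=False)

    @classmethod
    def from_masks(cls, masks: Iterable[int], size: int, n_bits: int) -> "GenotypeNetwork":
        masks = frozenset(masks)
        for m in masks:
            if m.bit_count() != size:
                raise ValueError(f"mask {m:#x} is not of size {size}")
        net = cls(n_bits=n_bits, size=size, masks=masks)
        for m in masks:
            rest = m
            while rest:
                bit = rest & -rest
                net._buckets.setdefault(m & ~bit, []).append(m)
                rest &= rest - 1
        return net

    @classmethod
    def from_genotype_set(cls, gs, size: int) -> "GenotypeNetwork":
        sub = gs.filter_size(size)
        return cls.from_masks((g.mask for g in sub.members), size, gs.n_bits)

    def __len__(self) -> int:
        return len(self.masks)

    def __contains__(self, mask: int) -> bool:
        return mask in self.masks

    def neighbors(self, mask: int) -> list[int]:
        """Swap neighbors of ``mask`` that are themselves in the network."""
        out: set[int] = set()
        rest = mask
        while rest:
            bit = rest & -rest
            out.update(self._buckets.get(mask & ~bit, ()))
            rest &= rest - 1
        out.discard(mask)
        return sorted(out)

    def degree(self, mask: int) -> int:
        return len(self.neighbors(mask))

    def edge_count(self) -> int:
        return sum(self.degree(m) for m in self.masks) // 2

    # -- connectivity ------------------------------------------------------

    def bfs_distances(self, source: int) -> dict[int, int]:
        """Shortest swap-path lengths from ``source`` within the network."""
        if source not in self.masks:
            raise ValueError("source is not a vertex of this network")
        dist = {source: 0}
        queue = deque([source])
        while queue:
            m = queue.popleft()
            d = dist[m] + 1
            for nb in self.neighbors(m):
                if nb not in dist:
                    dist[nb] = d
                    queue.append(nb)
        return dist

    def connected_components(self) -> list[frozenset[int]]:
        """Components, largest first (ties broken by smallest member)."""
        seen: set[int] = set()
        comps: list[frozenset[int]] = []
        for m in sorted(self.masks):
            if m in seen:
                continue
            comp = frozenset(self.bfs_distances(m))
            seen |= comp
            comps.append(comp)
        comps.sort(key=lambda c: (-len(c), min(c)))
        return comps

    def giant_component_fraction(self) -> float:
        if not self.masks:
            return float("nan")
        return len(self.connected_components()[0]) / len(self.masks)

    def is_connected(self) -> bool:
        return len(self.masks) > 0 and len(self.connected_components()) == 1

    def eccentricity(self, source: int) -> int:
        """Max shortest-path distance from ``source`` within its component."""
        return max(self.bfs_distances(source).values())

    def path_diameter(self) -> int:
        """Longest shortest swap path within the largest component.

        Paths are constrained to the network, so this can exceed the free
        swap-distance bound min(n, N-n); see :meth:`diameter` for the metric
        diameter that respects it.
        """
        comp = self.connected_components()[0]
        return max(self.eccentricity(m) for m in comp)

    def diameter(self) -> int:
        """Maximum swap distance between members of the largest component.

        This is the metric diameter in genotype space (half the maximal
        pairwise Hamming distance), exact over all pairs; it never exceeds
        min(n, N - n).
        """
        import numpy as np

        comp = self.connected_components()[0]
        arr = np.fromiter(comp, dtype=np.uint64)
        if arr.size == 1:
            return 0
        best = 0
        for k in range(arr.size - 1):
            ham = np.bitwise_count(arr[k] ^ arr[k + 1 :])
            best = max(best, int(ham.max()))
        return best // 2

    def sampled_diameter(self, n_samples: int, rng) -> int:
        """Lower bound on :meth:`diameter` from sampled member pairs."""
        import numpy as np

        comp = sorted(self.connected_components()[0])
        if len(comp) < 2:
            return 0
        arr = np.array(comp, dtype=np.uint64)
        i = rng.integers(0, arr.size, size=n_samples)
        j = rng.integers(0, arr.size, size=n_samples)
        ham = np.bitwise_count(arr[i] ^ arr[j])
        return int(ham.max()) // 2

    def path(self, source: int, target: int) -> list[int] | None:
        """One shortest swap path (list of masks), or None if disconnected."""
        if source not in self.masks or target not in self.masks:
            raise ValueError("endpoints must be vertices of the network")
        prev: dict[int, int | None] = {source: None}
        queue = deque([source])
        while queue:
            m = queue.popleft()
            if m == target:
                out = []
                cur: int | None = m
                while cur is not None:
                    out.append(cur)
                    cur = prev[cur]
                return out[::-1]
            for nb in self.neighbors(m):
                if nb not in prev:
                    prev[nb] = m
                    queue.append(nb)
        return None

    def to_networkx(self):  # pragma: no cover - convenience export
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.masks)
        for m in self.masks:
            for nb in self.neighbors(m):
                if m < nb:
                    g.add_edge(m, nb)
        return g


@dataclass(frozen=True)
class ComponentSummary:
    """Connectivity summary of one genotype network."""

    size: int  # metabolism size n
    n_members: int
    n_components: int
    component_sizes: tuple[int, ...]  # descending
    r_giant: float  # fraction of members in the largest component

    @classmethod
    def from_network(cls, net: "GenotypeNetwork") -> "ComponentSummary":
        comps = net.connected_components()
        sizes = tuple(len(c) for c in comps)
        return cls(
            size=net.size,
            n_members=len(net),
            n_components=len(comps),
            component_sizes=sizes,
            r_giant=sizes[0] / len(net) if net.masks else float("nan"),
        )


@dataclass(frozen=True)
class DiameterEstimate:
    """Diameter of a genotype network's giant component, in reaction swaps."""

    value: int
    mode: str  # "exact" | "sampled_lower_bound"
    sample_size: int | None
    max_possible: int  # min(n, N - n)


def diameter_estimate(
    net: GenotypeNetwork, sample_cap: int = 100_000, seed: int = 42
) -> DiameterEstimate:
    """Exact diameter when the giant component fits under ``sample_cap``,
    otherwise a seeded sampled lower bound."""
    import numpy as np

    giant = net.connected_components()[0]
    bound = max_swap_distance(net.size, net.n_bits)
    if len(giant) <= sample_cap:
        return DiameterEstimate(net.diameter(), "exact", None, bound)
    rng = np.random.default_rng(seed)
    return DiameterEstimate(
        net.sampled_diameter(sample_cap, rng), "sampled_lower_bound", sample_cap, bound
    )


def connectivity_inheritance(
    net_n: GenotypeNetwork, net_n1: GenotypeNetwork
) -> tuple[bool, str]:
    """Infer connectedness of the size-(n+1) network from the size-n one.

    If the size-n network is connected and every size-(n+1) member contains
    some size-n member, the size-(n+1) network is connected too: each
    size-(n+1) member reaches its size-n parent's neighborhood by one
    addition, and additions/swap paths lift to size n+1.  Returns
    ``(connected, mode)`` where mode is ``"inherited"`` when the inference
    applies and ``"bfs"`` when it falls back to a direct check.
    """
    if net_n1.size != net_n.size + 1:
        raise ValueError("networks must be of consecutive sizes")
    if net_n.is_connected():
        superset_of_member = all(
            any(m & parent == parent for parent in net_n.masks) for m in net_n1.masks
        )
        if superset_of_member:
            return True, "inherited"
    return net_n1.is_connected(), "bfs"


def max_distance_pairs(
    net: GenotypeNetwork, limit: int | None = None
) -> tuple[int, list[tuple[int, int]]]:
    """All (or the first ``limit``) giant-component pairs at the diameter."""
    import numpy as np

    comp = sorted(net.connected_components()[0])
    arr = np.array(comp, dtype=np.uint64)
    if arr.size == 1:
        return 0, [(comp[0], comp[0])]
    best = 0
    pairs: list[tuple[int, int]] = []
    for k in range(arr.size - 1):
        ham = np.bitwise_count(arr[k] ^ arr[k + 1 :])
        m = int(ham.max())
        if m > best:
            best, pairs = m, []
        if m == best:
            for off in np.nonzero(ham == m)[0]:
                if limit is None or len(pairs) < limit:
                    pairs.append((comp[k], comp[k + 1 + int(off)]))
    return best // 2, pairs


def cofactor_pair_filter(
    pairs: Sequence[tuple[int, int]], u
) -> tuple[float, list[tuple[int, int]]]:
    """Drop genotype pairs that differ by a declared co-factor isoform swap.

    A pair is eliminated when, for some declared co-factor reaction pair
    (a, b), one genotype uses isoform a but not b while the other uses b but
    not a.  Returns the percentage of pairs retained and the retained pairs.
    """
    keep: list[tuple[int, int]] = []
    bit_pairs = [
        (u.internal_bit(a), u.internal_bit(b)) for a, b in u.cofactor_pairs
    ]
    for m1, m2 in pairs:
        eliminated = False
        for ba, bb in bit_pairs:
            a1, b1 = m1 >> ba & 1, m1 >> bb & 1
            a2, b2 = m2 >> ba & 1, m2 >> bb & 1
            if (a1, b1) == (1, 0) and (a2, b2) == (0, 1):
                eliminated = True
            if (a1, b1) == (0, 1) and (a2, b2) == (1, 0):
                eliminated = True
        if not eliminated:
            keep.append((m1, m2))
    pct = 100.0 * len(keep) / len(pairs) if pairs else float("nan")
    return pct, keep


def blocked_at_max_distance(
    pairs: Sequence[tuple[int, int]], u, e, n_bits: int | None = None
) -> int:
    """Minimum over pairs of the summed blocked-reaction counts of both members."""
    from .fba import blocked_reactions

    if not pairs:
        raise ValueError("no pairs given")
    n_bits = u.N if n_bits is None else n_bits
    cache: dict[int, int] = {}

    def n_blocked(mask: int) -> int:
        if mask not in cache:
            cache[mask] = len(blocked_reactions(u, Genotype(mask, n_bits), e))
        return cache[mask]

    return min(n_blocked(a) + n_blocked(b) for a, b in pairs)


def min_inter_network_distance(
    net_a: Sequence[int] | frozenset[int],
    net_b: Sequence[int] | frozenset[int],
    n_bits: int,
) -> tuple[int, tuple[int, int]]:
    """D_min between two sets of equal-size genotypes, with a witness pair.

    Swap distance is half the Hamming distance; uses a vectorized XOR
    popcount over the full cross product.
    """
    import numpy as np

    a = np.fromiter(net_a, dtype=np.uint64)
    b = np.fromiter(net_b, dtype=np.uint64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both networks must be non-empty")
    if n_bits > 64:
        best, pair = None, None
        for ma in map(int, a):
            for mb in map(int, b):
                d = (ma ^ mb).bit_count() // 2
                if best is None or d < best:
                    best, pair = d, (ma, mb)
        return best, pair
    ham = np.bitwise_count(a[:, None] ^ b[None, :])
    i, j = np.unravel_index(int(np.argmin(ham)), ham.shape)
    return int(ham[i, j]) // 2, (int(a[i]), int(b[j]))
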