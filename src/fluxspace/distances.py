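"""Distances between genotype networks of different phenotypes.

Given equal-size viable genotype sets for different phenotype criteria,
D_min is the smallest swap distance between any member of one set and any
member of the other: the minimal number of reaction changes converting a
metabolism with one phenotype into a metabolism with the other.  D_min = 1
means the two networks abut.  The module also aggregates D_min by phenotypic
complexity (k, k') and builds the joint distribution of genotype distance
D_G versus phenotype distance D_P.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .fba import phenotype
from .genonet import GenotypeNetwork
from .genotypes import Genotype, genotype_distance


def overlap(a: frozenset[int], b: frozenset[int]) -> int:
    """Number of genotypes shared by two networks (D_min = 0 iff > 0)."""
    return len(frozenset(a) & frozenset(b))


def _bruteforce_dmin(a: np.ndarray, b: np.ndarray) -> int:
    best = None
    for k in range(a.size):
        ham = int(np.bitwise_count(a[k] ^ b).min())
        if best is None or ham < best:
            best = ham
            if best == 0:
                break
    return best // 2


def _subset_index(masks: Sequence[int]) -> set[int]:
    keys: set[int] = set()
    for m in masks:
        rest = m
        while rest:
            bit = rest & -rest
            keys.add(m & ~bit)
            rest &= rest - 1
    return keys


def min_network_distance(
    set_a: Sequence[int] | frozenset[int],
    set_b: Sequence[int] | frozenset[int],
    n_bits: int,
    giant_only: bool = False,
    size: int | None = None,
) -> int:
    """Exact D_min between two equal-size genotype sets.

    Checks D_min = 0 (overlap) and D_min = 1 (shared (n-1)-subset, via the
    same index that drives neighbor queries) in near-linear time before
    falling back to the vectorized all-cross-pairs minimum.  With
    ``giant_only=True`` each set is first restricted to the giant component
    of its genotype network (``size`` then must give the metabolism size).
    """
    a, b = frozenset(set_a), frozenset(set_b)
    if not a or not b:
        raise ValueError("both genotype sets must be non-empty")
    if giant_only:
        if size is None:
            size = next(iter(a)).bit_count()
        a = GenotypeNetwork.from_masks(a, size, n_bits).connected_components()[0]
        b = GenotypeNetwork.from_masks(b, size, n_bits).connected_components()[0]
    if a & b:
        return 0
    if _subset_index(sorted(a)) & _subset_index(sorted(b)):
        return 1
    arr_a = np.fromiter(sorted(a), dtype=np.uint64)
    arr_b = np.fromiter(sorted(b), dtype=np.uint64)
    if arr_a.size > arr_b.size:
        arr_a, arr_b = arr_b, arr_a
    return _bruteforce_dmin(arr_a, arr_b)


def dmin_matrix(
    nets: Mapping[str, frozenset[int] | Sequence[int]],
    n_bits: int,
    giant_only: bool = False,
    size: int | None = None,
):
    """Symmetric D_min matrix over named genotype networks (DataFrame)."""
    import pandas as pd

    names = list(nets)
    mat = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            d = min_network_distance(nets[a], nets[b], n_bits, giant_only, size)
            mat.loc[a, b] = mat.loc[b, a] = d
    return mat


@dataclass(frozen=True)
class ComplexityCell:
    """Aggregated network distances for one complexity pair (k, k')."""

    k1: int
    k2: int
    mean_dmin: float
    neighbor_fraction: float  # share of network pairs with D_min == 1
    n_pairs: int


def complexity_matrix(
    exclusive_sets: Mapping[str, frozenset[int]],
    complexities: Mapping[str, int],
    n_bits: int,
    giant_only: bool = False,
    size: int | None = None,
) -> list[ComplexityCell]:
    """Average D_min and neighbor fraction per phenotypic-complexity pair.

    ``exclusive_sets`` maps phenotype criterion strings (exclusive
    carbon-source combinations, e.g. ``"excl:glucose+lactate"``) to
    equal-size genotype sets; ``complexities`` gives each criterion's k.
    Pairs of distinct networks only; (k, k') is unordered.
    """
    names = [n for n in exclusive_sets if exclusive_sets[n]]
    cells: dict[tuple[int, int], list[int]] = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            d = min_network_distance(
                exclusive_sets[a], exclusive_sets[b], n_bits, giant_only, size
            )
            key = tuple(sorted((complexities[a], complexities[b])))
            cells.setdefault(key, []).append(d)
    return [
        ComplexityCell(
            k1,
            k2,
            float(np.mean(ds)),
            float(np.mean([d == 1 for d in ds])),
            len(ds),
        )
        for (k1, k2), ds in sorted(cells.items())
    ]


@dataclass
class DistanceDistribution:
    """Histograms of genotype distance D_G stratified by phenotype distance D_P."""

    size: int
    histograms: dict[int, dict[int, int]]  # D_P -> {D_G: count}

    def normalized(self) -> dict[int, dict[int, float]]:
        out: dict[int, dict[int, float]] = {}
        for dp, hist in self.histograms.items():
            total = sum(hist.values())
            out[dp] = {dg: c / total for dg, c in sorted(hist.items())}
        return out

    def mean_dg(self, dp: int) -> float:
        hist = self.histograms.get(dp, {})
        total = sum(hist.values())
        if not total:
            return float("nan")
        return sum(dg * c for dg, c in hist.items()) / total


def genotype_vs_phenotype(
    u,
    panel,
    masks: Sequence[int] | frozenset[int],
    sample: int,
    rng: np.random.Generator,
) -> DistanceDistribution:
    """Joint distribution of D_G and D_P over one size class.

    Samples ``sample`` focal genotypes without replacement from the viable
    size-n set ``masks`` and records, against every member of the set, the
    swap distance D_G and the Hamming distance D_P of the two phenotype
    vectors.  Unordered pairs are counted once; the self pair (0, 0) is
    excluded.
    """
    pool = sorted(masks)
    n_bits = u.N
    sample = min(sample, len(pool))
    focal_idx = sorted(map(int, rng.choice(len(pool), size=sample, replace=False)))
    phen: dict[int, int] = {}

    def phen_mask(mask: int) -> int:
        if mask not in phen:
            phen[mask] = phenotype(u, Genotype(mask, n_bits), panel).mask
        return phen[mask]

    size = pool[0].bit_count() if pool else 0
    hist: dict[int, dict[int, int]] = {}
    seen: set[tuple[int, int]] = set()
    for fi in focal_idx:
        f = pool[fi]
        pf = phen_mask(f)
        for m in pool:
            if m == f:
                continue
            key = (min(f, m), max(f, m))
            if key in seen:
                continue
            seen.add(key)
            dg = (f ^ m).bit_count() // 2
            dp = (pf ^ phen_mask(m)).bit_count()
            hist.setdefault(dp, {})
            hist[dp][dg] = hist[dp].get(dg, 0) + 1
    return DistanceDistribution(size, hist)


def sampled_pair_distances(
    masks: Sequence[int] | frozenset[int],
    n_bits: int,
    n_pairs: int,
    rng: np.random.Generator,
) -> list[int]:
    """Swap distances of uniformly sampled distinct pairs within one set."""
    pool = sorted(masks)
    if len(pool) < 2:
        raise ValueError("need at least two genotypes")
    out = []
    for _ in range(n_pairs):
        i, j = rng.choice(len(pool), size=2, replace=False)
        out.append((pool[int(i)] ^ pool[int(j)]).bit_count() // 2)
    return out


def random_baseline_distance(
    n: int, N: int, n_samples: int, rng: np.random.Generator
) -> tuple[float, float]:
    """Sampled mean and std of the swap distance of two uniform size-n sets."""
    dists = []
    for _ in range(n_samples):
        a = rng.choice(N, size=n, replace=False)
        b = rng.choice(N, size=n, replace=False)
        ga = Genotype.from_bits(map(int, a), N)
        gb = Genotype.from_bits(map(int, b), N)
        dists.append(genotype_distance(ga, gb))
    arr = np.asarray(dists, dtype=float)
    return float(arr.mean()), float(arr.std())


def expected_random_distance(n: int, N: int) -> float:
    """Closed-form mean swap distance of two uniform size-n reaction sets.

    Each present reaction of one genotype is missing from the other with
    probability (N-n)/N, giving n(N-n)/N expected mismatches (= swaps).
    """
    return n * (N - n) / N
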