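"""Neighborhood novelty: which new phenotypes are one reaction change away.

The neighborhood of a metabolism M is the set of genotypes differing from it
in one reaction — a single addition or deletion (``mode="hamming1"``, the
default) or a single same-size swap (``mode="swap"``).  The novelty set
P(M) collects the distinct phenotypes of those neighbors that gain at least
one carbon source M itself cannot grow on.  Two novelty sets are compared
with the dissimilarity statistic

    u(P1, P2) = 1 - |P1 ∩ P2| / (|P1| + |P2| - |P1 ∩ P2|)

(u = 0 for identical non-empty sets, u = 1 for disjoint non-empty sets,
undefined — reported as NaN and counted separately — when both sets are
empty).  Sampling u against the swap distance D between genotype pairs
quantifies how fast the spectrum of accessible innovations turns over
across a genotype network.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .fba import DEFAULT_THRESHOLD, PhenotypeVector, get_context, phenotype
from .genonet import swap_neighbors
from .genotypes import Genotype, genotype_distance
from .universe import EnvironmentPanel, ReactionUniverse

NEIGHBOR_MODES = ("hamming1", "swap")


def u_statistic(p1: frozenset, p2: frozenset) -> float:
    """1 - Jaccard similarity; NaN (undefined) when both sets are empty."""
    union = p1 | p2
    if not union:
        return float("nan")
    return 1.0 - len(p1 & p2) / len(union)


def hamming1_neighbors(g: Genotype) -> Iterable[Genotype]:
    """All genotypes differing from g by one addition or one deletion."""
    for i in range(g.n_bits):
        yield Genotype(g.mask ^ (1 << i), g.n_bits)


def viability_profile(
    u: ReactionUniverse,
    g: Genotype,
    panel: EnvironmentPanel,
    threshold_fraction: float = DEFAULT_THRESHOLD,
) -> frozenset[str]:
    """Names of panel sources the genotype is viable on."""
    return frozenset(
        e.name for e in panel if get_context(u, e, threshold_fraction).viable(g.mask)
    )


@dataclass(frozen=True)
class NeighborhoodSummary:
    """Novel phenotypes accessible in the 1-neighborhood of a genotype."""

    genotype: Genotype
    focal_phenotype: PhenotypeVector
    novel_phenotypes: frozenset[PhenotypeVector]
    n_neighbors: int
    mode: str

    @property
    def novel_count(self) -> int:
        return len(self.novel_phenotypes)


def novel_phenotypes(
    u: ReactionUniverse,
    g: Genotype,
    panel: EnvironmentPanel,
    mode: str = "hamming1",
    threshold_fraction: float = DEFAULT_THRESHOLD,
) -> NeighborhoodSummary:
    """Distinct neighbor phenotypes that strictly gain >= 1 carbon source.

    The focal genotype must be viable on at least one panel source.  A
    neighbor phenotype is novel when it sets at least one bit the focal
    phenotype lacks.
    """
    if mode not in NEIGHBOR_MODES:
        raise ValueError(f"unknown neighborhood mode {mode!r}")
    focal = phenotype(u, g, panel, threshold_fraction)
    if focal.k == 0:
        raise ValueError("focal genotype is viable on no panel source")
    neighbors = (
        hamming1_neighbors(g) if mode == "hamming1" else swap_neighbors(g)
    )
    novel: set[PhenotypeVector] = set()
    n_neighbors = 0
    for nb in neighbors:
        n_neighbors += 1
        p = phenotype(u, nb, panel, threshold_fraction)
        if p.mask & ~focal.mask:
            novel.add(p)
    return NeighborhoodSummary(g, focal, frozenset(novel), n_neighbors, mode)


@dataclass(frozen=True)
class PairDiversity:
    """u statistic of one genotype pair at swap distance D."""

    u: float  # NaN when both novelty sets are empty
    distance: int
    size: int

    @property
    def defined(self) -> bool:
        return self.u == self.u  # not NaN


def pair_diversity(s1: NeighborhoodSummary, s2: NeighborhoodSummary) -> PairDiversity:
    """Jaccard-complement diversity of two neighborhoods from one network."""
    if s1.mode != s2.mode:
        raise ValueError("summaries use different neighborhood modes")
    d = genotype_distance(s1.genotype, s2.genotype)
    return PairDiversity(
        u_statistic(s1.novel_phenotypes, s2.novel_phenotypes), d, s1.genotype.size
    )


def sample_pairs_at_distance(
    masks: Sequence[int] | frozenset[int],
    n_bits: int,
    distance: int,
    count: int,
    rng: np.random.Generator,
    max_tries: int = 100_000,
) -> list[tuple[int, int]]:
    """Seeded uniform sample of member pairs at exactly the given swap distance.

    Rejection sampling over uniform pairs; returns fewer than ``count`` pairs
    (possibly none) when the distance class is absent or too rare.
    """
    pool = sorted(masks)
    if len(pool) < 2:
        raise ValueError("need at least two genotypes to sample pairs")
    out: list[tuple[int, int]] = []
    tries = 0
    while len(out) < count and tries < max_tries:
        tries += 1
        i, j = rng.choice(len(pool), size=2, replace=False)
        a, b = pool[int(i)], pool[int(j)]
        if (a ^ b).bit_count() // 2 == distance:
            out.append((a, b))
    return out


@dataclass(frozen=True)
class DiversityPoint:
    """One row of a diversity curve: mean u at a given (n, D)."""

    size: int
    distance: int
    mean_u: float
    n_pairs: int
    n_undefined: int


def diversity_curve(
    u: ReactionUniverse,
    masks: Sequence[int] | frozenset[int],
    panel: EnvironmentPanel,
    distances: Iterable[int],
    pairs_per_distance: int,
    rng: np.random.Generator,
    mode: str = "hamming1",
    threshold_fraction: float = DEFAULT_THRESHOLD,
) -> list[DiversityPoint]:
    """Mean neighborhood diversity u as a function of genotype distance D.

    ``masks`` are equal-size genotypes from one network.  Pairs with both
    novelty sets empty are excluded from the mean and counted as undefined.
    Novelty sets are cached per genotype across pairs.
    """
    n_bits = u.N
    cache: dict[int, NeighborhoodSummary] = {}

    def summary(mask: int) -> NeighborhoodSummary:
        if mask not in cache:
            cache[mask] = novel_phenotypes(
                u, Genotype(mask, n_bits), panel, mode, threshold_fraction
            )
        return cache[mask]

    size = next(iter(masks)).bit_count() if masks else 0
    out: list[DiversityPoint] = []
    for d in distances:
        pairs = sample_pairs_at_distance(masks, n_bits, d, pairs_per_distance, rng)
        us = [pair_diversity(summary(a), summary(b)).u for a, b in pairs]
        defined = [x for x in us if x == x]
        mean_u = float(np.mean(defined)) if defined else float("nan")
        out.append(DiversityPoint(size, d, mean_u, len(defined), len(us) - len(defined)))
    return out


def mean_u_by_distance(
    pairs: Iterable[PairDiversity],
) -> dict[int, tuple[float, int, int]]:
    """Per-distance (mean u over defined pairs, defined count, undefined count)."""
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    undef: dict[int, int] = {}
    for p in pairs:
        if p.defined:
            sums[p.distance] = sums.get(p.distance, 0.0) + p.u
            counts[p.distance] = counts.get(p.distance, 0) + 1
        else:
            undef[p.distance] = undef.get(p.distance, 0) + 1
    return {
        d: (sums.get(d, float("nan")) / counts[d] if counts.get(d) else float("nan"),
            counts.get(d, 0), undef.get(d, 0))
        for d in sorted(set(counts) | set(undef))
    }


def u_distance_correlation(points: Sequence[DiversityPoint]) -> float:
    """Spearman rank correlation between D and mean u over curve points."""
    from scipy.stats import spearmanr

    pts = [p for p in points if p.mean_u == p.mean_u]
    d = [p.distance for p in pts]
    uu = [p.mean_u for p in pts]
    if len(set(d)) < 2 or len(set(uu)) < 2:
        return float("nan")
    return float(spearmanr(d, uu).statistic)


def randomization_null(
    summaries: Sequence[NeighborhoodSummary],
    phenotype_pool: Sequence[PhenotypeVector],
    stat: str = "novel_count",
    reps: int = 100,
    rng: np.random.Generator | None = None,
) -> tuple[float, np.ndarray, float]:
    """Randomization test for neighborhood statistics.

    The null redraws, for each focal metabolism, a surrogate neighborhood of
    the same size whose phenotypes are sampled uniformly from the empirical
    phenotype distribution (``phenotype_pool``, with multiplicities) of
    genotypes of the same size class; the surrogate novelty set keeps
    distinct phenotypes strictly gaining a source over the focal phenotype.

    ``stat`` is ``"novel_count"`` (mean |P(M)| over focals) or ``"u"`` (mean
    defined u over all focal pairs).  Returns (observed, null draws,
    empirical p = fraction of null draws >= observed); p is NaN when the
    phenotype pool is degenerate (fewer than two distinct phenotypes).
    """
    if reps <= 0:
        raise ValueError("reps must be positive")
    if not summaries:
        raise ValueError("no neighborhood summaries given")
    if stat not in ("novel_count", "u"):
        raise ValueError(f"unknown statistic {stat!r}")
    rng = np.random.default_rng(0) if rng is None else rng
    pool = list(phenotype_pool)

    def score(novel_sets: Sequence[frozenset[PhenotypeVector]]) -> float:
        if stat == "novel_count":
            return float(np.mean([len(p) for p in novel_sets]))
        us = [
            u_statistic(novel_sets[i], novel_sets[j])
            for i in range(len(novel_sets))
            for j in range(i + 1, len(novel_sets))
        ]
        defined = [x for x in us if x == x]
        return float(np.mean(defined)) if defined else float("nan")

    observed = score([s.novel_phenotypes for s in summaries])
    null = np.empty(reps)
    for r in range(reps):
        surrogate: list[frozenset[PhenotypeVector]] = []
        for s in summaries:
            draw = rng.choice(len(pool), size=s.n_neighbors, replace=True)
            surrogate.append(
                frozenset(
                    pool[int(k)]
                    for k in draw
                    if pool[int(k)].mask & ~s.focal_phenotype.mask
                )
            )
        null[r] = score(surrogate)
    if len(set(pool)) < 2:
        return observed, null, float("nan")
    p = float(np.mean(null >= observed))
    return observed, null, p
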