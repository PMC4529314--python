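"""Viability phenotyping by flux balance analysis.

A genotype is *viable* in an environment when the FBA optimum of the biomass
reaction, with all absent internal reactions constrained to zero flux,
strictly exceeds a fixed fraction (default 1%) of the biomass rate of the
complete universe (all N internal reactions present) in the same
environment.  The LP is

    max  c^T v   s.t.  S v = 0,  a <= v <= b

solved with the HiGHS solver through :func:`scipy.optimize.linprog`.
Structural diagnostics (essential, blocked, disconnected reactions) and the
minimal viable network size (a mixed-integer program) live here as well.

Reaction *indices* in this module are genotype bit positions, i.e. indices
into ``universe.internal_reaction_ids``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

from .genotypes import Genotype
from .universe import Environment, EnvironmentPanel, ReactionUniverse, environment_bounds

DEFAULT_THRESHOLD = 0.01
FLUX_EPS = 1e-6


class SolverError(RuntimeError):
    """The LP/MILP solver returned an unexpected status."""


@dataclass(frozen=True)
class ViabilityResult:
    biomass_rate: float
    viable: bool
    reference_rate: float
    threshold_fraction: float


@dataclass(frozen=True)
class PhenotypeVector:
    """Per-environment viability bits; popcount is the complexity k."""

    mask: int
    n_bits: int

    @property
    def k(self) -> int:
        return self.mask.bit_count()

    def viable_on(self, i: int) -> bool:
        return bool(self.mask >> i & 1)

    def bits(self) -> tuple[int, ...]:
        return tuple((self.mask >> i) & 1 for i in range(self.n_bits))

    def gains_over(self, other: "PhenotypeVector") -> int:
        """Number of environments viable here but not in ``other``."""
        return (self.mask & ~other.mask).bit_count()


class _EnvContext:
    """Cached LP skeleton and viability memo for one (universe, environment)."""

    def __init__(self, u: ReactionUniverse, e: Environment, threshold: float):
        self.universe = u
        self.environment = e
        self.threshold_fraction = threshold
        lb, ub = environment_bounds(u, e)
        self.lb = lb
        self.ub = ub
        self.S = u.stoich.tocsc()
        self.c = np.zeros(u.n_reactions)
        self.c[u.biomass_idx] = -1.0  # linprog minimizes
        self.internal_idx = u.internal_idx
        self.lp_calls = 0
        self._memo: dict[int, float] = {}
        self.reference_rate = self.optimum(Genotype.full(u.N).mask)

    def optimum(self, mask: int) -> float:
        """Maximal biomass rate for the genotype given as a bit mask."""
        cached = self._memo.get(mask)
        if cached is not None:
            return cached
        lb = self.lb.copy()
        ub = self.ub.copy()
        absent = [
            j
            for i, j in enumerate(self.internal_idx)
            if not (mask >> i) & 1
        ]
        if absent:
            lb[absent] = 0.0
            ub[absent] = 0.0
        res = linprog(
            self.c,
            A_eq=self.S,
            b_eq=np.zeros(self.S.shape[0]),
            bounds=np.column_stack([lb, ub]),
            method="highs",
        )
        self.lp_calls += 1
        if res.status == 2:  # infeasible: report biomass 0, not an exception
            rate = 0.0
        elif res.status == 0:
            rate = max(0.0, -res.fun)
        else:
            raise SolverError(f"LP solver status {res.status}: {res.message}")
        self._memo[mask] = rate
        return rate

    def viable(self, mask: int) -> bool:
        return self.optimum(mask) > self.threshold_fraction * self.reference_rate


def get_context(
    u: ReactionUniverse,
    e: Environment,
    threshold_fraction: float = DEFAULT_THRESHOLD,
) -> _EnvContext:
    cache = getattr(u, "_fba_contexts", None)
    if cache is None:
        cache = {}
        u._fba_contexts = cache
    key = (
        e.name,
        e.carbon_source,
        tuple(sorted(e.uptake_bounds.items())),
        threshold_fraction,
    )
    ctx = cache.get(key)
    if ctx is None:
        ctx = _EnvContext(u, e, threshold_fraction)
        cache[key] = ctx
    return ctx


def solve_fba(
    u: ReactionUniverse,
    g: Genotype,
    e: Environment,
    threshold_fraction: float = DEFAULT_THRESHOLD,
) -> ViabilityResult:
    """Biomass optimum and viability of one genotype in one environment."""
    if g.n_bits != u.N:
        raise ValueError(f"genotype length {g.n_bits} != universe N {u.N}")
    ctx = get_context(u, e, threshold_fraction)
    rate = ctx.optimum(g.mask)
    return ViabilityResult(
        biomass_rate=rate,
        viable=rate > threshold_fraction * ctx.reference_rate,
        reference_rate=ctx.reference_rate,
        threshold_fraction=threshold_fraction,
    )


def phenotype(
    u: ReactionUniverse,
    g: Genotype,
    panel: EnvironmentPanel,
    threshold_fraction: float = DEFAULT_THRESHOLD,
) -> PhenotypeVector:
    """Per-environment viability bits in panel order."""
    mask = 0
    for i, e in enumerate(panel):
        if solve_fba(u, g, e, threshold_fraction).viable:
            mask |= 1 << i
    return PhenotypeVector(mask, len(panel))


def essential_reactions(
    u: ReactionUniverse,
    panel: EnvironmentPanel,
    threshold_fraction: float = DEFAULT_THRESHOLD,
) -> set[int]:
    """Bit positions whose single deletion abolishes viability in *every*
    environment of the panel (always-essential reactions)."""
    full = Genotype.full(u.N)
    for e in panel:
        if not solve_fba(u, full, e, threshold_fraction).viable:
            raise ValueError(
                f"complete universe is inviable in environment {e.name!r}"
            )
    essential = set()
    for i in range(u.N):
        g = full.without_bit(i)
        if all(
            not solve_fba(u, g, e, threshold_fraction).viable for e in panel
        ):
            essential.add(i)
    return essential


def blocked_reactions(
    u: ReactionUniverse,
    g: Genotype,
    e: Environment,
    eps: float = FLUX_EPS,
    require_biomass: bool = False,
    threshold_fraction: float = DEFAULT_THRESHOLD,
) -> set[int]:
    """Present reactions forced to zero flux by stoichiometry.

    Flux variability analysis with no objective: reaction ``i`` is blocked
    when both its maximal and minimal feasible flux under ``S v = 0`` and the
    genotype/environment bounds lie within ``±eps`` of zero.  With
    ``require_biomass=True`` the feasible set is additionally constrained to
    biomass above the viability threshold.
    """
    ctx = get_context(u, e, threshold_fraction)
    lb = ctx.lb.copy()
    ub = ctx.ub.copy()
    for i, j in enumerate(u.internal_idx):
        if not g.has(i):
            lb[j] = 0.0
            ub[j] = 0.0
    if require_biomass:
        lb[u.biomass_idx] = max(
            lb[u.biomass_idx], threshold_fraction * ctx.reference_rate
        )
    bounds = np.column_stack([lb, ub])
    b_eq = np.zeros(u.stoich.shape[0])
    nonzero_seen: set[int] = set()
    blocked: set[int] = set()
    for i, j in enumerate(u.internal_idx):
        if not g.has(i):
            continue
        if i in nonzero_seen:
            continue
        extreme = 0.0
        for sense in (-1.0, 1.0):
            c = np.zeros(u.n_reactions)
            c[j] = sense
            res = linprog(c, A_eq=u.stoich, b_eq=b_eq, bounds=bounds, method="highs")
            ctx.lp_calls += 1
            if res.status == 2:
                continue  # infeasible system: all fluxes vacuously blocked
            if res.status != 0:
                raise SolverError(f"FVA solver status {res.status}: {res.message}")
            extreme = max(extreme, abs(res.x[j]))
            # any reaction with visibly nonzero flux in this vertex is unblocked
            for i2, j2 in enumerate(u.internal_idx):
                if g.has(i2) and abs(res.x[j2]) > eps:
                    nonzero_seen.add(i2)
        if extreme <= eps:
            blocked.add(i)
    return blocked


def _direction_sets(
    coeffs: dict[str, float], reversible: bool
) -> list[tuple[set[str], set[str]]]:
    subs = {m for m, c in coeffs.items() if c < 0}
    prods = {m for m, c in coeffs.items() if c > 0}
    orientations = [(subs, prods)]
    if reversible:
        orientations.append((prods, subs))
    return orientations


def disconnected_reactions(
    u: ReactionUniverse, g: Genotype, e: Environment, iterate: bool = False
) -> set[int]:
    """Purely topological test for reactions disconnected from a metabolism.

    A present reaction is disconnected when, for every orientation it can
    operate in, (i) none of its products is a biomass precursor or a
    substrate of another reaction of the resident metabolism (present
    internal reactions plus the always-present transporters), or (ii) at
    least one of its substrates is neither a product of other resident
    reactions nor a nutrient taken up from the environment.  By default the
    test is applied in a single pass against the full resident reaction set;
    ``iterate=True`` instead removes disconnected reactions and re-applies
    the test to a fixed point (a reaction can become disconnected once
    another disconnected one is gone), returning the cumulative set.
    """
    if iterate:
        total: set[int] = set()
        current = g
        while True:
            found = disconnected_reactions(u, current, e, iterate=False)
            if not found:
                return total
            total |= found
            for i in found:
                current = current.without_bit(i)
    precursors = set(u.precursor_ids)
    external: set[str] = set()
    nutrients: set[str] = set()
    for j in u.exchange_idx:
        rid = u.reaction_ids[j]
        external.update(u.reaction_coeffs(j))
        if e.uptake_bounds.get(rid, 0.0) > 0:
            nutrients.update(u.reaction_coeffs(j))
    resident: list[int] = [int(j) for j in u.transport_idx]
    present_internal = [(i, int(j)) for i, j in enumerate(u.internal_idx) if g.has(i)]
    resident += [j for _, j in present_internal]

    consumed_by: dict[int, set[str]] = {}
    produced_by: dict[int, set[str]] = {}
    for j in resident:
        coeffs = u.reaction_coeffs(j)
        orients = _direction_sets(coeffs, bool(u.reversible[j]))
        consumed_by[j] = set().union(*(s for s, _ in orients))
        # an orientation fed by an external metabolite the environment does
        # not supply cannot run, so its products are not actually produced
        produced_by[j] = set().union(
            *(
                p
                for s, p in orients
                if not any(m in external and m not in nutrients for m in s)
            ),
            set(),
        )

    disconnected: set[int] = set()
    for i, j in present_internal:
        consumed_others: set[str] = set()
        produced_others: set[str] = set()
        for j2 in resident:
            if j2 == j:
                continue
            consumed_others |= consumed_by[j2]
            produced_others |= produced_by[j2]
        coeffs = u.reaction_coeffs(j)
        is_disc = True
        for subs, prods in _direction_sets(coeffs, bool(u.reversible[j])):
            dead_products = all(
                m not in precursors and m not in consumed_others for m in prods
            )
            missing_substrate = any(
                m not in produced_others and m not in nutrients for m in subs
            )
            if not (dead_products or missing_substrate):
                is_disc = False
                break
        if is_disc:
            disconnected.add(i)
    return disconnected


def greedy_minimal_network(
    u: ReactionUniverse,
    environments: Sequence[Environment],
    threshold_fraction: float = DEFAULT_THRESHOLD,
) -> Genotype:
    """Irreducible viable network by greedy single-reaction deletion.

    Upper bound for :func:`minimal_viable_size`; deterministic (bits tried
    in ascending order).
    """
    g = Genotype.full(u.N)
    for i in range(u.N):
        trial = g.without_bit(i)
        if all(
            solve_fba(u, trial, e, threshold_fraction).viable for e in environments
        ):
            g = trial
    return g


def minimal_viable_size(
    u: ReactionUniverse,
    environments: Sequence[Environment] | EnvironmentPanel,
    threshold_fraction: float = DEFAULT_THRESHOLD,
    margin: float = 1e-4,
    time_limit: float | None = 600.0,
    warm_start: bool = True,
) -> tuple[int, Genotype]:
    """Smallest viable network size over a set of required environments.

    Mixed-integer program: binary presence variables y over internal
    reactions, one flux vector per environment coupled by
    ``lb_i * y_i <= v_i <= ub_i * y_i`` (the big-M is each reaction's own
    bound), biomass constrained to at least ``(threshold + margin) * ref``
    per environment, objective ``min sum(y)``.  The small ``margin`` keeps
    numerically degenerate solutions that sit exactly on the strict
    viability threshold out of the feasible set.  The witness is re-verified
    with the plain LP criterion before it is returned.
    """
    envs = list(environments)
    if not envs:
        raise ValueError("at least one environment is required")
    contexts = [get_context(u, e, threshold_fraction) for e in envs]
    for ctx in contexts:
        if ctx.reference_rate <= 0:
            raise ValueError(
                f"complete universe inviable in {ctx.environment.name!r}"
            )
    nE, nr, nI = len(envs), u.n_reactions, u.N
    nvar = nE * nr + nI
    c = np.zeros(nvar)
    c[nE * nr :] = 1.0
    integrality = np.zeros(nvar)
    integrality[nE * nr :] = 1.0
    lo = np.zeros(nvar)
    hi = np.ones(nvar)
    blocks = []
    con_lo: list[float] = []
    con_hi: list[float] = []
    m = u.stoich.shape[0]
    for e_i, ctx in enumerate(contexts):
        left = sparse.csc_matrix((m, e_i * nr))
        right = sparse.csc_matrix((m, (nE - 1 - e_i) * nr + nI))
        blocks.append(sparse.hstack([left, u.stoich, right]))
        con_lo += [0.0] * m
        con_hi += [0.0] * m
        lo[e_i * nr : (e_i + 1) * nr] = ctx.lb
        hi[e_i * nr : (e_i + 1) * nr] = ctx.ub
        data, rows, cols = [], [], []
        for k, j in enumerate(u.internal_idx):
            rows += [2 * k, 2 * k, 2 * k + 1, 2 * k + 1]
            cols += [e_i * nr + j, nE * nr + k, e_i * nr + j, nE * nr + k]
            data += [1.0, -ctx.ub[j], 1.0, -ctx.lb[j]]
        blocks.append(sparse.csc_matrix((data, (rows, cols)), shape=(2 * nI, nvar)))
        for _ in range(nI):
            con_lo += [-np.inf, 0.0]
            con_hi += [0.0, np.inf]
        lo[e_i * nr + u.biomass_idx] = (threshold_fraction + margin) * ctx.reference_rate
    constraints = [LinearConstraint(sparse.vstack(blocks), con_lo, con_hi)]
    if warm_start:
        ub_genotype = greedy_minimal_network(u, envs, threshold_fraction)
        size_cap = sparse.csc_matrix(
            (np.ones(nI), (np.zeros(nI, dtype=int), np.arange(nE * nr, nvar))),
            shape=(1, nvar),
        )
        constraints.append(LinearConstraint(size_cap, 0, ub_genotype.size))
    options = {} if time_limit is None else {"time_limit": time_limit}
    res = milp(
        c,
        constraints=constraints,
        integrality=integrality,
        bounds=Bounds(lo, hi),
        options=options,
    )
    if res.status != 0:
        raise SolverError(
            f"MILP did not reach optimality (status {res.status}: {res.message}; "
            f"best objective {res.fun})"
        )
    y = res.x[nE * nr :]
    witness = Genotype.from_bits([k for k in range(nI) if y[k] > 0.5], nI)
    for e in envs:
        if not solve_fba(u, witness, e, threshold_fraction).viable:
            raise SolverError(
                "MILP witness failed strict LP re-verification; "
                "increase the threshold margin"
            )
    return witness.size, witness


def viable_under(
    u: ReactionUniverse,
    g: Genotype,
    environments: Iterable[Environment],
    threshold_fraction: float = DEFAULT_THRESHOLD,
) -> bool:
    """Viability on every environment given, with short-circuiting."""
    return all(
        solve_fba(u, g, e, threshold_fraction).viable for e in environments
    )
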