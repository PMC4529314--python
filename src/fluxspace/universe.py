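"""Reaction universes, growth environments, and the tabular model format.

A *reaction universe* is a stoichiometric model partitioned into

* ``internal`` reactions — the N variable reactions whose presence/absence
  defines a metabolic genotype,
* ``transport`` reactions — always present, moving nutrients and waste
  across the boundary,
* ``exchange`` reactions — pseudo-reactions that connect external
  metabolites to the environment (uptake is a negative exchange flux),
* one ``biomass`` reaction — the FBA objective, draining the biomass
  precursor metabolites.

Models are serialized as a TSV dialect with one reaction per row
(``id  equation  reversible  lb  ub  class``) preceded by ``#!`` directive
lines declaring metabolites, biomass precursors and co-factor reaction
pairs.  Equations use plain text arrows, e.g. ``2 A + B -> C`` or
``A <-> B``; an empty side is allowed (drains such as the biomass reaction,
and exchange reactions written as ``A_e ->``).
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import sparse

REACTION_CLASSES = ("internal", "transport", "exchange", "biomass")


class ModelFormatError(ValueError):
    """Raised when a model or environment file fails validation."""


@dataclass(frozen=True)
class ReactionRow:
    """One reaction as written in the tabular format."""

    rid: str
    coeffs: Mapping[str, float]  # metabolite -> signed coefficient
    reversible: bool
    lb: float
    ub: float
    cls: str


@dataclass(eq=False)
class ReactionUniverse:
    """Stoichiometric model with an internal/transport partition.

    The order of ``internal_idx`` defines genotype bit positions: bit ``i``
    of a :class:`~fluxspace.genotypes.Genotype` refers to reaction
    ``reaction_ids[internal_idx[i]]``.
    """

    metabolite_ids: tuple[str, ...]
    reaction_ids: tuple[str, ...]
    stoich: sparse.csc_matrix
    lb: np.ndarray
    ub: np.ndarray
    reversible: np.ndarray
    classes: tuple[str, ...]
    precursor_ids: tuple[str, ...]
    cofactor_pairs: tuple[tuple[str, str], ...] = ()
    meta: dict = field(default_factory=dict)

    # ---- derived indexing -------------------------------------------------
    def __post_init__(self) -> None:
        self._ridx = {r: i for i, r in enumerate(self.reaction_ids)}
        self._midx = {m: i for i, m in enumerate(self.metabolite_ids)}
        self.internal_idx = np.array(
            [i for i, c in enumerate(self.classes) if c == "internal"], dtype=int
        )
        self.transport_idx = np.array(
            [i for i, c in enumerate(self.classes) if c == "transport"], dtype=int
        )
        self.exchange_idx = np.array(
            [i for i, c in enumerate(self.classes) if c == "exchange"], dtype=int
        )
        bm = [i for i, c in enumerate(self.classes) if c == "biomass"]
        if len(bm) != 1:
            raise ModelFormatError(
                f"expected exactly one biomass reaction, found {len(bm)}"
            )
        self.biomass_idx = bm[0]
        self.validate()

    @property
    def N(self) -> int:
        """Number of variable internal reactions (genotype length)."""
        return len(self.internal_idx)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    @property
    def internal_reaction_ids(self) -> tuple[str, ...]:
        return tuple(self.reaction_ids[i] for i in self.internal_idx)

    @property
    def objective(self) -> np.ndarray:
        """Objective coefficient vector c selecting the biomass reaction."""
        c = np.zeros(self.n_reactions)
        c[self.biomass_idx] = 1.0
        return c

    def reaction_index(self, rid: str) -> int:
        try:
            return self._ridx[rid]
        except KeyError:
            raise KeyError(f"unknown reaction id {rid!r}") from None

    def internal_bit(self, rid: str) -> int:
        """Genotype bit position of an internal reaction id."""
        j = self.reaction_index(rid)
        pos = np.searchsorted(self.internal_idx, j)
        if pos >= self.N or self.internal_idx[pos] != j:
            raise KeyError(f"reaction {rid!r} is not internal")
        return int(pos)

    def reaction_coeffs(self, j: int) -> dict[str, float]:
        col = self.stoich.getcol(j).tocoo()
        return {self.metabolite_ids[i]: float(v) for i, v in zip(col.row, col.data)}

    # ---- validation -------------------------------------------------------
    def validate(self) -> None:
        if len(set(self.reaction_ids)) != len(self.reaction_ids):
            raise ModelFormatError("duplicate reaction identifiers")
        if len(set(self.metabolite_ids)) != len(self.metabolite_ids):
            raise ModelFormatError("duplicate metabolite identifiers")
        if np.any(self.lb > self.ub):
            bad = self.reaction_ids[int(np.argmax(self.lb > self.ub))]
            raise ModelFormatError(f"reaction {bad!r} has lb > ub")
        counts = np.diff(self.stoich.tocsc().indptr)
        if np.any(counts == 0):
            bad = self.reaction_ids[int(np.argmax(counts == 0))]
            raise ModelFormatError(f"reaction {bad!r} has an empty column in S")
        bm_col = self.reaction_coeffs(self.biomass_idx)
        for p in self.precursor_ids:
            if p not in self._midx:
                raise ModelFormatError(f"precursor {p!r} is not a metabolite")
            if bm_col.get(p, 0.0) >= 0:
                raise ModelFormatError(
                    f"precursor {p!r} is not consumed by the biomass reaction"
                )
        for a, b in self.cofactor_pairs:
            for rid in (a, b):
                if rid not in self._ridx:
                    raise ModelFormatError(f"co-factor pair names unknown reaction {rid!r}")

    # ---- provenance -------------------------------------------------------
    def model_hash(self) -> str:
        h = hashlib.sha256()
        h.update(repr(self.metabolite_ids).encode())
        h.update(repr(self.reaction_ids).encode())
        h.update(repr(self.classes).encode())
        coo = self.stoich.tocoo()
        h.update(np.asarray(coo.row).tobytes())
        h.update(np.asarray(coo.col).tobytes())
        h.update(np.asarray(coo.data, dtype=float).tobytes())
        h.update(np.asarray(self.lb, dtype=float).tobytes())
        h.update(np.asarray(self.ub, dtype=float).tobytes())
        return h.hexdigest()[:16]


@dataclass(frozen=True)
class Environment:
    """A minimal growth environment with a sole carbon source.

    ``uptake_bounds`` maps exchange reaction ids to the maximal uptake rate
    (a positive magnitude; applied as a negative lower bound on the exchange
    flux).  Exchanges not listed are closed for uptake.
    """

    name: str
    carbon_source: str
    uptake_bounds: Mapping[str, float]

    @property
    def open_exchanges(self) -> frozenset[str]:
        return frozenset(k for k, v in self.uptake_bounds.items() if v > 0)


class EnvironmentPanel(Sequence):
    """Ordered, immutable list of environments; phenotype bit i = panel[i]."""

    def __init__(self, environments: Iterable[Environment]):
        envs = tuple(environments)
        names = [e.name for e in envs]
        if len(set(names)) != len(names):
            raise ModelFormatError("duplicate environment names in panel")
        self._envs = envs

    def __getitem__(self, i):
        return self._envs[i]

    def __len__(self) -> int:
        return len(self._envs)

    def __iter__(self):
        return iter(self._envs)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(e.name for e in self._envs)

    def index_of(self, name: str) -> int:
        return self.names.index(name)

    def subset(self, names: Iterable[str]) -> "EnvironmentPanel":
        by_name = {e.name: e for e in self._envs}
        return EnvironmentPanel(by_name[n] for n in names)


def environment_bounds(
    u: ReactionUniverse, e: Environment
) -> tuple[np.ndarray, np.ndarray]:
    """Flux bounds with environment-specific exchange constraints applied."""
    lb = u.lb.copy()
    ub = u.ub.copy()
    for j in u.exchange_idx:
        rid = u.reaction_ids[j]
        lb[j] = -float(e.uptake_bounds.get(rid, 0.0))
    return lb, ub


# ---------------------------------------------------------------------------
# equation strings
# ---------------------------------------------------------------------------

_TERM_RE = re.compile(r"^(?:(\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)\s+)?(\S+)$")


def parse_equation(eq: str) -> tuple[dict[str, float], bool]:
    """Parse ``"2 A + B -> C"`` into signed coefficients and reversibility."""
    if "<->" in eq:
        left, right = eq.split("<->", 1)
        reversible = True
    elif "->" in eq:
        left, right = eq.split("->", 1)
        reversible = False
    else:
        raise ModelFormatError(f"equation {eq!r} lacks an arrow")
    coeffs: dict[str, float] = {}

    def add_side(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split("+"):
            term = term.strip()
            mobj = _TERM_RE.match(term)
            if not mobj:
                raise ModelFormatError(f"malformed term {term!r} in {eq!r}")
            coef = float(mobj.group(1)) if mobj.group(1) else 1.0
            met = mobj.group(2)
            coeffs[met] = coeffs.get(met, 0.0) + sign * coef

    add_side(left, -1.0)
    add_side(right, +1.0)
    coeffs = {m: c for m, c in coeffs.items() if c != 0.0}
    if not coeffs:
        raise ModelFormatError(f"equation {eq!r} has zero net stoichiometry")
    return coeffs, reversible


def format_equation(coeffs: Mapping[str, float]) -> str:
    def fmt(c: float) -> str:
        if c == int(c):
            c = int(c)
            return "" if c == 1 else f"{c} "
        return f"{c!r} "

    lhs = " + ".join(f"{fmt(-c)}{m}" for m, c in coeffs.items() if c < 0)
    rhs = " + ".join(f"{fmt(c)}{m}" for m, c in coeffs.items() if c > 0)
    return f"{lhs} -> {rhs}".strip()


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def build_universe(
    rows: Sequence[ReactionRow],
    metabolite_ids: Sequence[str],
    precursor_ids: Sequence[str],
    cofactor_pairs: Sequence[tuple[str, str]] = (),
    meta: dict | None = None,
) -> ReactionUniverse:
    """Assemble a validated universe from parsed reaction rows.

    Sign convention: consumption negative, production positive; S has one
    column per reaction in row order.
    """
    mset = set(metabolite_ids)
    data, ridx, cidx = [], [], []
    midx = {m: i for i, m in enumerate(metabolite_ids)}
    for j, row in enumerate(rows):
        if row.cls not in REACTION_CLASSES:
            raise ModelFormatError(
                f"reaction {row.rid!r} has unknown class {row.cls!r}"
            )
        for met, c in row.coeffs.items():
            if met not in mset:
                raise ModelFormatError(
                    f"reaction {row.rid!r} names undeclared metabolite {met!r}"
                )
            data.append(c)
            ridx.append(midx[met])
            cidx.append(j)
        if not row.reversible and row.cls != "exchange" and row.lb < 0:
            raise ModelFormatError(
                f"irreversible reaction {row.rid!r} has negative lower bound"
            )
    S = sparse.csc_matrix(
        (data, (ridx, cidx)), shape=(len(metabolite_ids), len(rows))
    )
    return ReactionUniverse(
        metabolite_ids=tuple(metabolite_ids),
        reaction_ids=tuple(r.rid for r in rows),
        stoich=S,
        lb=np.array([r.lb for r in rows], dtype=float),
        ub=np.array([r.ub for r in rows], dtype=float),
        reversible=np.array([r.reversible for r in rows], dtype=bool),
        classes=tuple(r.cls for r in rows),
        precursor_ids=tuple(precursor_ids),
        cofactor_pairs=tuple(tuple(p) for p in cofactor_pairs),
        meta=dict(meta or {}),
    )


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

def load_universe(path: str | Path, format: str = "tabular") -> ReactionUniverse:
    """Load a reaction universe from disk.

    ``format="tabular"`` reads the TSV dialect documented in this module;
    ``format="sbml"`` reads an SBML file through cobrapy (reaction classes
    are then inferred: boundary reactions become exchanges, reactions that
    touch external metabolites become transports, the objective becomes the
    biomass reaction).
    """
    if format == "sbml":
        return _load_sbml(path)
    if format != "tabular":
        raise ValueError(f"unknown model format {format!r}")
    path = Path(path)
    metabolites: list[str] = []
    precursors: list[str] = []
    pairs: list[tuple[str, str]] = []
    meta: dict = {}
    rows: list[ReactionRow] = []
    header_seen = False
    for lineno, raw in enumerate(path.read_text().splitlines(), 1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#!"):
            body = line[2:].strip()
            key, _, value = body.partition(":")
            key = key.strip()
            value = value.strip()
            if key == "metabolites":
                metabolites.extend(value.split())
            elif key == "precursors":
                precursors.extend(value.split())
            elif key == "cofactor_pair":
                a_b = value.split()
                if len(a_b) != 2:
                    raise ModelFormatError(
                        f"{path}:{lineno}: cofactor_pair needs two reaction ids"
                    )
                pairs.append((a_b[0], a_b[1]))
            elif key == "meta":
                k, _, v = value.partition("=")
                meta[k.strip()] = v.strip()
            else:
                raise ModelFormatError(f"{path}:{lineno}: unknown directive {key!r}")
            continue
        if line.startswith("#"):
            continue
        fields = line.split("\t")
        if fields[0] == "id":
            header_seen = True
            continue
        if len(fields) != 6:
            raise ModelFormatError(
                f"{path}:{lineno}: expected 6 tab-separated fields, got {len(fields)}"
            )
        rid, eq, rev, lb, ub, cls = fields
        coeffs, rev_eq = parse_equation(eq)
        reversible = rev.strip() in ("1", "true", "True")
        if reversible != rev_eq:
            raise ModelFormatError(
                f"{path}:{lineno}: reversible flag contradicts arrow in {rid!r}"
            )
        rows.append(
            ReactionRow(rid.strip(), coeffs, reversible, float(lb), float(ub), cls.strip())
        )
    del header_seen
    if not rows:
        raise ModelFormatError(f"{path}: no reactions found")
    return build_universe(rows, metabolites, precursors, pairs, meta)


def save_universe(u: ReactionUniverse, path: str | Path) -> None:
    """Write a universe in the tabular dialect; round-trips exactly."""
    path = Path(path)
    lines = [f"#! meta: model_hash={u.model_hash()}"]
    for k, v in u.meta.items():
        if k != "model_hash":
            lines.append(f"#! meta: {k}={v}")
    lines.append("#! metabolites: " + " ".join(u.metabolite_ids))
    if u.precursor_ids:
        lines.append("#! precursors: " + " ".join(u.precursor_ids))
    for a, b in u.cofactor_pairs:
        lines.append(f"#! cofactor_pair: {a} {b}")
    lines.append("id\tequation\treversible\tlb\tub\tclass")
    for j, rid in enumerate(u.reaction_ids):
        eq = format_equation(u.reaction_coeffs(j))
        if u.reversible[j]:
            eq = eq.replace("->", "<->")
        lines.append(
            f"{rid}\t{eq}\t{int(u.reversible[j])}\t{float(u.lb[j])!r}\t{float(u.ub[j])!r}\t{u.classes[j]}"
        )
    path.write_text("\n".join(lines) + "\n")


def _load_sbml(path: str | Path) -> ReactionUniverse:
    try:
        import cobra.io
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("SBML reading requires the optional cobra dependency") from exc
    model = cobra.io.read_sbml_model(str(path))
    rows = []
    metabolites = [m.id for m in model.metabolites]
    objective_ids = {
        r.id for r in model.reactions if r.objective_coefficient
    }
    for r in model.reactions:
        if r.id in objective_ids:
            cls = "biomass"
        elif r.boundary:
            cls = "exchange"
        elif len({m.compartment for m in r.metabolites}) > 1:
            cls = "transport"
        else:
            cls = "internal"
        rows.append(
            ReactionRow(
                r.id,
                {m.id: float(c) for m, c in r.metabolites.items()},
                r.lower_bound < 0,
                float(r.lower_bound),
                float(r.upper_bound),
                cls,
            )
        )
    bm = next(r for r in model.reactions if r.id in objective_ids)
    precursors = [m.id for m, c in bm.metabolites.items() if c < 0]
    return build_universe(rows, metabolites, precursors, meta={"source": "sbml"})


def load_environments(path: str | Path, u: ReactionUniverse) -> EnvironmentPanel:
    """Read an environment panel from TSV (environment, exchange, bound, role).

    ``role`` is ``carbon`` for the sole carbon source of the environment and
    ``shared`` for nutrients common to the whole panel.  Order of first
    appearance fixes phenotype bit order.
    """
    path = Path(path)
    exchange_ids = {u.reaction_ids[j] for j in u.exchange_idx}
    order: list[str] = []
    uptake: dict[str, dict[str, float]] = {}
    carbon: dict[str, str] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if fields[0] == "environment":
            continue
        if len(fields) != 4:
            raise ModelFormatError(
                f"{path}:{lineno}: expected 4 fields (environment, exchange, bound, role)"
            )
        env, ex, bound, role = (f.strip() for f in fields)
        if ex not in exchange_ids:
            raise ModelFormatError(
                f"{path}:{lineno}: {ex!r} is not an exchange reaction of the model"
            )
        if env not in uptake:
            order.append(env)
            uptake[env] = {}
        uptake[env][ex] = float(bound)
        if role == "carbon":
            if env in carbon:
                raise ModelFormatError(f"{path}:{lineno}: two carbon sources for {env!r}")
            carbon[env] = ex
        elif role != "shared":
            raise ModelFormatError(f"{path}:{lineno}: unknown role {role!r}")
    envs = []
    for name in order:
        if name not in carbon:
            raise ModelFormatError(f"environment {name!r} declares no carbon source")
        envs.append(Environment(name, carbon[name], uptake[name]))
    return EnvironmentPanel(envs)


def save_environments(panel: EnvironmentPanel, path: str | Path) -> None:
    lines = ["environment\texchange\tbound\trole"]
    for e in panel:
        for ex, bound in e.uptake_bounds.items():
            role = "carbon" if ex == e.carbon_source else "shared"
            lines.append(f"{e.name}\t{ex}\t{bound!r}\t{role}")
    Path(path).write_text("\n".join(lines) + "\n")
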