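"""End-to-end analysis pipeline with provenance and stage caching.

``run_pipeline`` executes enumerate -> size histogram -> phenotype table ->
components/diameter -> disconnected fraction -> neighborhood diversity ->
network distances on one universe, writing TSV/JSON artifacts plus a
manifest into the output directory.  Outputs are deterministic for a fixed
config and seed; a stage whose artifact already exists under the same
config hash is reused and marked as such in the manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from ._version import __version__
from .datasets import load_ccm
from .enumeration import (
    Criterion,
    GenotypeSet,
    disconnected_fraction,
    enumerate_bruteforce,
    enumerate_divide_merge,
    phenotype_table,
    size_histogram,
)
from .fba import DEFAULT_THRESHOLD, FLUX_EPS
from .genonet import ComponentSummary, GenotypeNetwork, diameter_estimate
from .genotypes import Genotype
from .neighborhood import diversity_curve
from .distances import dmin_matrix
from .synthetic import SyntheticUniverseSpec, make_layered_universe, toy_a
from .universe import load_environments, load_universe


@dataclass
class RunConfig:
    """Full configuration of one pipeline run; serialized into every output."""

    model: str = "toy-a"  # path to tabular model, or "toy-a" / "ccm" / "synth"
    environments: str | None = None  # path; unused for built-in models
    criteria: list[str] = field(default_factory=list)  # default: one per source
    engine: str = "divide_merge"  # or "bruteforce"
    blocks: int = 3
    seed: int = 42
    pairs: int = 100  # neighborhood pairs per distance
    network_size: int | None = None  # size class for graph stages; default: modal
    threshold_fraction: float = DEFAULT_THRESHOLD
    flux_eps: float = FLUX_EPS
    synth_spec: dict = field(default_factory=dict)  # SyntheticUniverseSpec fields
    outdir: str = "results"

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    def config_hash(self) -> str:
        """Hash of all result-determining fields (the output path is not one)."""
        d = asdict(self)
        d.pop("outdir")
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


def _load_model(config: RunConfig):
    if config.model == "toy-a":
        return toy_a()
    if config.model == "ccm":
        return load_ccm()
    if config.model == "synth":
        u, panel, _ = make_layered_universe(SyntheticUniverseSpec(**config.synth_spec))
        return u, panel
    u = load_universe(config.model)
    if config.environments is None:
        raise ValueError("a model path requires an environments path")
    return u, load_environments(config.environments, u)


def run_pipeline(config: RunConfig) -> Path:
    """Run all stages; returns the output directory containing the manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    u, panel = _load_model(config)
    if u.N > 20 and config.engine == "bruteforce":
        raise ValueError("bruteforce engine refused for N > 20")

    cfg_hash = config.config_hash()
    cfg_path = out / "config.json"
    prior_hash = None
    if cfg_path.exists():
        try:
            prior_hash = json.loads((out / "manifest.json").read_text()).get("config_hash")
        except (OSError, json.JSONDecodeError):
            prior_hash = None
    cacheable = prior_hash == cfg_hash
    cfg_path.write_text(config.to_json() + "\n")

    manifest: dict = {
        "version": __version__,
        "config_hash": cfg_hash,
        "model_hash": u.model_hash(),
        "bit_order": list(u.internal_reaction_ids),
        "stages": [],
    }
    header = f"# model_hash={u.model_hash()} config_hash={cfg_hash}\n"

    def stage(name: str, outputs: list[str], compute, counts=None):
        paths = [out / o for o in outputs]
        if cacheable and all(p.exists() for p in paths):
            manifest["stages"].append({"name": name, "outputs": outputs, "reused": True})
            return None
        result = compute(paths)
        entry = {"name": name, "outputs": outputs, "reused": False}
        if counts:
            entry["counts"] = counts()
        manifest["stages"].append(entry)
        return result

    criteria = (
        [Criterion.parse(c) for c in config.criteria]
        if config.criteria
        else [Criterion.at_least(e.name) for e in panel]
    )

    # stage 1: enumerate per criterion ------------------------------------
    sets: dict[str, GenotypeSet] = {}
    lp_before = _total_lp_calls(u)
    for crit in criteria:
        fname = f"set_{_slug(crit)}.txt"

        def compute(paths, crit=crit, fname=fname):
            if config.engine == "bruteforce":
                gs = enumerate_bruteforce(u, panel, crit, config.threshold_fraction)
            else:
                gs = enumerate_divide_merge(
                    u, panel, crit, config.blocks, config.threshold_fraction
                )
            gs.save(paths[0])
            return gs

        gs = stage(f"enumerate[{crit}]", [fname], compute)
        if gs is None:
            gs = GenotypeSet.load(out / fname)
        sets[str(crit)] = gs
    enum_lp_calls = _total_lp_calls(u) - lp_before

    # stage 2: size histograms --------------------------------------------
    def compute_hist(paths):
        import pandas as pd

        frames = [size_histogram(gs).to_frame() for gs in sets.values()]
        table = pd.concat(frames, ignore_index=True)
        with open(paths[0], "w") as fh:
            fh.write(header)
            table.to_csv(fh, sep="\t", index=False)
        return table

    stage("size_histogram", ["size_histogram.tsv"], compute_hist,
          counts=lambda: {"lp_calls_enumeration": enum_lp_calls})

    # stage 3: phenotype table (only for per-source at_least criteria) ----
    per_source = {
        c.sources[0]: sets[str(c)]
        for c in criteria
        if c.kind == "at_least" and len(c.sources) == 1
    }
    if len(per_source) == len(panel):
        def compute_phen(paths):
            pt = phenotype_table(per_source, panel.names)
            with open(paths[0], "w") as fh:
                fh.write(header)
                pt.to_frame().to_csv(fh, sep="\t", index=False)
            (out / "implications.json").write_text(
                json.dumps(
                    {
                        "implications": pt.implications,
                        "forbidden_per_implication": pt.forbidden_per_implication,
                        "realized": pt.realized,
                    },
                    indent=2,
                )
                + "\n"
            )
        stage("phenotype_table", ["phenotype_table.tsv", "implications.json"], compute_phen)

    # graph stages use the first criterion's set --------------------------
    gs0 = sets[str(criteria[0])]
    hist0 = size_histogram(gs0)
    if not hist0.counts:
        sizes = []
    elif config.network_size is not None:
        sizes = [config.network_size]
    else:
        sizes = sorted(hist0.counts)

    # stage 4: components + diameter per size class -----------------------
    def compute_components(paths):
        rows = []
        for n in sizes:
            net = GenotypeNetwork.from_genotype_set(gs0, n)
            cs = ComponentSummary.from_network(net)
            de = diameter_estimate(net, seed=config.seed)
            rows.append(
                (str(criteria[0]), n, cs.n_members, cs.n_components,
                 f"{cs.r_giant:.6f}", de.value, de.mode, de.max_possible)
            )
        with open(paths[0], "w") as fh:
            fh.write(header)
            fh.write("criterion\tn\tmembers\tn_C\tr_G\tdiameter\tmode\tmax_possible\n")
            for row in rows:
                fh.write("\t".join(map(str, row)) + "\n")

    stage("components", ["components.tsv"], compute_components)

    # stage 5: disconnected fraction --------------------------------------
    env0 = panel[panel.index_of(criteria[0].sources[0])] if criteria[0].sources else panel[0]

    def compute_disc(paths):
        per_size, overall = disconnected_fraction(gs0, u, env0)
        with open(paths[0], "w") as fh:
            fh.write(header)
            fh.write("criterion\tenvironment\tn\tf_d\tconnected_fraction\n")
            for n, fd in per_size.items():
                fh.write(f"{criteria[0]}\t{env0.name}\t{n}\t{fd:.6f}\t{1-fd:.6f}\n")
            fh.write(f"{criteria[0]}\t{env0.name}\tall\t{overall:.6f}\t{1-overall:.6f}\n")

    stage("disconnected_fraction", ["disconnected.tsv"], compute_disc)

    # stage 6: neighborhood diversity on the giant component --------------
    def network_masks() -> frozenset[int]:
        n_star = config.network_size or max(hist0.counts, key=lambda n: hist0.counts[n])
        net = GenotypeNetwork.from_genotype_set(gs0, n_star)
        return net.connected_components()[0]

    def compute_neigh(paths):
        masks = network_masks()
        rng = np.random.default_rng(config.seed)
        n = next(iter(masks)).bit_count()
        dmax = min(n, u.N - n)
        points = diversity_curve(
            u, masks, panel, range(1, max(2, dmax + 1)), config.pairs, rng,
            threshold_fraction=config.threshold_fraction,
        )
        with open(paths[0], "w") as fh:
            fh.write(header + "# mode=hamming1\n")
            fh.write("n\tD\tmean_u\tn_pairs\tn_undefined\n")
            for p in points:
                fh.write(f"{p.size}\t{p.distance}\t{p.mean_u:.6f}\t{p.n_pairs}\t{p.n_undefined}\n")

    if len(network_masks()) >= 2:
        stage("neighborhood", ["neighborhood.tsv"], compute_neigh)

    # stage 7: inter-network distances ------------------------------------
    if len(per_source) >= 2:
        def compute_dist(paths):
            n_star = config.network_size or max(hist0.counts, key=lambda n: hist0.counts[n])
            nets = {}
            for src, gs in per_source.items():
                masks = frozenset(g.mask for g in gs.filter_size(n_star).members)
                if masks:
                    nets[src] = masks
            mat = dmin_matrix(nets, u.N)
            with open(paths[0], "w") as fh:
                fh.write(header + f"# n={n_star}\n")
                mat.to_csv(fh, sep="\t")

        stage("netdist", ["netdist.tsv"], compute_dist)

    manifest["lp_calls_total"] = _total_lp_calls(u)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return out


def _total_lp_calls(u) -> int:
    return sum(ctx.lp_calls for ctx in getattr(u, "_fba_contexts", {}).values())


def _slug(crit: Criterion) -> str:
    return str(crit).replace(":", "_").replace("+", "-")
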