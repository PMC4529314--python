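"""Build the bundled central carbon metabolism fixture from a published core model.

Starts from the genome-derived Escherichia coli core model bundled with
cobrapy and applies the curation used throughout this package:

* drop the ethanol branch (ALCD2x, ETOHt2r, EX_etoh_e) and the ATP
  maintenance drain (ATPM), so viability is determined by biomass
  production alone;
* merge the two aconitase half-reactions (ACONTa, ACONTb) into a single
  reversible aconitase ACONT (citrate <-> isocitrate);
* split the reversible ATP synthase ATPS4r into an irreversible synthase
  ATPS4 and an irreversible proton-pumping ATPase running the reverse
  direction, forming the third co-factor usage pair alongside the malic
  enzymes (ME1/ME2) and the transhydrogenases (NADTRHD/THD2);
* classify reactions: boundary pseudo-reactions are exchanges, reactions
  consuming or producing an external metabolite other than protons are
  always-present transports, the flux objective is the biomass reaction,
  everything else is an internal (genotype) reaction;
* record as biomass precursors the carbon-containing metabolites the
  biomass reaction consumes (its co-factor inputs atp/h2o/nad/nadph are
  not precursors).

Ten minimal environments share oxygen, ammonium, phosphate, CO2, protons
and water uptake and differ in a sole carbon source capped at 10
mmol/gDW/h.

Usage: python scripts/build_ccm_fixture.py [outdir]
"""

from __future__ import annotations

import gzip
import shutil
import sys
import tempfile
from importlib.resources import as_file, files
from pathlib import Path

from fluxspace.universe import (
    Environment,
    EnvironmentPanel,
    ReactionRow,
    build_universe,
    save_environments,
    save_universe,
)

REMOVE = {"ALCD2x", "ETOHt2r", "EX_etoh_e", "ATPM"}
COFACTOR_PAIRS = (("ME1", "ME2"), ("NADTRHD", "THD2"), ("ATPS4", "ATPase"))
BIOMASS_COFACTORS = {"atp_c", "h2o_c", "nad_c", "nadph_c"}

CARBON_EXCHANGES = {
    "glucose": "EX_glc__D_e",
    "fructose": "EX_fru_e",
    "acetate": "EX_ac_e",
    "2-oxoglutarate": "EX_akg_e",
    "fumarate": "EX_fum_e",
    "glutamate": "EX_glu__L_e",
    "lactate": "EX_lac__D_e",
    "malate": "EX_mal__L_e",
    "pyruvate": "EX_pyr_e",
    "succinate": "EX_succ_e",
}
SHARED_EXCHANGES = ("EX_co2_e", "EX_h_e", "EX_h2o_e", "EX_nh4_e", "EX_o2_e", "EX_pi_e")
CARBON_UPTAKE = 10.0
SHARED_UPTAKE = 1000.0


def load_core_model():
    import cobra.io

    src = files("cobra") / "data" / "textbook.xml.gz"
    with as_file(src) as gz, tempfile.TemporaryDirectory() as tmp:
        xml = Path(tmp) / "core.xml"
        with gzip.open(gz, "rb") as fin, open(xml, "wb") as fout:
            shutil.copyfileobj(fin, fout)
        return cobra.io.read_sbml_model(str(xml))


def classify(reaction) -> str:
    if reaction.objective_coefficient:
        return "biomass"
    if reaction.boundary:
        return "exchange"
    external = {
        m.id for m in reaction.metabolites if m.compartment == "e" and m.id != "h_e"
    }
    return "transport" if external else "internal"


def build():
    model = load_core_model()
    rows: list[ReactionRow] = []
    for r in model.reactions:
        if r.id in REMOVE or r.id in ("ACONTa", "ACONTb", "ATPS4r"):
            continue
        rows.append(
            ReactionRow(
                r.id,
                {m.id: float(c) for m, c in r.metabolites.items()},
                r.lower_bound < 0,
                float(r.lower_bound),
                float(r.upper_bound),
                classify(r),
            )
        )

    # merged aconitase: citrate <-> isocitrate (drops the bound intermediate)
    rows.append(
        ReactionRow("ACONT", {"cit_c": -1.0, "icit_c": 1.0}, True, -1000.0, 1000.0, "internal")
    )
    # split ATP synthase
    atps = {m.id: float(c) for m, c in model.reactions.get_by_id("ATPS4r").metabolites.items()}
    rows.append(ReactionRow("ATPS4", atps, False, 0.0, 1000.0, "internal"))
    rows.append(
        ReactionRow("ATPase", {m: -c for m, c in atps.items()}, False, 0.0, 1000.0, "internal")
    )

    used = {m for row in rows for m in row.coeffs}
    metabolites = [m.id for m in model.metabolites if m.id in used]
    bm = next(r for r in model.reactions if r.objective_coefficient)
    precursors = [
        m.id
        for m, c in bm.metabolites.items()
        if c < 0 and m.id not in BIOMASS_COFACTORS
    ]
    u = build_universe(
        rows,
        metabolites,
        precursors,
        COFACTOR_PAIRS,
        meta={"name": "ccm_core", "organism": "Escherichia coli (core model)"},
    )

    envs = []
    for name, ex in CARBON_EXCHANGES.items():
        uptake = {ex: CARBON_UPTAKE}
        uptake.update({s: SHARED_UPTAKE for s in SHARED_EXCHANGES})
        envs.append(Environment(name, ex, uptake))
    return u, EnvironmentPanel(envs)


def main() -> None:
    outdir = Path(sys.argv[1]) if len(sys.argv) > 1 else Path("src/fluxspace/data")
    outdir.mkdir(parents=True, exist_ok=True)
    u, panel = build()
    save_universe(u, outdir / "ccm_universe.tsv")
    save_environments(panel, outdir / "ccm_environments.tsv")
    n_trans = len(u.transport_idx)
    n_ex = len(u.exchange_idx)
    print(
        f"wrote {outdir}/ccm_universe.tsv: N={u.N} internal, "
        f"{n_trans} transport, {n_ex} exchange, {u.n_metabolites} metabolites, "
        f"{len(u.precursor_ids)} precursors, hash={u.model_hash()}"
    )
    print(f"wrote {outdir}/ccm_environments.tsv: {len(panel)} environments")


if __name__ == "__main__":
    main()
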