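"""In silico chemotaxonomy: catalog-gene detection and chemotype rules.

Chemotypes (fatty acids, polar lipids, respiratory quinone, polyamine
capabilities, PHB) are predicted purely from the presence/absence of
catalog genes, with one logged rule per predicted item:

fatty acids
    (i)   complete FASII core  => C16:0
    (ii)  fabA and fabB        => C16:1w7c and C18:1w7c (anaerobic route)
    (iii) a desaturase homolog (with both histidine clusters, when the
          protein sequence is available) => C16:1w7c (aerobic route);
          C18:1w9c is explicitly NOT predicted — the delta-9 desaturases of
          this group have no recorded oleic-acid product
    (iv)  all pfa/ole absent   => PUFA: no
    (v)   no branched-chain primer system in the catalog => branched: no
    (vi)  lpxA present         => C10:0 3-OH (lipid A hydroxy acid)

polar lipids: plsX+plsY+plsC+cdsA form the CDP-DAG backbone; backbone with
pssA+psd gives PE, with pgsA+pgpA gives PG; PG plus cls gives DPG.

quinone: the eight pathway ubi genes plus ispA+ispB give Q-8 (ispB fixes
the 8-unit side chain); missing pathway genes yield "undetermined" with a
gap list; missing accessory genes only warn.

polyamines: speA+speB -> putrescine via agmatine; speC -> putrescine via
ornithine; speD+speE -> autonomous spermidine; spuC+kauB -> GABA from
putrescine.

PHB: phaA+phaB+phaC+phaE.

Predictions are monotone: adding genes to a row never removes an item.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib.resources import files

import pandas as pd

from .errors import ConfigError, FormatError, GenotaxError
from .genome_io import GeneFeature
from ._align import align


# ---------------------------------------------------------------------------
# catalog


@dataclass
class PathwayCatalog:
    families: dict
    version: int = 1

    @property
    def symbols(self) -> list[str]:
        out = []
        for fam in self.families.values():
            out.extend(fam["symbols"])
        return out

    def family_of(self, symbol: str) -> str:
        for name, fam in self.families.items():
            if symbol in fam["symbols"]:
                return name
        raise GenotaxError(f"symbol {symbol!r} not in catalog")


def load_catalog(path=None) -> PathwayCatalog:
    """Load the bundled default catalog, or a user override."""
    if path is None:
        text = files("genotax.data").joinpath("catalog.json").read_text()
    else:
        text = open(path).read()
    raw = json.loads(text)
    catalog = PathwayCatalog(families=raw["families"], version=raw.get("version", 1))
    seen = {}
    for name, fam in catalog.families.items():
        for sym in fam["symbols"]:
            if sym in seen:
                raise ConfigError(f"catalog symbol {sym!r} in both {seen[sym]} and {name}")
            seen[sym] = name
    if not seen:
        raise ConfigError("catalog is empty")
    return catalog


# ---------------------------------------------------------------------------
# presence table


@dataclass
class PresenceTable:
    """strain x catalog-gene presence/absence with per-cell evidence."""

    table: pd.DataFrame  # bool, index=genome_id, columns=symbols
    evidence: dict[tuple[str, str], str] = field(default_factory=dict)

    def row(self, genome_id: str) -> dict[str, bool]:
        return self.table.loc[genome_id].to_dict()


def detect_genes(
    genome_id: str,
    features: list[GeneFeature],
    catalog: PathwayCatalog,
    mode: str = "symbol",
    reference_proteins: dict[str, str] | None = None,
    proteome: list[tuple[str, str]] | None = None,
    min_identity: float = 0.40,
    min_coverage: float = 0.70,
) -> PresenceTable:
    """One presence row for a genome.

    symbol mode: case-insensitive gene-symbol match against annotations.
    homology mode: each reference protein (symbol -> sequence, supplied by
    the caller) is aligned against the proteome; the best hit passing the
    identity/coverage thresholds is the evidence.
    """
    symbols = catalog.symbols
    if not symbols:
        raise ConfigError("catalog is empty")
    present = {s: False for s in symbols}
    evidence: dict[tuple[str, str], str] = {}
    if mode == "symbol":
        lookup = {s.lower(): s for s in symbols}
        for f in features:
            sym = lookup.get((f.gene_symbol or "").lower())
            if sym is not None and not present[sym]:
                present[sym] = True
                evidence[(genome_id, sym)] = f.feature_id
    elif mode == "homology":
        if reference_proteins is None or proteome is None:
            raise ConfigError("homology mode needs reference_proteins and a proteome")
        for sym in symbols:
            ref = reference_proteins.get(sym)
            if not ref:
                continue
            best = None
            for fid, prot in proteome:
                if not prot or min(len(ref), len(prot)) < min_coverage * max(len(ref), len(prot)):
                    continue
                res = align(ref, prot, mode="NW")
                if res is None or res.identity < min_identity:
                    continue
                if best is None or res.identity > best[1]:
                    best = (fid, res.identity)
            if best is not None:
                present[sym] = True
                evidence[(genome_id, sym)] = f"homology:{best[0]}:{best[1]:.3f}"
    else:
        raise ConfigError(f"unknown detection mode {mode!r}")
    table = pd.DataFrame([present], index=[genome_id], columns=symbols)
    return PresenceTable(table=table, evidence=evidence)


def detect_genes_panel(
    genomes: list[tuple[str, list[GeneFeature]]], catalog: PathwayCatalog, **kw
) -> PresenceTable:
    rows = [detect_genes(gid, feats, catalog, **kw) for gid, feats in genomes]
    return PresenceTable(
        table=pd.concat([r.table for r in rows]),
        evidence={k: v for r in rows for k, v in r.evidence.items()},
    )


def load_strain_presence_table(catalog: PathwayCatalog | None = None) -> PresenceTable:
    """The bundled eight-strain reference matrix as a PresenceTable."""
    from .synthetic import load_strain_presence

    strains, table = load_strain_presence()
    df = pd.DataFrame({s: table[s] for s in strains}).T
    if catalog is not None:
        df = df.reindex(columns=catalog.symbols, fill_value=False)
    ev = {
        (s, sym): "bundled reference matrix"
        for s in strains
        for sym, v in table[s].items()
        if v
    }
    return PresenceTable(table=df, evidence=ev)


# ---------------------------------------------------------------------------
# desaturase motifs


_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class MotifReport:
    hxxxh_positions: tuple[int, ...]
    hxxhh_positions: tuple[int, ...]

    @property
    def functional(self) -> bool:
        return bool(self.hxxxh_positions) and bool(self.hxxhh_positions)


def check_desaturase_motifs(protein_seq: str) -> MotifReport:
    """Scan for the H-x(3)-H and H-x(2)-H-H histidine clusters required for
    desaturase activity (overlapping occurrences counted, 0-based)."""
    if not protein_seq:
        raise FormatError("empty protein sequence")
    seq = protein_seq.upper()
    bad = set(seq) - _AA
    if bad:
        raise FormatError(f"non-amino-acid characters: {sorted(bad)}")
    hxxxh = tuple(m.start() for m in re.finditer(r"(?=H.{3}H)", seq))
    hxxhh = tuple(m.start() for m in re.finditer(r"(?=H.{2}HH)", seq))
    return MotifReport(hxxxh_positions=hxxxh, hxxhh_positions=hxxhh)


# ---------------------------------------------------------------------------
# rule engine


@dataclass
class RuleOutcome:
    item: str
    satisfied: bool
    rule: str
    evidence: list[str] = field(default_factory=list)


@dataclass
class ChemotypePrediction:
    genome_id: str
    fatty_acids: set[str] = field(default_factory=set)
    negations: dict[str, str] = field(default_factory=dict)
    polar_lipids: set[str] = field(default_factory=set)
    quinone: str = "undetermined"
    quinone_gaps: list[str] = field(default_factory=list)
    quinone_accessory_missing: list[str] = field(default_factory=list)
    polyamines: set[str] = field(default_factory=set)
    phb: bool = False
    phb_gaps: list[str] = field(default_factory=list)
    rules: list[RuleOutcome] = field(default_factory=list)
    pathway_completeness: dict[str, bool] = field(default_factory=dict)


def _require_complete(row: dict[str, bool], symbols: list[str]) -> None:
    missing = [s for s in symbols if s not in row]
    if missing:
        raise GenotaxError(f"presence row incomplete; missing symbols: {missing}")


def predict_fatty_acids(
    row: dict[str, bool],
    catalog: PathwayCatalog,
    desaturase_motifs: dict[str, MotifReport] | None = None,
    prediction: ChemotypePrediction | None = None,
) -> ChemotypePrediction:
    """Fatty-acid rules (i)-(vi); see module docstring.

    ``desaturase_motifs`` optionally maps Des symbols to motif reports; a
    present Des gene whose protein lacks either histidine cluster is
    demoted to "present, function-uncertain" and does not fire the aerobic
    rule.
    """
    fam = catalog.families
    fas = fam["fatty_acid_synthesis"]
    _require_complete(row, fas["symbols"] + fam["desaturase"]["symbols"] + fam["lipid_a"]["symbols"] + fam["pufa"]["symbols"])
    p = prediction or ChemotypePrediction(genome_id="row")
    # (i) FASII core completeness => C16:0
    complete = all(any(row[s] for s in group) for group in fas["required_groups"])
    p.pathway_completeness["fasii_core"] = complete
    gaps = ["/".join(g) for g in fas["required_groups"] if not any(row[s] for s in g)]
    p.rules.append(RuleOutcome("C16:0", complete, "FASII core complete", gaps if not complete else [s for g in fas["required_groups"] for s in g if row.get(s)]))
    if complete:
        p.fatty_acids.add("C16:0")
    # (ii) anaerobic omega-7 route
    anaerobic = row["fabA"] and row["fabB"]
    p.rules.append(RuleOutcome("C16:1w7c/C18:1w7c", anaerobic, "fabA+fabB anaerobic route", ["fabA", "fabB"] if anaerobic else []))
    if anaerobic:
        p.fatty_acids.update({"C16:1w7c", "C18:1w7c"})
    # (iii) aerobic desaturase route
    des_present = [s for s in fam["desaturase"]["symbols"] if row[s]]
    des_functional = []
    des_uncertain = []
    for s in des_present:
        report = (desaturase_motifs or {}).get(s)
        if report is None or report.functional:
            des_functional.append(s)
        else:
            des_uncertain.append(s)
    p.rules.append(
        RuleOutcome("C16:1w7c", bool(des_functional), "delta-9 desaturase aerobic route", des_functional)
    )
    if des_functional:
        p.fatty_acids.add("C16:1w7c")
    if des_uncertain:
        p.negations["desaturase_uncertain"] = ",".join(des_uncertain)
    p.negations["C18:1w9c"] = "not-expected"
    # (iv) PUFA
    pufa_genes = [s for s in fam["pufa"]["symbols"] if row[s]]
    if not pufa_genes:
        p.negations["PUFA"] = "no"
        p.rules.append(RuleOutcome("PUFA", False, "all pfa/ole absent", []))
    # (v) branched-chain: no primer system in catalog at all
    p.negations["branched"] = "no"
    p.rules.append(RuleOutcome("branched", False, "no branched-chain primer system in catalog", []))
    # (vi) lipid A hydroxy acid
    if row["lpxA"]:
        p.fatty_acids.add("C10:0 3-OH")
        p.rules.append(RuleOutcome("C10:0 3-OH", True, "lpxA present", ["lpxA"]))
    return p


def predict_polar_lipids(
    row: dict[str, bool], catalog: PathwayCatalog, prediction: ChemotypePrediction | None = None
) -> ChemotypePrediction:
    fam = catalog.families["polar_lipid"]
    _require_complete(row, fam["symbols"])
    p = prediction or ChemotypePrediction(genome_id="row")
    backbone = all(row[s] for s in fam["backbone"])
    p.pathway_completeness["cdp_dag_backbone"] = backbone
    pe = backbone and all(row[s] for s in fam["pe_branch"])
    pg = backbone and all(row[s] for s in fam["pg_branch"])
    dpg = pg and all(row[s] for s in fam["dpg"])
    for lipid, ok, genes in (
        ("PE", pe, fam["backbone"] + fam["pe_branch"]),
        ("PG", pg, fam["backbone"] + fam["pg_branch"]),
        ("DPG", dpg, fam["backbone"] + fam["pg_branch"] + fam["dpg"]),
    ):
        p.rules.append(RuleOutcome(lipid, ok, f"{lipid} pathway complete", genes if ok else []))
        if ok:
            p.polar_lipids.add(lipid)
    return p


def predict_quinone(
    row: dict[str, bool], catalog: PathwayCatalog, prediction: ChemotypePrediction | None = None
) -> ChemotypePrediction:
    fam = catalog.families["quinone"]
    _require_complete(row, fam["symbols"])
    p = prediction or ChemotypePrediction(genome_id="row")
    gaps = [s for s in fam["pathway"] if not row[s]]
    accessory_missing = [s for s in fam["accessory"] if not row[s]]
    p.quinone_accessory_missing = accessory_missing
    if not gaps:
        p.quinone = "Q-8"
        p.rules.append(RuleOutcome("Q-8", True, "ubi pathway + ispAB complete", fam["pathway"]))
    else:
        p.quinone = "undetermined"
        p.quinone_gaps = gaps
        p.rules.append(RuleOutcome("Q-8", False, "ubi pathway incomplete", gaps))
    return p


def predict_polyamines(
    row: dict[str, bool], catalog: PathwayCatalog, prediction: ChemotypePrediction | None = None
) -> ChemotypePrediction:
    fam = catalog.families["polyamine"]
    _require_complete(row, fam["symbols"])
    p = prediction or ChemotypePrediction(genome_id="row")
    caps = {
        "putrescine_via_agmatine": all(row[s] for s in fam["agmatine_route"]),
        "putrescine_via_ornithine": all(row[s] for s in fam["ornithine_route"]),
        "spermidine_autonomous": all(row[s] for s in fam["spermidine"]),
        "GABA_from_putrescine": all(row[s] for s in fam["gaba_route"]),
    }
    routes = {
        "putrescine_via_agmatine": fam["agmatine_route"],
        "putrescine_via_ornithine": fam["ornithine_route"],
        "spermidine_autonomous": fam["spermidine"],
        "GABA_from_putrescine": fam["gaba_route"],
    }
    for cap, ok in caps.items():
        p.rules.append(RuleOutcome(cap, ok, "+".join(routes[cap]), routes[cap] if ok else []))
        if ok:
            p.polyamines.add(cap)
    return p


def predict_phb(
    row: dict[str, bool], catalog: PathwayCatalog, prediction: ChemotypePrediction | None = None
) -> ChemotypePrediction:
    fam = catalog.families["phb"]
    _require_complete(row, fam["symbols"])
    p = prediction or ChemotypePrediction(genome_id="row")
    gaps = [s for s in fam["symbols"] if not row[s]]
    p.phb = not gaps
    p.phb_gaps = gaps
    p.rules.append(RuleOutcome("PHB", p.phb, "phaABCE complete", fam["symbols"] if p.phb else gaps))
    return p


def predict_chemotype(
    genome_id: str,
    row: dict[str, bool],
    catalog: PathwayCatalog,
    desaturase_motifs: dict[str, MotifReport] | None = None,
) -> ChemotypePrediction:
    """All chemotype components for one presence row."""
    p = ChemotypePrediction(genome_id=genome_id)
    predict_fatty_acids(row, catalog, desaturase_motifs, p)
    predict_polar_lipids(row, catalog, p)
    predict_quinone(row, catalog, p)
    predict_polyamines(row, catalog, p)
    predict_phb(row, catalog, p)
    return p
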