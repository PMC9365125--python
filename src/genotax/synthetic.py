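"""Synthetic genome evolution with recorded ground truth.

Generates an ancestral bacterial chromosome with labelled marker genes
(16S rRNA; recA/mreB/rpoA/topA), catalog pathway genes, and generic ORFs,
then evolves descendant lineages by:

* per-site substitutions drawn Bernoulli(d) on the *final* state (repeated
  hits collapse), partitioned into transitions/transversions by a fixed
  ts/tv ratio — so expected sequence identity between ancestor and
  descendant is exactly 1 - d and the Kimura two-parameter estimator is
  exactly matched by construction;
* large-scale inversions (reverse-complement of a configured interval);
* lineage-specific gene loss (the ancestor carries the union of all
  lineages' gene complements; each lineage's missing genes are excised).

Every stochastic choice derives from ``SimulationConfig.seed``; identical
seeds give byte-identical genomes.  The realized events are recorded in
:class:`SimulationTruth` so downstream metrics can be scored against truth.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .genome_io import GeneFeature, GenomeRecord, translate_cds, write_fasta, write_gff3
from ._align import revcomp

logger = logging.getLogger(__name__)

MARKER_SET = ("16S", "recA", "mreB", "rpoA", "topA")

#: marker gene lengths in nt (16S is a non-coding rRNA gene)
_MARKER_LENGTHS = {"16S": 1540, "recA": 1062, "mreB": 1041, "rpoA": 990, "topA": 2592}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]


@dataclass
class SimulationConfig:
    """Parameters of one simulation run (seed is mandatory)."""

    seed: int
    ancestor_length: int = 1_000_000
    gc: float = 0.5
    marker_set: tuple[str, ...] = MARKER_SET
    #: lineage -> set of catalog gene symbols that lineage retains; the
    #: ancestor is built with the union of all complements.
    gene_complement: dict[str, frozenset[str]] = field(default_factory=dict)
    #: product annotation per implanted symbol (defaults to "<symbol> protein")
    products: dict[str, str] = field(default_factory=dict)
    #: lineage -> expected per-site substitution probability d in [0, 0.35]
    branch_divergence: dict[str, float] = field(default_factory=dict)
    ts_tv_ratio: float = 2.0
    #: (lineage_id, start, length) intervals to invert, applied in order
    inversions: list[tuple[str, int, int]] = field(default_factory=list)
    indel_rate: float = 0.0
    #: generic "hypothetical protein" ORFs present in every lineage
    extra_genes: int = 120

    def __post_init__(self):
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        for lin, d in self.branch_divergence.items():
            if not (0.0 <= d <= 0.35):
                raise ConfigError(f"divergence d={d} for {lin!r} outside [0, 0.35]")


@dataclass
class LineageTruth:
    """Realized evolutionary events on one lineage branch."""

    lineage_id: str
    divergence: float
    substitutions: int = 0
    transitions: int = 0
    transversions: int = 0
    realized_divergence: float = 0.0
    binomial_sigma: float = 0.0
    deleted_genes: list[str] = field(default_factory=list)
    kept_genes: list[str] = field(default_factory=list)
    #: inversion intervals in final descendant coordinates [(start, end)]
    inversions: list[tuple[int, int]] = field(default_factory=list)
    marker_coords: dict[str, tuple[int, int, str]] = field(default_factory=dict)


@dataclass
class SimulationTruth:
    """Ground truth for one simulation: ancestor gene roster and per-lineage
    realized events."""

    config_seed: int
    ancestor_length: int = 0
    #: symbol -> (start, end, strand, product, protein)
    ancestor_genes: dict[str, tuple[int, int, str, str, str]] = field(default_factory=dict)
    lineages: dict[str, LineageTruth] = field(default_factory=dict)

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, (LineageTruth,)):
                return o.__dict__
            raise TypeError(type(o))

        return json.dumps(self.__dict__, default=default, indent=1)


# ---------------------------------------------------------------------------
# ancestor construction


def _random_orf(rng: np.random.Generator, n_codons: int) -> str:
    body = "".join(rng.choice(_SENSE_CODONS, size=n_codons))
    return "ATG" + body + "TAA"


def _gene_roster(config: SimulationConfig, rng: np.random.Generator) -> list[tuple[str, str, str]]:
    """Build (symbol, product, sequence) for every gene the ancestor carries."""
    roster = []
    for sym in config.marker_set:
        length = _MARKER_LENGTHS.get(sym, 900)
        if sym == "16S":
            seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
            roster.append((sym, "16S ribosomal RNA", seq))
        else:
            roster.append((sym, config.products.get(sym, f"{sym} protein"), _random_orf(rng, (length - 6) // 3)))
    union: set[str] = set()
    for genes in config.gene_complement.values():
        union |= set(genes)
    for sym in sorted(union):
        n_codons = int(rng.integers(150, 401))
        roster.append((sym, config.products.get(sym, f"{sym} protein"), _random_orf(rng, n_codons)))
    for i in range(config.extra_genes):
        sym = f"orf{i + 1:04d}"
        n_codons = int(rng.integers(150, 401))
        roster.append((sym, "hypothetical protein", _random_orf(rng, n_codons)))
    return roster


def generate_ancestor(config: SimulationConfig) -> tuple[GenomeRecord, SimulationTruth]:
    """Random background sequence at the configured GC with every gene
    implanted as a labelled feature at non-overlapping positions."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed & 0x7FFFFFFF, 0]))
    L = config.ancestor_length
    roster = _gene_roster(config, rng)
    total_gene_len = sum(len(seq) for _, _, seq in roster)
    if total_gene_len > 0.9 * L:
        raise ConfigError(
            f"genes ({total_gene_len} bp) exceed 90% of ancestor length {L}"
        )
    # background at configured GC
    p = np.array([(1 - config.gc) / 2, config.gc / 2, config.gc / 2, (1 - config.gc) / 2])
    arr = _BASES[rng.choice(4, size=L, p=p)]
    # spread genes with random intergenic gaps summing exactly to the slack
    order = rng.permutation(len(roster))
    slack = L - total_gene_len
    gaps = rng.multinomial(slack, np.full(len(roster) + 1, 1.0 / (len(roster) + 1)))
    truth = SimulationTruth(config_seed=config.seed, ancestor_length=L)
    features = []
    cursor = 0
    for gi, idx in enumerate(order):
        sym, product, seq = roster[idx]
        cursor += int(gaps[gi])
        start, end = cursor, cursor + len(seq)
        strand = "+" if rng.random() < 0.5 else "-"
        placed = seq if strand == "+" else revcomp(seq)
        arr[start:end] = np.frombuffer(placed.encode(), dtype=np.uint8)
        protein = "" if sym == "16S" else translate_cds(seq)
        features.append(
            GeneFeature(
                feature_id=f"anc_{sym}",
                gene_symbol=sym,
                product=product,
                replicon_id="chr",
                start=start,
                end=end,
                strand=strand,
                protein_seq=protein,
            )
        )
        truth.ancestor_genes[sym] = (start, end, strand, product, protein)
        cursor = end
    features.sort(key=lambda f: f.start)
    genome = GenomeRecord(
        genome_id="ancestor",
        organism_label="synthetic ancestor",
        replicons=[("chr", arr.tobytes().decode("ascii"), "circular")],
        source="synthetic",
        features=features,
    )
    return genome, truth


# ---------------------------------------------------------------------------
# lineage evolution


def _lineage_rng(seed: int, lineage_id: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32(lineage_id.encode())])
    )


def _substitute(arr: np.ndarray, d: float, kappa: float, rng) -> tuple[np.ndarray, int, int]:
    """Per-site Bernoulli(d) substitution on the final state; returns
    (mutated array, transitions, transversions)."""
    if d <= 0:
        return arr, 0, 0
    codes = np.full(arr.size, 4, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        codes[arr == b] = i
    hit = (rng.random(arr.size) < d) & (codes != 4)
    n = int(hit.sum())
    if n == 0:
        return arr, 0, 0
    old = codes[hit]
    is_ts = rng.random(n) < kappa / (kappa + 1.0)
    coin = rng.integers(0, 2, size=n).astype(np.uint8)
    new = np.where(
        is_ts,
        old ^ 2,                                   # A<->G, C<->T
        np.where(old % 2 == 0, 1 + 2 * coin, 2 * coin),  # purine->pyrimidine and v.v.
    ).astype(np.uint8)
    out = arr.copy()
    out[hit] = _BASES[new]
    return out, int(is_ts.sum()), int(n - is_ts.sum())


def _excise(seq: str, features: list[GeneFeature], intervals: list[tuple[int, int]]):
    """Remove intervals (sorted, disjoint) from the sequence, dropping
    features inside them and shifting the rest."""
    intervals = sorted(intervals)
    keep_parts = []
    cursor = 0
    for a, b in intervals:
        keep_parts.append(seq[cursor:a])
        cursor = b
    keep_parts.append(seq[cursor:])
    new_seq = "".join(keep_parts)
    starts = [a for a, _ in intervals]
    cum = np.cumsum([b - a for a, b in intervals]) if intervals else np.array([])

    def shift(pos: int) -> int:
        i = np.searchsorted(starts, pos, side="right")
        return pos - (int(cum[i - 1]) if i > 0 else 0)

    out_feats = []

    for f in features:
        if any(a <= f.start and f.end <= b for a, b in intervals):
            continue
        out_feats.append(
            GeneFeature(
                feature_id=f.feature_id,
                gene_symbol=f.gene_symbol,
                product=f.product,
                replicon_id=f.replicon_id,
                start=shift(f.start),
                end=shift(f.end),
                strand=f.strand,
                protein_seq=f.protein_seq,
            )
        )
    return new_seq, out_feats


def _invert(seq: str, features: list[GeneFeature], start: int, length: int):
    end = start + length
    if not (0 <= start < end <= len(seq)):
        raise ConfigError(f"inversion [{start},{end}) outside genome of length {len(seq)}")
    new_seq = seq[:start] + revcomp(seq[start:end]) + seq[end:]
    out = []
    for f in features:
        if f.end <= start or f.start >= end:
            out.append(f)
            continue
        if f.start < start or f.end > end:
            logger.warning(
                "inversion [%d,%d) truncates feature %s; feature dropped", start, end, f.feature_id
            )
            continue
        if f.gene_symbol in MARKER_SET:
            logger.warning("inversion overlaps marker gene %s", f.gene_symbol)
        out.append(
            GeneFeature(
                feature_id=f.feature_id,
                gene_symbol=f.gene_symbol,
                product=f.product,
                replicon_id=f.replicon_id,
                start=start + end - f.end,
                end=start + end - f.start,
                strand="-" if f.strand == "+" else "+",
                protein_seq=f.protein_seq,
            )
        )
    out.sort(key=lambda f: f.start)
    return new_seq, out


def evolve(
    genome: GenomeRecord,
    lineage_id: str,
    config: SimulationConfig,
    truth: SimulationTruth | None = None,
) -> tuple[GenomeRecord, SimulationTruth]:
    """Evolve one descendant lineage from ``genome``.

    Order of events: substitutions, then gene deletions (symbols absent
    from the lineage's gene complement), then configured inversions
    (coordinates interpreted on the post-deletion sequence).
    """
    if truth is None:
        truth = SimulationTruth(config_seed=config.seed, ancestor_length=genome.length)
    rng = _lineage_rng(config.seed, lineage_id)
    d = config.branch_divergence.get(lineage_id, 0.0)
    if not (0.0 <= d <= 0.35):
        raise ConfigError(f"divergence d={d} outside [0, 0.35]")
    rid, seq, topo = genome.replicons[0]
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    arr, ts, tv = _substitute(arr, d, config.ts_tv_ratio, rng)
    new_seq = arr.tobytes().decode("ascii")
    n_sub = ts + tv
    lt = LineageTruth(
        lineage_id=lineage_id,
        divergence=d,
        substitutions=n_sub,
        transitions=ts,
        transversions=tv,
        realized_divergence=n_sub / len(seq),
        binomial_sigma=float(np.sqrt(len(seq) * d * (1 - d))),
    )
    features = list(genome.features)
    # protein sequences must reflect the mutated DNA: retranslate CDS features
    tmp = GenomeRecord(genome_id="tmp", replicons=[(rid, new_seq, topo)], features=[])
    refreshed = []
    for f in features:
        prot = f.protein_seq
        if prot:
            nt = tmp.sequence(rid)[f.start : f.end]
            if f.strand == "-":
                nt = revcomp(nt)
            prot = translate_cds(nt).replace("*", "X")  # substitutions may create stops
        refreshed.append(
            GeneFeature(f.feature_id, f.gene_symbol, f.product, rid, f.start, f.end, f.strand, prot)
        )
    features = refreshed

    # lineage-specific gene loss
    if lineage_id in config.gene_complement:
        keep = set(config.gene_complement[lineage_id])
        deletable = {
            f.gene_symbol
            for f in features
            if f.gene_symbol
            and f.gene_symbol not in config.marker_set
            and not f.gene_symbol.startswith("orf")
        }
        drop = sorted(deletable - keep)
        intervals = [(f.start, f.end) for f in features if f.gene_symbol in set(drop)]
        new_seq, features = _excise(new_seq, features, intervals)
        lt.deleted_genes = drop
        lt.kept_genes = sorted(
            {f.gene_symbol for f in features if f.gene_symbol and not f.gene_symbol.startswith("orf")}
        )
    else:
        lt.kept_genes = sorted(
            {f.gene_symbol for f in features if f.gene_symbol and not f.gene_symbol.startswith("orf")}
        )

    for lin, start, length in config.inversions:
        if lin != lineage_id:
            continue
        new_seq, features = _invert(new_seq, features, start, length)
        lt.inversions.append((start, start + length))

    for f in features:
        if f.gene_symbol in config.marker_set:
            lt.marker_coords[f.gene_symbol] = (f.start, f.end, f.strand)
    features = [
        GeneFeature(
            f"{lineage_id}_{f.gene_symbol or f.feature_id}",
            f.gene_symbol,
            f.product,
            rid,
            f.start,
            f.end,
            f.strand,
            f.protein_seq,
        )
        for f in features
    ]
    descendant = GenomeRecord(
        genome_id=lineage_id,
        organism_label=f"synthetic lineage {lineage_id}",
        replicons=[(rid, new_seq, topo)],
        source="synthetic",
        features=features,
    )
    truth.lineages[lineage_id] = lt
    return descendant, truth


# ---------------------------------------------------------------------------
# convenience constructors


def make_pair(
    seed: int,
    divergence: float,
    length: int = 1_000_000,
    inversions: list[tuple[int, int]] | None = None,
    extra_genes: int = 120,
    gene_complement: frozenset[str] = frozenset(),
    ts_tv_ratio: float = 2.0,
) -> tuple[GenomeRecord, GenomeRecord, SimulationTruth]:
    """Ancestor plus one descendant at per-site divergence ``divergence``."""
    config = SimulationConfig(
        seed=seed,
        ancestor_length=length,
        gene_complement={"D": frozenset(gene_complement)} if gene_complement else {},
        branch_divergence={"D": divergence},
        inversions=[("D", s, l) for s, l in (inversions or [])],
        extra_genes=extra_genes,
        ts_tv_ratio=ts_tv_ratio,
    )
    ancestor, truth = generate_ancestor(config)
    descendant, truth = evolve(ancestor, "D", config, truth)
    return ancestor, descendant, truth


@dataclass
class PanelTruth:
    """Truth record for a two-clade strain panel."""

    clade_map: dict[str, str]
    #: symbol -> set of lineage ids carrying the gene
    gene_presence: dict[str, set[str]]
    lttr_counts: dict[str, int]
    truth: SimulationTruth


def load_strain_presence() -> tuple[list[str], dict[str, dict[str, bool]]]:
    """Bundled eight-strain presence matrix as (strains, {strain: {symbol: bool}})."""
    from importlib.resources import files

    text = files("genotax.data").joinpath("strain_presence.tsv").read_text()
    lines = [l for l in text.splitlines() if l and not l.startswith("#")]
    strains = lines[0].split("\t")[1:]
    table: dict[str, dict[str, bool]] = {s: {} for s in strains}
    for line in lines[1:]:
        cells = line.split("\t")
        for s, v in zip(strains, cells[1:]):
            table[s][cells[0]] = v == "+"
    return strains, table


def make_panel(
    seed: int,
    length: int = 1_000_000,
    d_within: float = 0.02,
    d_between: float = 0.10,
    lttr_mean_a: int = 122,
    lttr_mean_b: int = 65,
    extra_genes: int = 40,
) -> tuple[list[GenomeRecord], PanelTruth]:
    """Eight-lineage two-clade panel mirroring the bundled strain matrix.

    Clade A (3 lineages, *Aliamphritea*-patterned) and clade B (5 lineages,
    *Amphritea*-patterned) descend from clade ancestors separated by
    ``d_between``; lineages within a clade are separated by ``d_within``.
    Each lineage additionally carries its own complement of LysR-type
    transcriptional regulator genes, Poisson-distributed around the clade
    mean, implanted as lineage-unique reserved symbols.
    """
    strains, table = load_strain_presence()
    clade_map = {s: ("A" if s.startswith("Al_") else "B") for s in strains}
    if len(strains) < 2:
        raise ConfigError("panel needs at least 2 lineages")
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 1]))
    lttr_counts = {
        s: int(rng.poisson(lttr_mean_a if clade_map[s] == "A" else lttr_mean_b))
        for s in strains
    }
    # clade-disjoint LTTR pools: each clade's regulator repertoire is its own
    # gene family set, so bin truth stays clean (clade-A pool -> A_unique
    # where all three carry it, dispensable where counts differ)
    pools = {
        c: [
            f"LTR{c}{i + 1:04d}"
            for i in range(max(lttr_counts[s] for s in strains if clade_map[s] == c))
        ]
        for c in ("A", "B")
    }
    products = {
        sym: "LysR family transcriptional regulator" for p in pools.values() for sym in p
    }
    complements = {
        s: frozenset(
            {sym for sym, present in table[s].items() if present}
            | set(pools[clade_map[s]][: lttr_counts[s]])
        )
        for s in strains
    }
    half_between = round(d_between / 2, 6)
    half_within = round(d_within / 2, 6)
    branch = {"cladeA": half_between, "cladeB": half_between}
    branch.update({s: half_within for s in strains})
    config = SimulationConfig(
        seed=seed,
        ancestor_length=length,
        gene_complement=complements,
        products=products,
        branch_divergence=branch,
        extra_genes=extra_genes,
    )
    root, truth = generate_ancestor(config)
    anc_a, truth = evolve(root, "cladeA", config, truth)
    anc_b, truth = evolve(root, "cladeB", config, truth)
    genomes = []
    for s in strains:
        parent = anc_a if clade_map[s] == "A" else anc_b
        g, truth = evolve(parent, s, config, truth)
        genomes.append(g)
    presence: dict[str, set[str]] = {}
    for g in genomes:
        for f in g.features:
            if f.gene_symbol:
                presence.setdefault(f.gene_symbol, set()).add(g.genome_id)
    return genomes, PanelTruth(
        clade_map=clade_map, gene_presence=presence, lttr_counts=lttr_counts, truth=truth
    )


def write_lineage(outdir, genome: GenomeRecord, truth: SimulationTruth) -> None:
    """Write FASTA + GFF3 + truth JSON for one genome."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(outdir / f"{genome.genome_id}.fna", [(r[0], r[1]) for r in genome.replicons])
    write_gff3(outdir / f"{genome.genome_id}.gff3", genome)
    (outdir / f"{genome.genome_id}.truth.json").write_text(truth.to_json())
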