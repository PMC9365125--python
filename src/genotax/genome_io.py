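"""Genome I/O: FASTA / GFF3 / gene-TSV reading, the in-memory genome model,
and basic per-genome statistics.

The canonical in-memory objects are :class:`GenomeRecord` (an assembly:
ordered replicons plus gene features) and :class:`GeneFeature`.  Internal
coordinates are always 0-based half-open on the forward strand; files are
read and written in their native conventions (GFF3 is 1-based inclusive).

Ns are tolerated in sequences but excluded from G+C content; alignment
stages treat them as mismatches.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

from .errors import FormatError, ReferenceError_, UndefinedValueError
from ._align import revcomp

_DNA = set("ACGTN")
#: IUPAC ambiguity codes accepted when ``iupac_to_n`` is on.
_IUPAC_EXTRA = set("RYSWKMBDHV")


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene/CDS on a replicon (0-based half-open interval)."""

    feature_id: str
    gene_symbol: str
    product: str
    replicon_id: str
    start: int
    end: int
    strand: str  # '+' or '-'
    protein_seq: str = ""

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"feature {self.feature_id}: invalid interval [{self.start},{self.end})"
            )
        if self.strand not in "+-":
            raise FormatError(f"feature {self.feature_id}: strand must be + or -")


@dataclass
class GenomeRecord:
    """An assembly: ordered replicons with sequences and gene annotations."""

    genome_id: str
    organism_label: str = ""
    replicons: list[tuple[str, str, str]] = field(default_factory=list)
    # each replicon: (replicon_id, sequence, topology 'circular'|'linear')
    source: str = "synthetic"
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self):
        ids = [r[0] for r in self.replicons]
        if len(ids) != len(set(ids)):
            raise FormatError(f"{self.genome_id}: duplicate replicon ids")
        for _, seq, _ in self.replicons:
            extra = set(seq) - _DNA
            if extra:
                raise FormatError(
                    f"{self.genome_id}: illegal characters {sorted(extra)} in sequence"
                )

    @property
    def length(self) -> int:
        return sum(len(s) for _, s, _ in self.replicons)

    def sequence(self, replicon_id: str) -> str:
        for rid, seq, _ in self.replicons:
            if rid == replicon_id:
                return seq
        raise ReferenceError_(f"{self.genome_id}: unknown replicon {replicon_id!r}")

    def feature_sequence(self, feat: GeneFeature) -> str:
        """Forward-strand gene sequence (reverse-complemented for '-')."""
        seq = self.sequence(feat.replicon_id)[feat.start : feat.end]
        return revcomp(seq) if feat.strand == "-" else seq


# ---------------------------------------------------------------------------
# FASTA

def _normalize_sequence(raw: str, name: str, rna_ok: bool, iupac_to_n: bool) -> str:
    seq = raw.upper()
    if rna_ok:
        seq = seq.replace("U", "T")
    if iupac_to_n:
        seq = "".join("N" if c in _IUPAC_EXTRA else c for c in seq)
    extra = set(seq) - _DNA
    if extra:
        raise FormatError(f"record {name!r}: characters outside ACGTN: {sorted(extra)}")
    return seq


def read_fasta(path, rna_ok: bool = False, iupac_to_n: bool = False) -> list[tuple[str, str]]:
    """Read a (multi-)FASTA of DNA into [(id, uppercase sequence), ...].

    ``rna_ok`` maps U->T; ``iupac_to_n`` maps ambiguity codes to N; any
    remaining character outside {A,C,G,T,N} raises :class:`FormatError`.
    """
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        records.append((rec.id, _normalize_sequence(str(rec.seq), rec.id, rna_ok, iupac_to_n)))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    return records


def read_protein_fasta(path) -> list[tuple[str, str]]:
    """Read a protein FASTA (no alphabet normalization beyond uppercasing)."""
    records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    return records


def write_fasta(path, records: list[tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Annotations

_TSV_COLUMNS = ["feature_id", "gene", "product", "replicon", "start", "end", "strand", "protein"]


def read_annotations(path, dialect: str = "gff3", genome: GenomeRecord | None = None) -> list[GeneFeature]:
    """Read gene annotations from GFF3 or a DFAST-style gene TSV.

    File coordinates are 1-based inclusive and converted to 0-based
    half-open.  When ``genome`` is given, replicon ids are validated and
    missing protein sequences are translated from the genome (minus-strand
    features from the reverse complement).
    """
    if dialect == "gff3":
        feats = _read_gff3(path)
    elif dialect == "gene_tsv":
        feats = _read_gene_tsv(path)
    else:
        raise FormatError(f"unknown annotation dialect {dialect!r}")
    if genome is not None:
        known = {r[0]: len(r[1]) for r in genome.replicons}
        out = []
        for f in feats:
            if f.replicon_id not in known:
                raise ReferenceError_(f"feature {f.feature_id}: unknown replicon {f.replicon_id!r}")
            if f.end > known[f.replicon_id]:
                raise FormatError(f"feature {f.feature_id}: end beyond replicon length")
            if not f.protein_seq and (f.end - f.start) % 3 == 0:
                nt = genome.feature_sequence(f)
                f = replace(f, protein_seq=translate_cds(nt))
            out.append(f)
        feats = out
    return feats


def _read_gff3(path) -> list[GeneFeature]:
    feats = []
    for rec in gffutils.iterators.DataIterator(str(path)):
        if rec.featuretype not in ("CDS", "gene", "rRNA"):
            continue
        if rec.end < rec.start:
            raise FormatError(f"GFF3 feature with end < start at {rec.seqid}:{rec.start}")
        attrs = rec.attributes
        fid = (attrs.get("ID") or attrs.get("locus_tag") or [f"{rec.seqid}:{rec.start}"])[0]
        feats.append(
            GeneFeature(
                feature_id=fid,
                gene_symbol=(attrs.get("gene") or [""])[0],
                product=(attrs.get("product") or [""])[0],
                replicon_id=rec.seqid,
                start=rec.start - 1,
                end=rec.end,
                strand=rec.strand if rec.strand in "+-" else "+",
                protein_seq=(attrs.get("protein_seq") or [""])[0],
            )
        )
    return feats


def _read_gene_tsv(path) -> list[GeneFeature]:
    feats = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[: len(_TSV_COLUMNS)] != _TSV_COLUMNS:
            raise FormatError(f"gene TSV header must start with {_TSV_COLUMNS}")
        for line in fh:
            if not line.strip():
                continue
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            start, end = int(row["start"]), int(row["end"])
            if end < start:
                raise FormatError(f"feature {row['feature_id']}: end < start")
            feats.append(
                GeneFeature(
                    feature_id=row["feature_id"],
                    gene_symbol=row.get("gene", ""),
                    product=row.get("product", ""),
                    replicon_id=row["replicon"],
                    start=start - 1,
                    end=end,
                    strand=row["strand"],
                    protein_seq=row.get("protein", ""),
                )
            )
    return feats


def write_gff3(path, genome: GenomeRecord) -> None:
    """Write features as GFF3 (1-based inclusive, CDS records)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rid, seq, _ in genome.replicons:
            fh.write(f"##sequence-region {rid} 1 {len(seq)}\n")
        for f in genome.features:
            attrs = [f"ID={f.feature_id}"]
            if f.gene_symbol:
                attrs.append(f"gene={f.gene_symbol}")
            if f.product:
                attrs.append(f"product={f.product}")
            ftype = "rRNA" if "16S" in (f.gene_symbol or "") else "CDS"
            fh.write(
                f"{f.replicon_id}\tgenotax\t{ftype}\t{f.start + 1}\t{f.end}\t.\t{f.strand}\t0\t"
                + ";".join(attrs)
                + "\n"
            )


def write_gene_tsv(path, genome: GenomeRecord) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for f in genome.features:
            fh.write(
                "\t".join(
                    [
                        f.feature_id,
                        f.gene_symbol,
                        f.product,
                        f.replicon_id,
                        str(f.start + 1),
                        str(f.end),
                        f.strand,
                        f.protein_seq,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Derived quantities

def translate_cds(nt: str) -> str:
    """Translate a forward-strand CDS, trimming a trailing stop codon."""
    prot = str(Seq(nt[: len(nt) - len(nt) % 3]).translate())
    return prot[:-1] if prot.endswith("*") else prot


def gc_content(genome: GenomeRecord) -> float:
    """G+C percentage over all replicons; N excluded; 1-decimal rounding."""
    counts = {b: 0 for b in "ACGT"}
    for _, seq, _ in genome.replicons:
        for b in "ACGT":
            counts[b] += seq.count(b)
    total = sum(counts.values())
    if total == 0:
        raise UndefinedValueError(f"{genome.genome_id}: no unambiguous bases")
    return round(100.0 * (counts["G"] + counts["C"]) / total, 1)


def extract_proteome(genome: GenomeRecord) -> list[tuple[str, str]]:
    """One protein per CDS feature (verbatim if annotated, else translated).

    Features whose length is not divisible by 3 (and carry no protein) or
    whose translation contains an internal stop are skipped; the skip count
    is attached to the returned list as ``.skipped`` is not possible on a
    list, so callers needing the count use :func:`extract_proteome_counted`.
    """
    return extract_proteome_counted(genome)[0]


def extract_proteome_counted(genome: GenomeRecord) -> tuple[list[tuple[str, str]], int]:
    proteins, skipped = [], 0
    for f in genome.features:
        if f.gene_symbol == "16S":
            continue  # rRNA, not a CDS
        if f.protein_seq:
            proteins.append((f.feature_id, f.protein_seq))
            continue
        nt = genome.feature_sequence(f)
        if len(nt) % 3 != 0:
            skipped += 1
            continue
        prot = translate_cds(nt)
        if "*" in prot:
            skipped += 1
            continue
        proteins.append((f.feature_id, prot))
    return proteins, skipped
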