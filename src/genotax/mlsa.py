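"""Multilocus sequence analysis: four-gene supermatrix and distance tree.

Markers (*recA*, *mreB*, *rpoA*, *topA*) are pulled from annotations by
exact (case-insensitive) gene-symbol match — inputs are annotated genomes,
so no homology search is attempted.  Per-gene alignments use a center-star
multiple alignment (center = sequence minimizing summed pairwise edit
distance, others folded in by global alignment); the concatenated
supermatrix keeps partition boundaries.  Trees come from standard
neighbor-joining with negative branch lengths clamped to zero.

The external MSA/network tools of classical MLSA workflows are replaced by
these in-repo equivalents by design: the claim this module supports is
clade membership (monophyly), which is insensitive to alignment polish.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import edlib
import numpy as np

from .errors import GenotaxError, MarkerError
from .genome_io import GenomeRecord
from .ogri import k2_distance
from ._align import aligned_strings

MARKER_GENES = ("recA", "mreB", "rpoA", "topA")


@dataclass
class MarkerSet:
    genome_id: str
    sequences: dict[str, str]  # gene symbol -> nucleotide sequence


@dataclass
class Supermatrix:
    taxa: list[str]
    per_gene: dict[str, list[tuple[str, str]]]  # gene -> [(taxon, aligned row)]
    concatenated: list[tuple[str, str]]
    partitions: list[tuple[str, int, int]]  # (gene, start, end) 1-based inclusive


def extract_markers(genome: GenomeRecord, symbols: tuple[str, ...] = MARKER_GENES) -> MarkerSet:
    """One sequence per requested symbol; missing or duplicated markers are
    hard errors naming the genome and the gene."""
    found: dict[str, list[str]] = {s: [] for s in symbols}
    lower = {s.lower(): s for s in symbols}
    for f in genome.features:
        sym = lower.get(f.gene_symbol.lower()) if f.gene_symbol else None
        if sym is not None:
            found[sym].append(genome.feature_sequence(f))
    missing = [s for s, seqs in found.items() if not seqs]
    if missing:
        raise MarkerError(f"{genome.genome_id}: missing marker(s) {', '.join(missing)}")
    multi = [s for s, seqs in found.items() if len(seqs) > 1]
    if multi:
        raise MarkerError(f"{genome.genome_id}: multi-copy marker(s) {', '.join(multi)}")
    return MarkerSet(genome_id=genome.genome_id, sequences={s: seqs[0] for s, seqs in found.items()})


# ---------------------------------------------------------------------------
# center-star multiple alignment


def _merge_into_center(center_cols: list[str], rows: list[list[str]], pair: tuple[str, str]):
    """Fold one center-vs-new pairwise alignment into the growing MSA.

    ``center_cols`` is the current gapped center row; ``rows`` the already
    aligned other rows.  Gap columns new to either side are inserted so all
    rows stay flush.
    """
    c_aln, n_aln = pair
    out_center, out_new = [], []
    out_rows = [[] for _ in rows]
    i = j = 0  # i over current MSA columns, j over pairwise columns
    while i < len(center_cols) or j < len(c_aln):
        msa_char = center_cols[i] if i < len(center_cols) else None
        pw_char = c_aln[j] if j < len(c_aln) else None
        if msa_char is not None and msa_char == "-" and (pw_char is None or pw_char != "-"):
            # gap already present in MSA center but not in pairwise: keep it
            out_center.append("-")
            for r, row in enumerate(rows):
                out_rows[r].append(row[i])
            out_new.append("-")
            i += 1
        elif pw_char is not None and pw_char == "-" and (msa_char is None or msa_char != "-"):
            # new gap introduced by this sequence
            out_center.append("-")
            for r in range(len(rows)):
                out_rows[r].append("-")
            out_new.append(n_aln[j])
            j += 1
        else:
            out_center.append(msa_char if msa_char is not None else pw_char)
            for r, row in enumerate(rows):
                out_rows[r].append(row[i])
            out_new.append(n_aln[j])
            i += 1
            j += 1
    return out_center, out_rows, out_new


def align_gene(sequences: list[tuple[str, str]]) -> list[tuple[str, str]]:
    """Center-star multiple alignment of named sequences."""
    if not sequences:
        raise GenotaxError("align_gene: empty input")
    if len(sequences) == 1:
        return list(sequences)
    names = [n for n, _ in sequences]
    seqs = [s for _, s in sequences]
    n = len(seqs)
    dist = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = edlib.align(seqs[i], seqs[j], mode="NW")["editDistance"]
        dist[i, j] = dist[j, i] = d
    center = int(np.argmin(dist.sum(axis=1)))
    order = [i for i in range(n) if i != center]
    center_cols = list(seqs[center])
    rows: list[list[str]] = []
    row_names: list[str] = []
    for idx in order:
        pair = aligned_strings(seqs[center], seqs[idx])
        center_cols, rows, new_row = _merge_into_center(center_cols, rows, pair)
        rows.append(new_row)
        row_names.append(names[idx])
    out = {names[center]: "".join(center_cols)}
    for name, row in zip(row_names, rows):
        out[name] = "".join(row)
    return [(name, out[name]) for name in names]


def concatenate(
    per_gene: dict[str, list[tuple[str, str]]],
    gene_order: tuple[str, ...] = MARKER_GENES,
) -> Supermatrix:
    """Row-wise concatenation in fixed gene order with a partition map."""
    genes = [g for g in gene_order if g in per_gene]
    extra = sorted(set(per_gene) - set(genes))
    genes += extra
    if not genes:
        raise GenotaxError("concatenate: no gene alignments")
    taxa = [n for n, _ in per_gene[genes[0]]]
    taxa_set = set(taxa)
    for g in genes:
        have = {n for n, _ in per_gene[g]}
        if have != taxa_set:
            missing = taxa_set ^ have
            raise GenotaxError(f"gene {g}: taxa mismatch ({', '.join(sorted(missing))})")
    rows = {t: [] for t in taxa}
    partitions = []
    pos = 0
    for g in genes:
        table = dict(per_gene[g])
        length = len(next(iter(table.values())))
        if any(len(r) != length for r in table.values()):
            raise GenotaxError(f"gene {g}: ragged alignment")
        partitions.append((g, pos + 1, pos + length))
        pos += length
        for t in taxa:
            rows[t].append(table[t])
    concatenated = [(t, "".join(rows[t])) for t in taxa]
    return Supermatrix(taxa=taxa, per_gene=per_gene, concatenated=concatenated, partitions=partitions)


def k2_matrix(alignment: list[tuple[str, str]]) -> tuple[list[str], np.ndarray]:
    """Pairwise K2 distance matrix over an alignment."""
    names = [n for n, _ in alignment]
    rows = [r for _, r in alignment]
    n = len(names)
    mat = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = k2_distance(rows[i], rows[j]).d
        mat[i, j] = mat[j, i] = d
    return names, mat


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(dist: np.ndarray, labels: list[str]) -> str:
    """Standard neighbor-joining; returns Newick with branch lengths
    (6 decimals), negative branch lengths clamped to 0."""
    dist = np.asarray(dist, dtype=float)
    if dist.shape[0] != dist.shape[1] or dist.shape[0] != len(labels):
        raise GenotaxError("distance matrix / label size mismatch")
    if np.abs(dist - dist.T).max() > 1e-9:
        raise GenotaxError("distance matrix not symmetric")
    n = len(labels)
    if n == 1:
        return f"{labels[0]};"
    nodes = [f"{lab}" for lab in labels]
    D = dist.copy()
    active = list(range(n))

    def bl(x: float) -> str:
        return f"{max(0.0, x):.6f}"

    while len(active) > 2:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = np.unravel_index(np.argmin(q), q.shape)
        if i > j:
            i, j = j, i
        ai, aj = active[i], active[j]
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        new = f"({nodes[ai]}:{bl(li)},{nodes[aj]}:{bl(lj)})"
        # distances from the new node to the rest
        dnew = 0.5 * (sub[i, :] + sub[j, :] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        for idx, a in enumerate(active):
            D[-1, a] = D[a, -1] = dnew[idx]
        nodes.append(new)
        active = [a for a in active if a not in (ai, aj)] + [D.shape[0] - 1]

    a, b = active
    if len(labels) == 2:
        half = D[a, b] / 2.0
        return f"({nodes[a]}:{bl(half)},{nodes[b]}:{bl(half)});"
    return f"({nodes[a]}:{bl(D[a, b])},{nodes[b]}:0.000000);"


def mlsa_tree(genomes: list[GenomeRecord], symbols: tuple[str, ...] = MARKER_GENES) -> tuple[Supermatrix, str]:
    """Full MLSA pipeline: extract markers, align each gene, concatenate,
    K2 distances, NJ tree."""
    marker_sets = [extract_markers(g, symbols) for g in genomes]
    per_gene = {}
    for sym in symbols:
        per_gene[sym] = align_gene([(ms.genome_id, ms.sequences[sym]) for ms in marker_sets])
    sm = concatenate(per_gene, symbols)
    names, mat = k2_matrix(sm.concatenated)
    return sm, nj_tree(mat, names)


def newick_bipartitions(newick: str) -> set[frozenset[str]]:
    """Non-trivial leaf bipartitions (as the smaller-side leaf sets) of an
    unrooted tree, for topology comparisons."""
    import re

    tokens = re.findall(r"\(|\)|[^(),;:]+|,|;|:", newick)
    stack: list[list[set[str]]] = []
    all_leaves: set[str] = set()
    clades: list[set[str]] = []
    i = 0
    current: set[str] | None = None
    while i < len(tokens):
        tok = tokens[i]
        if tok == "(":
            stack.append([])
            i += 1
        elif tok == ")":
            group = stack.pop()
            merged = set().union(*group)
            clades.append(merged)
            current = merged
            if stack:
                stack[-1].append(merged)
            i += 1
        elif tok == ",":
            i += 1
        elif tok == ":":
            i += 2  # skip branch length
        elif tok in (";",):
            i += 1
        else:
            leaf = tok.strip()
            if leaf:
                all_leaves.add(leaf)
                if stack:
                    stack[-1].append({leaf})
                current = {leaf}
            i += 1
    out = set()
    for clade in clades:
        if 1 < len(clade) < len(all_leaves) - 1:
            other = all_leaves - clade
            out.add(frozenset(min(clade, other, key=lambda s: (len(s), sorted(s)))))
    return out


def is_monophyletic(newick: str, group: set[str]) -> bool:
    """Whether ``group`` forms one side of some bipartition of the tree."""
    leaves = set()
    import re

    for tok in re.findall(r"[^(),;:]+", newick):
        name = tok.strip()
        if name and not _is_number(name):
            leaves.add(name)
    group = set(group)
    if len(group) <= 1 or group == leaves:
        return True
    target = frozenset(min(group, leaves - group, key=lambda s: (len(s), sorted(s))))
    return target in newick_bipartitions(newick)


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False
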