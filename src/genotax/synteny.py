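"""Whole-genome synteny: k-mer dotplot, collinear block chaining and
inversion inference.

Match points are exact shared k-mers (default k = 21) between two genomes,
on both strands, with repeat masking: a k-mer occurring more than
``max_frequency`` times in either genome is discarded.  Points are chained
greedily into strand-consistent monotone runs; each maximal run of
reverse-oriented blocks flanked by forward blocks is called one inversion
event.  Replicons flagged as plasmids are excluded from comparisons.
"""

from __future__ import annotations

import numpy as np

from .errors import GenotaxError
from .genome_io import GenomeRecord
from ._align import encode, kmer_codes

from dataclasses import dataclass

#: structured dtype of dotplot match points
POINT_DTYPE = np.dtype(
    [("a_pos", np.int64), ("b_pos", np.int64), ("strand", "U1"), ("length", np.int32)]
)


@dataclass(frozen=True)
class SyntenyBlock:
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    orientation: str  # '+' or '-'
    n_points: int


@dataclass(frozen=True)
class InversionEvent:
    a_start: int
    a_end: int
    b_start: int
    b_end: int

    @property
    def size(self) -> int:
        return self.a_end - self.a_start


def _concat_sequence(genome: GenomeRecord, include_plasmids: bool) -> str:
    parts = []
    for rid, seq, _ in genome.replicons:
        if not include_plasmids and "plasmid" in rid.lower():
            continue
        parts.append(seq)
    return "N".join(parts)  # N spacer invalidates k-mers crossing boundaries


def _masked_kmers(seq: str, k: int, max_frequency: int):
    pos, km = kmer_codes(encode(seq), k)
    order = np.argsort(km, kind="stable")
    skm, spos = km[order], pos[order]
    # frequency mask
    uniq, counts = np.unique(skm, return_counts=True)
    bad = uniq[counts > max_frequency]
    keep = ~np.isin(skm, bad)
    return skm[keep], spos[keep]


def _join(km_a, pos_a, km_b, pos_b):
    lo = np.searchsorted(km_b, km_a, side="left")
    hi = np.searchsorted(km_b, km_a, side="right")
    counts = hi - lo
    qidx = np.repeat(np.arange(km_a.size), counts)
    if qidx.size == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    starts = np.repeat(lo, counts)
    offs = np.arange(qidx.size) - np.repeat(
        np.concatenate(([0], np.cumsum(counts)[:-1])), counts
    )
    return pos_a[qidx], pos_b[starts + offs]


def dotplot_points(
    genome_a: GenomeRecord,
    genome_b: GenomeRecord,
    k: int = 21,
    max_frequency: int = 4,
    include_plasmids: bool = False,
) -> np.ndarray:
    """Shared-k-mer match points (structured array sorted by a_pos)."""
    if k < 11:
        raise GenotaxError("k < 11 would admit spurious matches")
    seq_a = _concat_sequence(genome_a, include_plasmids)
    seq_b = _concat_sequence(genome_b, include_plasmids)
    if len(seq_a) < k or len(seq_b) < k:
        raise GenotaxError("genome shorter than k")
    from ._align import revcomp

    km_a, pos_a = _masked_kmers(seq_a, k, max_frequency)
    km_bf, pos_bf = _masked_kmers(seq_b, k, max_frequency)
    a_f, b_f = _join(km_a, pos_a, km_bf, pos_bf)
    # reverse strand: match A against the reverse complement of B and map
    # coordinates back to forward-B (position of the k-mer's left end)
    seq_b_rc = revcomp(seq_b)
    km_br, pos_br = _masked_kmers(seq_b_rc, k, max_frequency)
    a_r, b_rc = _join(km_a, pos_a, km_br, pos_br)
    b_r = len(seq_b) - b_rc - k
    points = np.empty(a_f.size + a_r.size, dtype=POINT_DTYPE)
    points["a_pos"][: a_f.size] = a_f
    points["b_pos"][: a_f.size] = b_f
    points["strand"][: a_f.size] = "+"
    points["a_pos"][a_f.size :] = a_r
    points["b_pos"][a_f.size :] = b_r
    points["strand"][a_f.size :] = "-"
    points["length"] = k
    points.sort(order=["a_pos", "b_pos"])
    return points


def chain_blocks(points: np.ndarray, max_gap: int = 20000, min_points: int = 5) -> list[SyntenyBlock]:
    """Greedy chaining of strand-consistent monotone runs.

    Consecutive points (by a_pos) extend the current chain when the strand
    matches, the a-gap is within ``max_gap``, and b moves monotonically
    (increasing for '+', decreasing for '-') by at most ``max_gap``.
    Chains shorter than ``min_points`` are dropped.
    """
    blocks: list[SyntenyBlock] = []
    if points.size == 0:
        return blocks
    a = points["a_pos"]
    b = points["b_pos"]
    s = points["strand"]
    k = int(points["length"][0]) if points.size else 0

    start = 0
    for i in range(1, points.size + 1):
        ok = False
        if i < points.size:
            da = a[i] - a[i - 1]
            db = b[i] - b[i - 1]
            if s[i] == s[i - 1] and 0 <= da <= max_gap:
                ok = (0 <= db <= max_gap) if s[i] == "+" else (-max_gap <= db <= 0)
        if not ok:
            n = i - start
            if n >= min_points:
                bs = b[start:i]
                blocks.append(
                    SyntenyBlock(
                        a_start=int(a[start]),
                        a_end=int(a[i - 1]) + k,
                        b_start=int(bs.min()),
                        b_end=int(bs.max()) + k,
                        orientation=str(s[start]),
                        n_points=int(n),
                    )
                )
            start = i
    return blocks


def detect_inversions(blocks: list[SyntenyBlock]) -> list[InversionEvent]:
    """Each maximal run of '-' blocks flanked by '+' blocks is one event."""
    events = []
    i = 0
    n = len(blocks)
    while i < n:
        if blocks[i].orientation == "-":
            j = i
            while j < n and blocks[j].orientation == "-":
                j += 1
            flanked = i > 0 and j < n  # '+' on both sides by construction of the scan
            if flanked:
                run = blocks[i:j]
                events.append(
                    InversionEvent(
                        a_start=min(bl.a_start for bl in run),
                        a_end=max(bl.a_end for bl in run),
                        b_start=min(bl.b_start for bl in run),
                        b_end=max(bl.b_end for bl in run),
                    )
                )
            i = j
        else:
            i += 1
    return events


def find_inversions(
    genome_a: GenomeRecord,
    genome_b: GenomeRecord,
    k: int = 21,
    max_frequency: int = 4,
    max_gap: int = 20000,
    min_points: int = 5,
) -> tuple[np.ndarray, list[SyntenyBlock], list[InversionEvent]]:
    """Dotplot + chaining + inversion inference in one call."""
    points = dotplot_points(genome_a, genome_b, k=k, max_frequency=max_frequency)
    blocks = chain_blocks(points, max_gap=max_gap, min_points=min_points)
    return points, blocks, detect_inversions(blocks)
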