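"""Internal pairwise-alignment and k-mer machinery.

Everything here is a private backend: the public metric modules (ogri,
pangenome, synteny, mlsa) define *what* is measured; this module only
supplies fast primitives — edlib-based alignment with identity bookkeeping,
2-bit sequence encoding, and rolling k-mer code arrays.

The alignment contract used throughout: given two sequences, return the
identity (matches / alignment columns), the number of matches, the number
of alignment columns, and the matched target interval.  Ns never count as
matches (edlib treats distinct characters as mismatches and 'N' vs 'N' as
equal; sequences are pre-screened so N-rich fragments are discarded before
alignment).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib
import numpy as np

_RC = str.maketrans("ACGTN", "TGCAN")

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")

#: 2-bit base codes; N = 4 marks an invalid window position.
_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def encode(seq: str) -> np.ndarray:
    """Map a DNA string to uint8 codes (A0 C1 G2 T3, anything else 4)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Rolling k-mer integer codes over a 2-bit encoded sequence.

    Returns ``(positions, kmers)`` keeping only windows free of N.
    """
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.uint64)
    out = np.zeros(n, dtype=np.uint64)
    bad = np.zeros(n, dtype=bool)
    for j in range(k):
        col = codes[j : j + n]
        out = (out << np.uint64(2)) | (col & np.uint8(3)).astype(np.uint64)
        bad |= col == 4
    pos = np.nonzero(~bad)[0]
    return pos, out[pos]


@dataclass(frozen=True)
class AlignmentResult:
    identity: float          # matches / alignment columns
    matches: int
    columns: int             # alignment length incl. indel columns
    target_start: int        # matched interval on the target (half-open)
    target_end: int

    @property
    def distance(self) -> float:
        return 1.0 - self.identity


def _parse_cigar(cigar: str, edit_distance: int) -> tuple[int, int]:
    """Return (matches, columns) from an edlib cigar.

    edlib emits extended cigars ('='/'X'); a plain 'M' (match-or-mismatch)
    is resolved through the edit distance: X + I + D = distance.
    """
    eq = x = ins = dele = m = 0
    for num, op in _CIGAR_RE.findall(cigar):
        n = int(num)
        if op == "=":
            eq += n
        elif op == "X":
            x += n
        elif op == "I":
            ins += n
        elif op == "D":
            dele += n
        else:
            m += n
    if m:  # standard cigar fallback
        x = edit_distance - ins - dele
        eq = m - x
    return eq, eq + x + ins + dele


def align(query: str, target: str, mode: str = "NW") -> AlignmentResult | None:
    """Align query to target with edlib and report identity.

    mode "NW": global/global.  mode "HW": query global, target local
    (infix), the work-horse for fragment-vs-window searches.
    """
    if not query or not target:
        return None
    res = edlib.align(query, target, mode=mode, task="path")
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    matches, columns = _parse_cigar(res["cigar"], res["editDistance"])
    if columns == 0:
        return None
    t0, t1 = res["locations"][0]
    return AlignmentResult(
        identity=matches / columns,
        matches=matches,
        columns=columns,
        target_start=int(t0),
        target_end=int(t1) + 1,
    )


def aligned_strings(a: str, b: str) -> tuple[str, str]:
    """Global alignment of two sequences, returned as gapped strings."""
    res = edlib.align(a, b, mode="NW", task="path")
    nice = edlib.getNiceAlignment(res, a, b)
    return nice["query_aligned"], nice["target_aligned"]


class KmerIndex:
    """Sorted k-mer index of one nucleotide sequence (forward strand).

    Supports candidate-location voting for a query sequence: shared k-mers
    cast votes for an alignment offset band; the best bands are verified by
    an actual alignment downstream.
    """

    def __init__(self, seq: str, k: int):
        self.k = k
        self.length = len(seq)
        pos, km = kmer_codes(encode(seq), k)
        order = np.argsort(km, kind="stable")
        self._kmers = km[order]
        self._pos = pos[order]

    def lookup(self, kmers: np.ndarray, max_hits_per_kmer: int = 8) -> tuple[np.ndarray, np.ndarray]:
        """Return (query_index, target_position) pairs for shared k-mers."""
        if kmers.size == 0 or self._kmers.size == 0:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        lo = np.searchsorted(self._kmers, kmers, side="left")
        hi = np.searchsorted(self._kmers, kmers, side="right")
        counts = np.minimum(hi - lo, max_hits_per_kmer)
        qidx = np.repeat(np.arange(kmers.size), counts)
        if qidx.size == 0:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        # ragged gather of target positions
        starts = np.repeat(lo, counts)
        offs = np.arange(qidx.size) - np.repeat(
            np.concatenate(([0], np.cumsum(counts)[:-1])), counts
        )
        tpos = self._pos[starts + offs]
        return qidx, tpos

    def candidate_offsets(
        self,
        query: str,
        stride: int = 4,
        band: int = 256,
        top: int = 3,
        max_hits_per_kmer: int = 8,
    ) -> list[int]:
        """Vote on diagonal offsets (target_pos - query_pos) for a query.

        Returns up to ``top`` offset-band representatives, most-supported
        first; ties broken toward the lower offset for determinism.
        """
        codes = encode(query)
        pos, km = kmer_codes(codes, self.k)
        if pos.size == 0:
            return []
        sel = slice(0, None, stride)
        qidx, tpos = self.lookup(km[sel], max_hits_per_kmer)
        if qidx.size == 0:
            return []
        offsets = tpos - pos[sel][qidx]
        bands = offsets // band
        uniq, counts = np.unique(bands, return_counts=True)
        order = np.lexsort((uniq, -counts))
        return [int(uniq[i]) * band for i in order[:top]]
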