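"""Overall genome relatedness indices: ANI, AAI, in silico DDH and
K2-corrected 16S similarity.

ANI follows the orthologous-fragment convention: both genomes are cut into
consecutive 1,020 bp windows, each fragment is searched against the whole
partner genome on both strands, and a fragment pair counts as orthologous
only when each fragment is the other's best hit.  The reported value is the
mean identity over orthologous pairs, averaged over both directions.

in silico DDH uses distance formula ``d2 = 1 - sum(identities)/sum(HSP
length)`` over ungapped high-scoring segment pairs found by k-mer
seed-and-extend, transformed to a hybridization percentage by a strictly
decreasing logistic map (:class:`DdhModel`).  The default coefficients are
a calibration of that map to the canonical inter-genome correspondences
(ANI 95% <-> dDDH 70% at the species boundary, and the mid-30s dDDH regime
around 89% ANI); they are configuration, not constants of nature, and a
reimplementation tolerance of about +/-2 percentage points against the
reference web service should be assumed.

AAI is the mean identity over reciprocal best-hit protein pairs.

The pairwise-alignment backend is a pluggable contract (two sequences in;
identity, aligned length and coordinates out); the default backend is
edlib.  Ties in best-hit selection break toward the lower subject
coordinate, then the lexicographically smaller replicon id.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .errors import GenotaxError, UndefinedValueError
from .genome_io import GenomeRecord
from ._align import KmerIndex, align, aligned_strings, encode, kmer_codes, revcomp

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FragmentHit:
    query_fragment_index: int
    subject_replicon_id: str
    subject_start: int
    subject_end: int
    strand: str
    identity: float
    alignment_length: int


@dataclass
class OgriResult:
    """One pairwise relatedness metric with its support counts."""

    genome_a: str
    genome_b: str
    metric: str  # ANI | AAI | dDDH | 16S
    value: float  # percent
    support: int
    parameters: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.value <= 100.0):
            raise GenotaxError(f"{self.metric}: value {self.value} outside [0,100]")


# ---------------------------------------------------------------------------
# fragmentation + ANI


@dataclass(frozen=True)
class Fragment:
    index: int
    replicon_id: str
    start: int
    sequence: str


def fragment_genome(genome: GenomeRecord, fragment_length: int = 1020, max_n_fraction: float = 0.2) -> list[Fragment]:
    """Consecutive non-overlapping windows per replicon; the trailing
    remainder and N-rich fragments (> 20% N) are discarded."""
    fragments = []
    dropped = 0
    idx = 0
    for rid, seq, _ in genome.replicons:
        for start in range(0, len(seq) - fragment_length + 1, fragment_length):
            window = seq[start : start + fragment_length]
            if window.count("N") > max_n_fraction * fragment_length:
                dropped += 1
                continue
            fragments.append(Fragment(idx, rid, start, window))
            idx += 1
    if dropped:
        logger.info("fragment_genome: dropped %d N-rich fragments", dropped)
    if not fragments:
        raise UndefinedValueError(
            f"{genome.genome_id}: shorter than one fragment ({fragment_length} bp)"
        )
    return fragments


class _GenomeIndex:
    """Per-replicon k-mer indexes of one genome, for fragment searches."""

    def __init__(self, genome: GenomeRecord, k: int = 12):
        self.replicons = [(rid, seq) for rid, seq, _ in genome.replicons]
        self.indexes = {rid: KmerIndex(seq, k) for rid, seq in self.replicons}

    BAND = 256

    def best_hit(self, frag: Fragment, min_identity: float, min_coverage: float) -> FragmentHit | None:
        frag_len = len(frag.sequence)
        margin = max(64, frag_len // 8)
        best: FragmentHit | None = None
        for rid, seq in sorted(self.replicons):
            index = self.indexes[rid]
            for strand, query in (("+", frag.sequence), ("-", revcomp(frag.sequence))):
                for off in index.candidate_offsets(query, band=self.BAND):
                    # the offset is a band floor: the window must span the
                    # whole band plus slack for indels on either side
                    lo = max(0, off - margin)
                    hi = min(len(seq), off + self.BAND + frag_len + margin)
                    if hi - lo < frag_len * min_coverage:
                        continue
                    res = align(query, seq[lo:hi], mode="HW")
                    if res is None:
                        continue
                    # the query is fully consumed in HW mode, so coverage is
                    # the alignment length against the fragment length
                    if res.columns < min_coverage * frag_len or res.identity < min_identity:
                        continue
                    s0, s1 = lo + res.target_start, lo + res.target_end
                    cand = FragmentHit(frag.index, rid, s0, s1, strand, res.identity, res.columns)
                    if (
                        best is None
                        or cand.identity > best.identity
                        or (
                            cand.identity == best.identity
                            and (cand.subject_start, cand.subject_replicon_id)
                            < (best.subject_start, best.subject_replicon_id)
                        )
                    ):
                        best = cand
        return best


def _directional_hits(
    frags: list[Fragment], target: GenomeRecord, params: dict
) -> dict[int, FragmentHit]:
    index = _GenomeIndex(target, k=params["seed_k"])
    hits = {}
    for frag in frags:
        hit = index.best_hit(frag, params["min_identity"], params["min_coverage"])
        if hit is not None:
            hits[frag.index] = hit
    return hits


def _fragment_of(frags: list[Fragment], replicon_id: str, pos: int, fragment_length: int) -> int | None:
    """Fragment index of the partner genome containing a subject position."""
    for f in frags:
        if f.replicon_id == replicon_id and f.start <= pos < f.start + fragment_length:
            return f.index
    return None


def compute_ani(
    genome_a: GenomeRecord,
    genome_b: GenomeRecord,
    fragment_length: int = 1020,
    min_identity: float = 0.35,
    min_coverage: float = 0.70,
    seed_k: int = 12,
) -> OgriResult:
    """Orthologous-fragment average nucleotide identity (percent)."""
    params = dict(
        fragment_length=fragment_length,
        min_identity=min_identity,
        min_coverage=min_coverage,
        seed_k=seed_k,
    )
    frags_a = fragment_genome(genome_a, fragment_length)
    frags_b = fragment_genome(genome_b, fragment_length)
    hits_ab = _directional_hits(frags_a, genome_b, params)
    hits_ba = _directional_hits(frags_b, genome_a, params)

    # map hit midpoints onto partner fragment indices for reciprocity
    by_pos_b = {(f.replicon_id, f.start // fragment_length): f.index for f in frags_b}
    by_pos_a = {(f.replicon_id, f.start // fragment_length): f.index for f in frags_a}

    def partner(hit: FragmentHit, table) -> int | None:
        mid = (hit.subject_start + hit.subject_end) // 2
        return table.get((hit.subject_replicon_id, mid // fragment_length))

    identities = []
    pairs = 0
    for ia, hit in hits_ab.items():
        ib = partner(hit, by_pos_b)
        if ib is None or ib not in hits_ba:
            continue
        back = hits_ba[ib]
        if partner(back, by_pos_a) == ia:
            identities.append((hit.identity + back.identity) / 2.0)
            pairs += 1
    if pairs == 0:
        raise UndefinedValueError(
            f"ANI undefined for {genome_a.genome_id} vs {genome_b.genome_id}: no orthologous fragment pairs"
        )
    return OgriResult(
        genome_a=genome_a.genome_id,
        genome_b=genome_b.genome_id,
        metric="ANI",
        value=100.0 * float(np.mean(identities)),
        support=pairs,
        parameters=params,
    )


# ---------------------------------------------------------------------------
# AAI


def _protein_kmers(seq: str, k: int = 6) -> set[str]:
    return {seq[i : i + k] for i in range(0, len(seq) - k + 1)}


def _best_protein_hits(
    prots_a: list[tuple[str, str]],
    prots_b: list[tuple[str, str]],
    min_identity: float,
    min_coverage: float,
) -> dict[str, tuple[str, float]]:
    """Best hit in B for each protein of A, via a shared-k-mer prefilter
    verified by global alignment."""
    inv: dict[str, list[int]] = {}
    for j, (_, seq) in enumerate(prots_b):
        for km in _protein_kmers(seq):
            inv.setdefault(km, []).append(j)
    hits = {}
    for pid, seq in prots_a:
        votes = Counter()
        for km in _protein_kmers(seq):
            for j in inv.get(km, ()):
                votes[j] += 1
        best = None
        for j, _ in votes.most_common(12):
            bid, bseq = prots_b[j]
            if min(len(seq), len(bseq)) < min_coverage * max(len(seq), len(bseq)):
                continue
            res = align(seq, bseq, mode="NW")
            if res is None or res.identity < min_identity:
                continue
            cand = (res.identity, bid)
            if best is None or cand[0] > best[0] or (cand[0] == best[0] and cand[1] < best[1]):
                best = cand
        if best is not None:
            hits[pid] = (best[1], best[0])
    return hits


def compute_aai(
    proteome_a: list[tuple[str, str]],
    proteome_b: list[tuple[str, str]],
    min_identity: float = 0.30,
    min_coverage: float = 0.70,
    min_proteins: int = 100,
    genome_a: str = "A",
    genome_b: str = "B",
) -> OgriResult:
    """Average amino acid identity over reciprocal best-hit pairs (percent)."""
    if len(proteome_a) < min_proteins or len(proteome_b) < min_proteins:
        raise UndefinedValueError(
            f"AAI needs at least {min_proteins} proteins per genome "
            f"(got {len(proteome_a)}, {len(proteome_b)})"
        )
    ab = _best_protein_hits(proteome_a, proteome_b, min_identity, min_coverage)
    ba = _best_protein_hits(proteome_b, proteome_a, min_identity, min_coverage)
    identities = []
    for pid, (bid, ident) in ab.items():
        back = ba.get(bid)
        if back is not None and back[0] == pid:
            identities.append((ident + back[1]) / 2.0)
    if not identities:
        raise UndefinedValueError(f"AAI undefined: no reciprocal best-hit pairs")
    return OgriResult(
        genome_a=genome_a,
        genome_b=genome_b,
        metric="AAI",
        value=100.0 * float(np.mean(identities)),
        support=len(identities),
        parameters=dict(min_identity=min_identity, min_coverage=min_coverage),
    )


# ---------------------------------------------------------------------------
# in silico DDH


@dataclass(frozen=True)
class DdhModel:
    """Monotone map from formula-2 distance to a DDH percentage.

    value = 100 / (1 + exp(intercept + slope * d2)); strictly decreasing in
    d2 for slope > 0, bounded in (0, 100).
    """

    intercept: float = -2.0183
    slope: float = 23.42

    def __call__(self, d2: float) -> float:
        return 100.0 / (1.0 + math.exp(self.intercept + self.slope * d2))


@dataclass(frozen=True)
class Hsp:
    a_start: int
    a_end: int
    identity: float
    matches: int

    @property
    def length(self) -> int:
        return self.a_end - self.a_start


def _diagonal_hsps(
    codes_a: np.ndarray,
    codes_b: np.ndarray,
    offset: int,
    seed_lo: int,
    seed_hi: int,
    pad: int,
    xdrop: int,
    mismatch_penalty: int,
    min_length: int,
) -> list[Hsp]:
    """Ungapped maximal-scoring segments on one diagonal (b = a + offset).

    Scores +1 per match, -penalty per mismatch; segments are cut where the
    running score drops more than ``xdrop`` below its maximum.
    """
    a_lo = max(0, seed_lo - pad, -offset)
    a_hi = min(codes_a.size, seed_hi + pad, codes_b.size - offset)
    if a_hi - a_lo < min_length:
        return []
    a = codes_a[a_lo:a_hi]
    b = codes_b[a_lo + offset : a_hi + offset]
    match = (a == b) & (a != 4) & (b != 4)
    score = np.where(match, 1, -mismatch_penalty).astype(np.int64)
    cum = np.cumsum(score)
    run_max = np.maximum.accumulate(cum)
    cut = np.nonzero(run_max - cum > xdrop)[0]
    hsps = []
    prev = 0
    for nxt in np.concatenate((cut, [match.size])):
        if nxt <= prev:
            prev = nxt + 1
            continue
        seg_cum = cum[prev : nxt + 1] - (cum[prev - 1] if prev > 0 else 0)
        peak = int(np.argmax(seg_cum))
        valley = int(np.argmin(seg_cum[: peak + 1])) if peak > 0 else -1
        start = prev + valley + 1 if valley >= 0 and seg_cum[valley] < 0 else prev
        end = prev + peak + 1
        if end - start >= min_length:
            m = int(match[start:end].sum())
            hsps.append(Hsp(a_lo + start, a_lo + end, m / (end - start), m))
        prev = nxt + 1
    return hsps


def _find_hsps(seq_a: str, seq_b: str, k: int, min_seeds: int, xdrop: int, mismatch_penalty: int, min_length: int) -> list[Hsp]:
    codes_a = encode(seq_a)
    hsps: list[Hsp] = []
    for strand, sb in (("+", seq_b), ("-", revcomp(seq_b))):
        codes_b = encode(sb)
        pos_a, km_a = kmer_codes(codes_a, k)
        pos_b, km_b = kmer_codes(codes_b, k)
        order_b = np.argsort(km_b, kind="stable")
        skm, spos = km_b[order_b], pos_b[order_b]
        lo = np.searchsorted(skm, km_a, side="left")
        hi = np.searchsorted(skm, km_a, side="right")
        counts = np.minimum(hi - lo, 4)
        qidx = np.repeat(np.arange(km_a.size), counts)
        if qidx.size == 0:
            continue
        starts = np.repeat(lo, counts)
        offs = np.arange(qidx.size) - np.repeat(
            np.concatenate(([0], np.cumsum(counts)[:-1])), counts
        )
        tpos = spos[starts + offs]
        apos = pos_a[qidx]
        diag = tpos - apos
        for off in np.unique(diag):
            sel = diag == off
            if int(sel.sum()) < min_seeds:
                continue
            a_sel = apos[sel]
            hsps.extend(
                _diagonal_hsps(
                    codes_a,
                    codes_b,
                    int(off),
                    int(a_sel.min()),
                    int(a_sel.max()) + k,
                    pad=2000,
                    xdrop=xdrop,
                    mismatch_penalty=mismatch_penalty,
                    min_length=min_length,
                )
            )
    # resolve overlaps on the A axis, keeping the higher-identity HSP
    hsps.sort(key=lambda h: (-h.identity, h.a_start))
    kept: list[Hsp] = []
    occupied: list[tuple[int, int]] = []
    for h in hsps:
        overlap = sum(
            max(0, min(h.a_end, e) - max(h.a_start, s)) for s, e in occupied
        )
        if overlap > 0.5 * h.length:
            continue
        kept.append(h)
        occupied.append((h.a_start, h.a_end))
    return kept


def compute_isddh(
    genome_a: GenomeRecord,
    genome_b: GenomeRecord,
    model: DdhModel = DdhModel(),
    seed_k: int = 15,
    min_seeds: int = 2,
    xdrop: int = 30,
    mismatch_penalty: int = 2,
    min_hsp_length: int = 100,
) -> OgriResult:
    """in silico DDH, distance formula 2 over ungapped HSPs (percent)."""
    seq_a = "".join(s for _, s, _ in genome_a.replicons)
    seq_b = "".join(s for _, s, _ in genome_b.replicons)
    hsps = _find_hsps(seq_a, seq_b, seed_k, min_seeds, xdrop, mismatch_penalty, min_hsp_length)
    total = sum(h.length for h in hsps)
    if total == 0:
        raise UndefinedValueError(
            f"dDDH undefined for {genome_a.genome_id} vs {genome_b.genome_id}: no HSPs"
        )
    matches = sum(h.matches for h in hsps)
    d2 = 1.0 - matches / total
    return OgriResult(
        genome_a=genome_a.genome_id,
        genome_b=genome_b.genome_id,
        metric="dDDH",
        value=model(d2),
        support=total,
        parameters=dict(
            d2=d2,
            seed_k=seed_k,
            xdrop=xdrop,
            mismatch_penalty=mismatch_penalty,
            min_hsp_length=min_hsp_length,
            intercept=model.intercept,
            slope=model.slope,
            n_hsps=len(hsps),
        ),
    )


# ---------------------------------------------------------------------------
# Kimura two-parameter distance and 16S similarity


@dataclass(frozen=True)
class K2Distance:
    P: float  # transition proportion
    Q: float  # transversion proportion
    d: float  # substitutions per site
    aligned_length: int

    @property
    def similarity(self) -> float:
        """Similarity convention: 100 * (1 - d)."""
        return 100.0 * (1.0 - self.d)


_PURINE = {"A", "G"}
_PYRIMIDINE = {"C", "T"}


def k2_distance(aligned_a: str, aligned_b: str) -> K2Distance:
    """Kimura 2-parameter distance between two equal-length aligned
    sequences; columns with a gap or N in either sequence are excluded."""
    if len(aligned_a) != len(aligned_b):
        raise GenotaxError("aligned sequences must have equal length")
    n = p = q = 0
    for x, y in zip(aligned_a.upper(), aligned_b.upper()):
        if x in "-N." or y in "-N.":
            continue
        n += 1
        if x == y:
            continue
        if (x in _PURINE and y in _PURINE) or (x in _PYRIMIDINE and y in _PYRIMIDINE):
            p += 1
        else:
            q += 1
    if n == 0:
        raise UndefinedValueError("no comparable columns")
    P, Q = p / n, q / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise UndefinedValueError(f"K2 distance saturated (P={P:.4f}, Q={Q:.4f})")
    d = -0.5 * math.log(w1 * math.sqrt(w2))
    return K2Distance(P=P, Q=Q, d=d, aligned_length=n)


def compute_16s_similarity(
    seq_a: str,
    seq_b: str,
    mode: str = "k2",
    genome_a: str = "A",
    genome_b: str = "B",
) -> OgriResult:
    """Pairwise 16S similarity from a global alignment of two gene
    sequences; ``mode='k2'`` reports 100*(1-d_K2), ``mode='identity'``
    reports raw percent identity over aligned non-gap columns."""
    ga, gb = aligned_strings(seq_a, seq_b)
    if mode == "k2":
        k2 = k2_distance(ga, gb)
        value, support = k2.similarity, k2.aligned_length
        params = dict(mode=mode, P=k2.P, Q=k2.Q, d=k2.d)
    elif mode == "identity":
        pairs = [
            (x, y) for x, y in zip(ga, gb) if x not in "-N." and y not in "-N."
        ]
        if not pairs:
            raise UndefinedValueError("no comparable columns")
        ident = sum(1 for x, y in pairs if x == y) / len(pairs)
        value, support, params = 100.0 * ident, len(pairs), dict(mode=mode)
    else:
        raise GenotaxError(f"unknown 16S mode {mode!r}")
    return OgriResult(
        genome_a=genome_a, genome_b=genome_b, metric="16S", value=max(0.0, value),
        support=support, parameters=params,
    )


def trim_to_reference_window(
    alignment: list[tuple[str, str]], reference_id: str, start: int = 54, end: int = 1390
) -> list[tuple[str, str]]:
    """Restrict a multiple alignment to the columns covering positions
    ``start..end`` (1-based inclusive) of the *ungapped* reference row."""
    ref = dict(alignment).get(reference_id)
    if ref is None:
        raise GenotaxError(f"reference {reference_id!r} not in alignment")
    ungapped = sum(1 for c in ref if c not in "-.")
    if ungapped < end:
        raise GenotaxError(
            f"reference has {ungapped} bases; window {start}-{end} out of range"
        )
    cols = []
    pos = 0
    for i, c in enumerate(ref):
        if c not in "-.":
            pos += 1
            if start <= pos <= end:
                cols.append(i)
    lo, hi = cols[0], cols[-1] + 1
    return [(name, row[lo:hi]) for name, row in alignment]
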