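"""Pangenome clustering and Core / clade-unique binning.

Protein clustering is deterministic greedy incremental clustering: proteins
are sorted by length (descending; ties by genome id then feature id) and
each joins the first existing cluster whose representative aligns at the
identity/coverage thresholds, else founds a new cluster.  This replaces
graph-based MCL clustering on purpose — absolute cluster counts from such
tools are not reproduction targets here; the tested claims are the bin
logic (Core = present in every genome; clade-unique = present in every
member of one clade and absent from the other) and clade-specific gene
placement.

The LysR-type transcriptional regulator (LTTR) comparison is a
case-insensitive keyword count on product annotations followed by a Welch
two-sample t test (scipy backend).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import GenotaxError
from .genome_io import GeneFeature
from ._align import align


@dataclass
class GeneCluster:
    cluster_id: str
    representative: tuple[str, str]  # (genome_id, feature_id)
    members: list[tuple[str, str]] = field(default_factory=list)

    @property
    def presence(self) -> set[str]:
        return {g for g, _ in self.members}


@dataclass(frozen=True)
class BinAssignment:
    cluster_id: str
    bin: str  # Core | cladeA_unique | cladeB_unique | dispensable


def _protein_kmers(seq: str, k: int = 6) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def cluster_proteins(
    proteomes: dict[str, list[tuple[str, str]]],
    min_identity: float = 0.50,
    min_coverage: float = 0.80,
) -> list[GeneCluster]:
    """Greedy incremental clustering of a panel of proteomes.

    ``proteomes``: genome_id -> [(feature_id, protein_seq)].  A protein
    joins the first (oldest) cluster whose representative aligns at
    >= min_identity over >= min_coverage of the shorter sequence.
    """
    if len(proteomes) < 2:
        raise GenotaxError("cluster_proteins needs at least 2 proteomes")
    for gid, prots in proteomes.items():
        if not prots:
            raise GenotaxError(f"empty proteome for {gid}")
    entries = [
        (gid, fid, seq)
        for gid, prots in proteomes.items()
        for fid, seq in prots
    ]
    entries.sort(key=lambda e: (-len(e[2]), e[0], e[1]))
    clusters: list[GeneCluster] = []
    reps: list[str] = []
    inv: dict[str, list[int]] = {}  # protein k-mer -> cluster indexes
    for gid, fid, seq in entries:
        votes = Counter()
        kmers = _protein_kmers(seq)
        for km in kmers:
            for ci in inv.get(km, ()):
                votes[ci] += 1
        placed = None
        for ci in sorted(votes):  # oldest qualifying cluster wins
            rep = reps[ci]
            short, long_ = min(len(seq), len(rep)), max(len(seq), len(rep))
            if short < min_coverage * long_:
                continue
            res = align(seq, rep, mode="NW")
            if res is None or res.identity < min_identity:
                continue
            placed = ci
            break
        if placed is None:
            ci = len(clusters)
            clusters.append(
                GeneCluster(cluster_id=f"GC{ci + 1:06d}", representative=(gid, fid), members=[(gid, fid)])
            )
            reps.append(seq)
            for km in kmers:
                inv.setdefault(km, []).append(ci)
        else:
            clusters[placed].members.append((gid, fid))
    return clusters


def assign_bins(
    clusters: list[GeneCluster], clade_map: dict[str, str]
) -> tuple[list[BinAssignment], dict[str, tuple[int, int]]]:
    """Assign each cluster to Core / cladeX_unique / dispensable and
    summarize (cluster count, member-gene count) per bin."""
    clades = sorted(set(clade_map.values()))
    if len(clades) != 2:
        raise GenotaxError(f"clade_map must define exactly 2 clades, got {clades}")
    all_genomes = set(clade_map)
    clade_members = {c: {g for g, cl in clade_map.items() if cl == c} for c in clades}
    assignments = []
    summary: dict[str, list[int]] = {}
    for cl in clusters:
        pres = cl.presence
        unknown = pres - all_genomes
        if unknown:
            raise GenotaxError(f"genomes missing from clade map: {sorted(unknown)}")
        if pres == all_genomes:
            b = "Core"
        elif pres == clade_members[clades[0]]:
            b = f"{clades[0]}_unique"
        elif pres == clade_members[clades[1]]:
            b = f"{clades[1]}_unique"
        else:
            b = "dispensable"
        assignments.append(BinAssignment(cluster_id=cl.cluster_id, bin=b))
        summary.setdefault(b, [0, 0])
        summary[b][0] += 1
        summary[b][1] += len(cl.members)
    return assignments, {b: (c, g) for b, (c, g) in summary.items()}


def count_keyword_genes(features: list[GeneFeature], keyword: str = "LysR") -> int:
    """Case-insensitive substring match of ``keyword`` on product strings."""
    kw = keyword.lower()
    return sum(1 for f in features if kw in (f.product or "").lower())


def welch_t(group_a, group_b) -> tuple[float, float, float]:
    """Welch two-sample t test: (t, Welch-Satterthwaite df, two-sided p)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise GenotaxError("welch_t needs n >= 2 per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if np.isclose(a.mean(), b.mean()):
            return 0.0, float(a.size + b.size - 2), 1.0
        raise GenotaxError("welch_t undefined: zero variance in both groups")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)
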