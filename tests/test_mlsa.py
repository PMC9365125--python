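import itertools

import numpy as np
import pytest

from genotax.errors import GenotaxError, MarkerError
from genotax.genome_io import GeneFeature, GenomeRecord
from genotax.mlsa import (
    align_gene,
    concatenate,
    extract_markers,
    is_monophyletic,
    k2_matrix,
    newick_bipartitions,
    nj_tree,
)


def _genome_with(symbols):
    seq = "ATGAAATTTGGGTAA" * len(symbols)
    feats = [
        GeneFeature(f"f{i}", sym, "p", "chr", 15 * i, 15 * (i + 1), "+")
        for i, sym in enumerate(symbols)
    ]
    return GenomeRecord(genome_id="g", replicons=[("chr", seq, "linear")], features=feats)


class TestExtractMarkers:
    def test_all_four_markers(self):
        ms = extract_markers(_genome_with(["recA", "mreB", "rpoA", "topA"]))
        assert set(ms.sequences) == {"recA", "mreB", "rpoA", "topA"}

    def test_missing_marker_named(self):
        with pytest.raises(MarkerError, match="topA"):
            extract_markers(_genome_with(["recA", "mreB", "rpoA"]))

    def test_multi_copy_marker_rejected(self):
        with pytest.raises(MarkerError, match="recA"):
            extract_markers(_genome_with(["recA", "recA", "mreB", "rpoA", "topA"]))

    def test_case_insensitive_match(self):
        ms = extract_markers(_genome_with(["RECA", "mreb", "rpoA", "topa"]))
        assert set(ms.sequences) == {"recA", "mreB", "rpoA", "topA"}


def _exhaustive_3way_length(s1, s2, s3):
    """Minimal multiple-alignment length for three short sequences by full
    3D dynamic programming (gap columns allowed in any subset of rows)."""
    n1, n2, n3 = len(s1), len(s2), len(s3)
    INF = 10**9
    dp = np.full((n1 + 1, n2 + 1, n3 + 1), INF, dtype=np.int64)
    dp[0, 0, 0] = 0
    moves = [m for m in itertools.product((0, 1), repeat=3) if any(m)]
    for i in range(n1 + 1):
        for j in range(n2 + 1):
            for k in range(n3 + 1):
                cur = dp[i, j, k]
                if cur == INF:
                    continue
                for di, dj, dk in moves:
                    ni, nj, nk = i + di, j + dj, k + dk
                    if ni <= n1 and nj <= n2 and nk <= n3:
                        if cur + 1 < dp[ni, nj, nk]:
                            dp[ni, nj, nk] = cur + 1
    return int(dp[n1, n2, n3])


class TestAlignGene:
    def test_identical_sequences_gap_free(self):
        aln = align_gene([("a", "ACGTACGT"), ("b", "ACGTACGT"), ("c", "ACGTACGT")])
        assert all("-" not in row for _, row in aln)

    def test_single_substitution(self):
        aln = dict(align_gene([("a", "ACGTACGT"), ("b", "ACTTACGT")]))
        assert len(aln["a"]) == 8
        mismatches = sum(1 for x, y in zip(aln["a"], aln["b"]) if x != y)
        assert mismatches == 1

    def test_insertion_alignment_length_matches_exhaustive_oracle(self):
        base = "ACGTACGTACGTACG"
        with_ins = base[:7] + "TTT" + base[7:]
        seqs = [("a", base), ("b", base), ("c", with_ins)]
        aln = align_gene(seqs)
        length = len(aln[0][1])
        assert length == len(base) + 3
        assert length == _exhaustive_3way_length(base, base, with_ins)
        for name, row in aln:
            assert row.replace("-", "") == dict(seqs)[name]

    def test_empty_input_rejected(self):
        with pytest.raises(GenotaxError):
            align_gene([])

    def test_rows_stay_flush(self):
        seqs = [("a", "ACGTACGTAA"), ("b", "ACGACGTAA"), ("c", "ACGTACCGTAA"), ("d", "ACGTAC")]
        aln = align_gene(seqs)
        lengths = {len(row) for _, row in aln}
        assert len(lengths) == 1
        for name, row in aln:
            assert row.replace("-", "") == dict(seqs)[name]


class TestConcatenate:
    def _aln(self, length, taxa=("x", "y")):
        return [(t, "A" * length) for t in taxa]

    def test_lengths_sum(self):
        per_gene = {
            "recA": self._aln(300),
            "mreB": self._aln(900),
            "rpoA": self._aln(600),
            "topA": self._aln(2100),
        }
        sm = concatenate(per_gene)
        assert len(sm.concatenated[0][1]) == 3900
        assert sm.partitions == [
            ("recA", 1, 300),
            ("mreB", 301, 1200),
            ("rpoA", 1201, 1800),
            ("topA", 1801, 3900),
        ]

    def test_single_gene_equals_alignment(self):
        per_gene = {"recA": [("x", "ACGT"), ("y", "ACGA")]}
        sm = concatenate(per_gene)
        assert sm.concatenated == per_gene["recA"]

    def test_canonical_gene_order_applied(self):
        genes = {
            "recA": [("x", "AA"), ("y", "AA")],
            "mreB": [("x", "CC"), ("y", "CC")],
            "rpoA": [("x", "GG"), ("y", "GG")],
            "topA": [("x", "TT"), ("y", "TT")],
        }
        shuffled = dict(reversed(list(genes.items())))
        assert concatenate(genes).concatenated == concatenate(shuffled).concatenated

    def test_missing_taxon_rejected(self):
        per_gene = {"recA": [("x", "AA"), ("y", "AA")], "mreB": [("x", "CC")]}
        with pytest.raises(GenotaxError):
            concatenate(per_gene)


class TestNj:
    def test_three_taxon_closed_form(self):
        # additive distances (a,b)=2, (a,c)=4, (b,c)=4 -> branches 1, 1, 3
        d = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float)
        newick = nj_tree(d, ["a", "b", "c"])
        lengths = dict(
            (name, float(bl))
            for name, bl in __import__("re").findall(r"([a-z]+):([\d.]+)", newick)
        )
        assert lengths == {"a": 1.0, "b": 1.0, "c": 3.0}

    def test_two_taxa_half_distance(self):
        newick = nj_tree(np.array([[0, 3], [3, 0]], float), ["a", "b"])
        assert newick == "((a:1.500000,b:1.500000));" or newick == "(a:1.500000,b:1.500000);"

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(GenotaxError):
            nj_tree(np.array([[0, 1], [2, 0]], float), ["a", "b"])

    def test_agrees_with_skbio_on_random_matrix(self):
        import dendropy
        from dendropy.calculate import treecompare
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(0)
        labels = [f"t{i}" for i in range(6)]
        # random tree-ish distances: perturbed additive matrix stays NJ-consistent
        base = rng.uniform(0.5, 1.0, size=(6, 6))
        d = (base + base.T) / 2
        np.fill_diagonal(d, 0)
        mine = nj_tree(d, labels)
        theirs = str(skbio_nj(DistanceMatrix(d, labels)))
        tns = dendropy.TaxonNamespace()
        t1 = dendropy.Tree.get(data=mine, schema="newick", taxon_namespace=tns)
        t2 = dendropy.Tree.get(data=theirs, schema="newick", taxon_namespace=tns)
        assert treecompare.symmetric_difference(t1, t2) == 0


class TestTopologyHelpers:
    def test_bipartitions_of_balanced_quartet(self):
        # the quartet has a single internal edge; both sides canonicalize
        # to the lexicographically smaller leaf set
        newick = "((a:1,b:1):1,(c:1,d:1):1);"
        assert newick_bipartitions(newick) == {frozenset({"a", "b"})}
        assert is_monophyletic(newick, {"c", "d"})

    def test_monophyly(self):
        newick = "((a:1,b:1):1,(c:1,(d:1,e:1):1):1);"
        assert is_monophyletic(newick, {"a", "b"})
        assert is_monophyletic(newick, {"d", "e"})
        assert not is_monophyletic(newick, {"a", "c"})


def test_supermatrix_k2_is_convex_combination_of_gene_k2():
    """Concatenated K2 numerator counts are column-weighted sums of the
    per-gene counts, so the supermatrix P/Q are convex combinations."""
    g1 = [("x", "A" * 60), ("y", "G" * 2 + "A" * 58)]  # 2 transitions / 60
    g2 = [("x", "A" * 40), ("y", "C" * 1 + "A" * 39)]  # 1 transversion / 40
    sm = concatenate({"recA": g1, "mreB": g2})
    _, mat = k2_matrix(sm.concatenated)
    from genotax.ogri import k2_distance

    k_cat = k2_distance(dict(sm.concatenated)["x"], dict(sm.concatenated)["y"])
    k1 = k2_distance(g1[0][1], g1[1][1])
    k2_ = k2_distance(g2[0][1], g2[1][1])
    w1, w2 = 60 / 100, 40 / 100
    assert k_cat.P == pytest.approx(w1 * k1.P + w2 * k2_.P)
    assert k_cat.Q == pytest.approx(w1 * k1.Q + w2 * k2_.Q)
    assert mat[0, 1] == pytest.approx(k_cat.d)
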