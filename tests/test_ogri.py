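import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from genotax.errors import GenotaxError, UndefinedValueError
from genotax.genome_io import GenomeRecord, extract_proteome
from genotax.ogri import (
    DdhModel,
    compute_16s_similarity,
    compute_aai,
    compute_ani,
    compute_isddh,
    fragment_genome,
    k2_distance,
    trim_to_reference_window,
)
from genotax.synthetic import make_pair
from genotax._align import align, revcomp


def _genome(seq, gid="g"):
    return GenomeRecord(genome_id=gid, replicons=[("chr", seq, "linear")])


def _random_seq(n, seed):
    rng = np.random.default_rng(seed)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


class TestFragmentation:
    @pytest.mark.parametrize("length,expected", [(5100, 5), (5099, 4), (1_000_000, 980)])
    def test_fragment_counts(self, length, expected):
        frags = fragment_genome(_genome(_random_seq(length, 0)))
        assert len(frags) == expected

    def test_n_rich_fragments_dropped(self):
        seq = _random_seq(1020, 1) + "N" * 1020 + _random_seq(1020, 2)
        assert len(fragment_genome(_genome(seq))) == 2

    def test_too_short_genome_errors(self):
        with pytest.raises(UndefinedValueError):
            fragment_genome(_genome("ACGT" * 10))


class TestAni:
    def test_self_identity(self):
        g = _genome(_random_seq(20_000, 3))
        res = compute_ani(g, g)
        assert res.value == 100.0
        assert res.support == 19

    def test_symmetry(self, small_pair):
        anc, desc, _ = small_pair
        assert compute_ani(anc, desc).value == pytest.approx(compute_ani(desc, anc).value, abs=1e-9)

    def test_unrelated_genomes_undefined(self):
        a, b = _genome(_random_seq(5000, 4), "a"), _genome(_random_seq(5000, 5), "b")
        with pytest.raises(UndefinedValueError):
            compute_ani(a, b, fragment_length=1020)

    def test_matches_exhaustive_brute_force(self):
        """The seeded fragment search must equal an exhaustive best-infix
        search (edlib over the whole partner genome, both strands)."""
        frag_len = 300
        anc, desc, _ = make_pair(seed=11, divergence=0.05, length=12_000, extra_genes=0)

        def brute_force_hits(frags, target_seq):
            hits = {}
            for f in frags:
                best = None
                for strand, q in (("+", f.sequence), ("-", revcomp(f.sequence))):
                    res = align(q, target_seq, mode="HW")
                    if res is None or res.identity < 0.35 or res.columns < 0.7 * frag_len:
                        continue
                    cand = (res.identity, res.target_start, res.target_end)
                    if best is None or cand[0] > best[0] or (cand[0] == best[0] and cand[1] < best[1]):
                        best = cand
                if best:
                    hits[f.index] = best
            return hits

        def brute_force_ani(ga, gb):
            fa = fragment_genome(ga, frag_len)
            fb = fragment_genome(gb, frag_len)
            ha = brute_force_hits(fa, gb.replicons[0][1])
            hb = brute_force_hits(fb, ga.replicons[0][1])
            idents = []
            for ia, (ident, s0, s1) in ha.items():
                ib = ((s0 + s1) // 2) // frag_len
                if ib in hb:
                    back_ident, t0, t1 = hb[ib]
                    if ((t0 + t1) // 2) // frag_len == ia:
                        idents.append((ident + back_ident) / 2)
            return 100.0 * float(np.mean(idents))

        mine = compute_ani(anc, desc, fragment_length=frag_len).value
        oracle = brute_force_ani(anc, desc)
        assert mine == pytest.approx(oracle, abs=1e-9)


class TestAai:
    def test_self_identity_and_support(self, small_pair):
        anc, _, _ = small_pair
        prots = extract_proteome(anc)
        res = compute_aai(prots, prots)
        assert res.value == 100.0
        assert res.support == len(prots)

    def test_symmetry(self, small_pair):
        anc, desc, _ = small_pair
        pa, pb = extract_proteome(anc), extract_proteome(desc)
        assert compute_aai(pa, pb).value == pytest.approx(compute_aai(pb, pa).value, abs=1e-9)

    def test_protein_floor_enforced(self):
        with pytest.raises(UndefinedValueError):
            compute_aai([("p", "MKL")], [("p", "MKL")], min_proteins=100)


class TestDdh:
    def test_self_distance_zero(self, small_pair):
        anc, _, _ = small_pair
        res = compute_isddh(anc, anc)
        assert res.parameters["d2"] == 0.0
        assert res.value == pytest.approx(DdhModel()(0.0))

    def test_transform_at_zero_frozen(self):
        # regression fixture: direct evaluation of the logistic map at d2=0
        assert DdhModel()(0.0) == pytest.approx(88.2705111, abs=1e-6)

    def test_transform_strictly_decreasing(self):
        model = DdhModel()
        values = [model(d) for d in np.linspace(0, 0.5, 40)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_no_hsps_undefined(self):
        a = _genome(_random_seq(5000, 6), "a")
        b = _genome(_random_seq(5000, 7), "b")
        with pytest.raises(UndefinedValueError):
            compute_isddh(a, b)


class TestK2:
    def test_identical_sequences(self):
        k2 = k2_distance("ACGTACGT", "ACGTACGT")
        assert (k2.P, k2.Q, k2.d) == (0.0, 0.0, 0.0)
        assert k2.similarity == 100.0

    def test_hand_computed_example(self):
        # 100 bp, 2 transitions (A<->G), 1 transversion (A<->C)
        a = "A" * 100
        b = "G" * 2 + "C" + "A" * 97
        k2 = k2_distance(a, b)
        assert k2.P == pytest.approx(0.02)
        assert k2.Q == pytest.approx(0.01)
        assert k2.d == pytest.approx(-0.5 * math.log(0.95 * math.sqrt(0.98)), abs=1e-12)

    def test_gap_and_n_columns_excluded(self):
        k2 = k2_distance("ACG-N", "ACGTT")
        assert k2.aligned_length == 3
        assert k2.d == 0.0

    def test_saturation_error(self):
        with pytest.raises(UndefinedValueError):
            k2_distance("A" * 10, "G" * 10)

    def test_unequal_length_rejected(self):
        with pytest.raises(GenotaxError):
            k2_distance("ACGT", "ACG")

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(st.sampled_from("ACGT"), min_size=50, max_size=200), st.integers(0, 2**31 - 1))
    def test_k2_at_least_p_distance(self, bases, seed):
        a = "".join(bases)
        rng = np.random.default_rng(seed)
        b = list(a)
        for i in rng.choice(len(b), size=len(b) // 10, replace=False):
            b[i] = "ACGT"[rng.integers(0, 4)]
        b = "".join(b)
        try:
            k2 = k2_distance(a, b)
        except UndefinedValueError:
            return
        p_dist = sum(1 for x, y in zip(a, b) if x != y) / len(a)
        assert k2.d >= p_dist - 1e-12


class TestS16:
    def test_identical(self):
        seq = _random_seq(1500, 8)
        assert compute_16s_similarity(seq, seq).value == 100.0

    def test_identity_mode(self):
        a = "ACGT" * 100
        b = "ACGA" + "ACGT" * 99
        res = compute_16s_similarity(a, b, mode="identity")
        assert res.value == pytest.approx(100 * 399 / 400)


class TestTrimWindow:
    def _alignment(self):
        ref = _random_seq(1500, 9)
        other = ref[:700] + "T" + ref[701:]
        return [("ref", ref), ("other", other)]

    def test_trimmed_reference_length_is_1337(self):
        out = trim_to_reference_window(self._alignment(), "ref", 54, 1390)
        ref_row = dict(out)["ref"]
        assert sum(1 for c in ref_row if c not in "-.") == 1337

    def test_full_window_unchanged(self):
        aln = self._alignment()
        assert trim_to_reference_window(aln, "ref", 1, 1500) == aln

    def test_single_column_window(self):
        out = trim_to_reference_window(self._alignment(), "ref", 700, 700)
        assert all(len(row) == 1 for _, row in out)

    def test_reference_shorter_than_window_errors(self):
        with pytest.raises(GenotaxError):
            trim_to_reference_window(self._alignment(), "ref", 54, 2000)

    def test_missing_reference_errors(self):
        with pytest.raises(GenotaxError):
            trim_to_reference_window(self._alignment(), "nope")
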