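import re

import numpy as np
import pytest

from genotax.errors import ConfigError, FormatError, GenotaxError
from genotax.chemotax import (
    MotifReport,
    check_desaturase_motifs,
    detect_genes,
    load_catalog,
    load_strain_presence_table,
    predict_chemotype,
    predict_fatty_acids,
    predict_phb,
    predict_polar_lipids,
    predict_polyamines,
    predict_quinone,
)
from genotax.genome_io import GeneFeature


@pytest.fixture(scope="module")
def catalog():
    return load_catalog()


def _row(catalog, present):
    return {s: s in present for s in catalog.symbols}


ALIAMPHRITEA_LIKE = {
    "accA", "accB", "accC", "accD", "fabD", "fabH", "fabY", "fabB", "fabF",
    "fabG", "fabA", "fabZ", "fabV", "Des1", "Des2", "Des3", "lpxA",
    "plsX", "plsY", "plsC", "cdsA", "pssA", "psd", "pgsA", "pgpA",
    "ubiC", "ubiA", "ubiD", "ubiX", "ubiI", "ubiG", "ubiH", "ubiE",
    "ispA", "ispB", "ubiB", "ubiJ", "ubiK", "ubiF",
    "speA", "speB", "speE", "spuC", "kauB",
    "phaA", "phaB", "phaC", "phaE",
}


class TestCatalog:
    def test_bundled_catalog_loads(self, catalog):
        assert "fabA" in catalog.symbols
        assert catalog.family_of("speD") == "polyamine"

    def test_duplicate_symbol_rejected(self, tmp_path):
        bad = tmp_path / "cat.json"
        bad.write_text(
            '{"families": {"x": {"symbols": ["fabA"]}, "y": {"symbols": ["fabA"]}}}'
        )
        with pytest.raises(ConfigError):
            load_catalog(bad)


class TestDetectGenes:
    def test_empty_annotations_all_absent(self, catalog):
        table = detect_genes("g", [], catalog)
        assert not table.table.loc["g"].any()

    def test_symbol_match_with_evidence(self, catalog):
        feats = [GeneFeature("f1", "fabA", "dehydratase", "chr", 0, 9, "+")]
        table = detect_genes("g", feats, catalog)
        assert table.row("g")["fabA"] is np.True_ or table.row("g")["fabA"] is True
        assert table.evidence[("g", "fabA")] == "f1"

    def test_homology_mode_finds_relabeled_gene(self, catalog):
        # a gene annotated as "hypothetical protein" but with intact sequence
        # must still be detected from the caller-supplied reference protein
        rng = np.random.default_rng(5)
        prot = "".join("ACDEFGHIKLMNPQRSTVWY"[i] for i in rng.integers(0, 20, 200))
        feats = [GeneFeature("f9", "", "hypothetical protein", "chr", 0, 603, "+")]
        table = detect_genes(
            "g",
            feats,
            catalog,
            mode="homology",
            reference_proteins={"fabA": prot},
            proteome=[("f9", prot)],
        )
        assert table.row("g")["fabA"]
        assert table.evidence[("g", "fabA")].startswith("homology:f9")

    def test_homology_mode_requires_references(self, catalog):
        with pytest.raises(ConfigError):
            detect_genes("g", [], catalog, mode="homology")


class TestMotifs:
    def test_both_motifs_found_with_positions(self):
        # oracle: hand regular-expression scan
        seq = "AAHAAAHAAAAHAAHH"
        report = check_desaturase_motifs(seq)
        assert report.functional
        assert report.hxxxh_positions == tuple(m.start() for m in re.finditer(r"(?=H.{3}H)", seq))
        assert 2 in report.hxxxh_positions
        assert report.hxxhh_positions == (11,)

    def test_poly_a_has_no_motifs(self):
        assert not check_desaturase_motifs("A" * 40).functional

    def test_short_sequence_no_motifs_no_error(self):
        report = check_desaturase_motifs("HAH")
        assert report.hxxxh_positions == () and report.hxxhh_positions == ()

    def test_bad_characters_rejected(self):
        with pytest.raises(FormatError):
            check_desaturase_motifs("MKLX*")

    def test_empty_rejected(self):
        with pytest.raises(FormatError):
            check_desaturase_motifs("")


class TestFattyAcids:
    def test_aliamphritea_pattern(self, catalog):
        p = predict_fatty_acids(_row(catalog, ALIAMPHRITEA_LIKE), catalog)
        assert p.fatty_acids == {"C16:0", "C16:1w7c", "C18:1w7c", "C10:0 3-OH"}
        assert p.negations["PUFA"] == "no"
        assert p.negations["branched"] == "no"
        assert p.negations["C18:1w9c"] == "not-expected"

    def test_all_absent_row(self, catalog):
        p = predict_fatty_acids(_row(catalog, set()), catalog)
        assert p.fatty_acids == set()
        assert p.pathway_completeness["fasii_core"] is False

    def test_aerobic_route_without_fabA(self, catalog):
        present = (ALIAMPHRITEA_LIKE - {"fabA", "lpxA"}) | {"Des1"}
        p = predict_fatty_acids(_row(catalog, present), catalog)
        assert p.fatty_acids == {"C16:1w7c"}  # aerobic only; no C18:1w7c, no C16:0

    def test_desaturase_without_motifs_demoted(self, catalog):
        row = _row(catalog, ALIAMPHRITEA_LIKE - {"fabA", "fabB", "lpxA"})
        motifs = {s: MotifReport((), ()) for s in ("Des1", "Des2", "Des3")}
        p = predict_fatty_acids(row, catalog, desaturase_motifs=motifs)
        assert "C16:1w7c" not in p.fatty_acids
        assert "Des1" in p.negations["desaturase_uncertain"]

    def test_incomplete_row_lists_missing_symbols(self, catalog):
        with pytest.raises(GenotaxError, match="fabZ"):
            predict_fatty_acids({"fabA": True}, catalog)


class TestPolarLipids:
    def test_opalescens_pattern_has_dpg(self, catalog):
        present = {"plsX", "plsY", "plsC", "cdsA", "pssA", "psd", "pgsA", "pgpA", "cls"}
        p = predict_polar_lipids(_row(catalog, present), catalog)
        assert p.polar_lipids == {"PG", "PE", "DPG"}

    def test_pt3_pattern_pg_pe_only(self, catalog):
        present = {"plsX", "plsY", "plsC", "cdsA", "pssA", "psd", "pgsA", "pgpA"}
        p = predict_polar_lipids(_row(catalog, present), catalog)
        assert p.polar_lipids == {"PG", "PE"}

    def test_pssA_absent_pg_only(self, catalog):
        present = {"plsX", "plsY", "plsC", "cdsA", "psd", "pgsA", "pgpA"}
        p = predict_polar_lipids(_row(catalog, present), catalog)
        assert p.polar_lipids == {"PG"}

    def test_backbone_gap_blocks_everything(self, catalog):
        present = {"plsX", "plsY", "cdsA", "pssA", "psd", "pgsA", "pgpA", "cls"}
        p = predict_polar_lipids(_row(catalog, present), catalog)
        assert p.polar_lipids == set()


class TestQuinone:
    FULL = {"ubiC", "ubiA", "ubiD", "ubiX", "ubiI", "ubiG", "ubiH", "ubiE", "ispA", "ispB",
            "ubiB", "ubiJ", "ubiK", "ubiF"}

    def test_full_set_gives_q8(self, catalog):
        p = predict_quinone(_row(catalog, self.FULL), catalog)
        assert p.quinone == "Q-8" and p.quinone_gaps == []

    def test_ispB_missing_undetermined(self, catalog):
        p = predict_quinone(_row(catalog, self.FULL - {"ispB"}), catalog)
        assert p.quinone == "undetermined" and p.quinone_gaps == ["ispB"]

    def test_accessory_missing_still_q8_with_warning(self, catalog):
        p = predict_quinone(_row(catalog, self.FULL - {"ubiK"}), catalog)
        assert p.quinone == "Q-8"
        assert p.quinone_accessory_missing == ["ubiK"]


class TestPolyamines:
    def test_aliamphritea_pattern(self, catalog):
        present = {"speA", "speB", "speE", "spuC", "kauB"}
        p = predict_polyamines(_row(catalog, present), catalog)
        assert p.polyamines == {"putrescine_via_agmatine", "GABA_from_putrescine"}

    def test_amphritea_pattern_all_four(self, catalog):
        present = {"speA", "speB", "speC", "speD", "speE", "spuC", "kauB"}
        p = predict_polyamines(_row(catalog, present), catalog)
        assert p.polyamines == {
            "putrescine_via_agmatine",
            "putrescine_via_ornithine",
            "spermidine_autonomous",
            "GABA_from_putrescine",
        }

    def test_speE_alone_gives_nothing(self, catalog):
        p = predict_polyamines(_row(catalog, {"speE"}), catalog)
        assert p.polyamines == set()


class TestPhb:
    @pytest.mark.parametrize(
        "present,expected,gaps",
        [
            ({"phaA", "phaB", "phaC", "phaE"}, True, []),
            ({"phaA", "phaB", "phaE"}, False, ["phaC"]),
            (set(), False, ["phaA", "phaB", "phaC", "phaE"]),
        ],
    )
    def test_rule(self, catalog, present, expected, gaps):
        p = predict_phb(_row(catalog, present), catalog)
        assert p.phb is expected and p.phb_gaps == gaps


class TestProperties:
    def _items(self, p):
        out = set(p.fatty_acids) | set(p.polar_lipids) | set(p.polyamines)
        if p.quinone == "Q-8":
            out.add("Q-8")
        if p.phb:
            out.add("PHB")
        return out

    def test_monotone_in_gene_addition(self, catalog):
        rng = np.random.default_rng(11)
        symbols = catalog.symbols
        for _ in range(60):
            mask = rng.random(len(symbols)) < 0.5
            present = {s for s, m in zip(symbols, mask) if m}
            extra = {s for s in symbols if rng.random() < 0.2}
            base = self._items(predict_chemotype("g", _row(catalog, present), catalog))
            bigger = self._items(
                predict_chemotype("g", _row(catalog, present | extra), catalog)
            )
            assert base <= bigger

    def test_prediction_depends_only_on_row(self, catalog):
        row = _row(catalog, ALIAMPHRITEA_LIKE)
        p1 = predict_chemotype("g", dict(row), catalog)
        p2 = predict_chemotype("g", dict(reversed(list(row.items()))), catalog)
        assert self._items(p1) == self._items(p2)
        assert [r.item for r in p1.rules] == [r.item for r in p2.rules]


class TestBundledStrains:
    def test_shapes_and_headline_predictions(self, catalog):
        pt = load_strain_presence_table(catalog)
        assert pt.table.shape[0] == 8
        for strain in pt.table.index:
            p = predict_chemotype(strain, pt.row(strain), catalog)
            assert {"C16:0", "C16:1w7c", "C18:1w7c"} <= p.fatty_acids
            assert p.quinone == "Q-8"
            assert p.phb
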