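"""Panel registry and variant/clinical table I/O."""

import pytest

from crcgerm.models import AnnotatedVariant
from crcgerm.tables import (
    TableFormatError,
    load_panel,
    read_clinical_table,
    read_variant_table,
    write_clinical_table,
    write_results_table,
)

VCF_FIXTURE = """\
##fileformat=VCFv4.2
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=EFFECT,Number=1,Type=String,Description="Effect class">
##INFO=<ID=MAF_G,Number=1,Type=Float,Description="Global MAF">
##INFO=<ID=ADA,Number=1,Type=Float,Description="ADA splice score">
##INFO=<ID=RF,Number=1,Type=Float,Description="RF splice score">
##INFO=<ID=PRED_SIFT,Number=1,Type=String,Description="SIFT call">
##INFO=<ID=PRED_Polyphen2,Number=1,Type=String,Description="Polyphen2 call">
##INFO=<ID=BDM_COREAD,Number=1,Type=Float,Description="Driver score, colorectal">
##INFO=<ID=CARRIERS,Number=1,Type=String,Description="Carrier ids">
##contig=<ID=chr1>
##contig=<ID=chr3>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
chr1\t1000\t.\tA\tT\t.\t.\tGENE=APC;EFFECT=missense;MAF_G=0.002;PRED_SIFT=deleterious;PRED_Polyphen2=tolerated;CARRIERS=P001
chr1\t2000\t.\tG\tC\t.\t.\tGENE=MLH1;EFFECT=frameshift;CARRIERS=P002;BDM_COREAD=0.91
chr3\t3000\t.\tC\tA\t.\t.\tGENE=SMAD9;EFFECT=splice_site;MAF_G=0.0001;ADA=0.97;RF=0.88
"""


class TestPanel:
    def test_packaged_panel_composition(self, panel):
        assert len(panel) == 206
        n_diag = sum(e.category == "diagnostic" for e in panel)
        n_cand = sum(e.category == "candidate" for e in panel)
        assert (n_diag, n_cand) == (102, 104)
        assert n_diag + n_cand == len(panel)
        assert len({e.symbol for e in panel}) == 206

    def test_empty_file_gives_empty_panel(self, tmp_path):
        p = tmp_path / "panel.tsv"
        p.write_text("symbol\tcategory\tpenetrance\n")
        assert load_panel(p) == []

    def test_duplicate_symbol_rejected(self, tmp_path):
        p = tmp_path / "panel.tsv"
        p.write_text(
            "symbol\tcategory\tpenetrance\nAPC\tdiagnostic\thigh\nAPC\tcandidate\tunknown\n"
        )
        with pytest.raises(TableFormatError, match="duplicate"):
            load_panel(p)

    def test_unknown_vocabulary_token_names_row(self, tmp_path):
        p = tmp_path / "panel.tsv"
        p.write_text("symbol\tcategory\tpenetrance\nAPC\tsomatic\thigh\n")
        with pytest.raises(TableFormatError, match="row 2"):
            load_panel(p)


class TestVariantTables:
    def test_tsv_round_trip_is_identity(self, tmp_path, cohort_seed1):
        variants, _, _ = cohort_seed1
        path = tmp_path / "variants.tsv"
        write_results_table(variants, path)
        back = read_variant_table(path, "tsv")
        assert len(back) == len(variants)
        for a, b in zip(variants, back):
            assert a == b

    def test_empty_input_writes_header_only(self, tmp_path):
        path = tmp_path / "empty.tsv"
        write_results_table([], path)
        lines = path.read_text().splitlines()
        assert len(lines) == 1
        assert read_variant_table(path, "tsv") == []

    def test_score_out_of_range_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        write_results_table(
            [AnnotatedVariant("chr1", 10, "A", "G", "APC", ada_score=0.4)], path
        )
        text = path.read_text().replace("0.4", "1.7")
        path.write_text(text)
        with pytest.raises(TableFormatError, match="row 2"):
            read_variant_table(path, "tsv")

    def test_vcf_dialect_maps_info_keys(self, tmp_path):
        path = tmp_path / "cohort.vcf"
        path.write_text(VCF_FIXTURE)
        variants = read_variant_table(path, "vcf")
        assert len(variants) == 3
        v1, v2, v3 = variants
        assert v1.gene == "APC" and v1.maf_global == pytest.approx(0.002)
        assert v1.predictor_calls["SIFT"] == "deleterious"
        assert v1.predictor_calls["FATHMM"] == "missing"
        assert v1.patient_ids == {"P001"}
        assert v2.maf_global is None  # absent annotation stays missing
        assert v2.driver_scores["COREAD"] == pytest.approx(0.91)
        assert v3.effect_class == "splice_site" and v3.ada_score == pytest.approx(0.97)

    def test_extra_columns_parallel_check(self, tmp_path):
        v = AnnotatedVariant("chr1", 10, "A", "G", "APC")
        with pytest.raises(ValueError):
            write_results_table([v], tmp_path / "x.tsv", extra_columns=[{}, {}])


class TestClinicalTables:
    def test_round_trip(self, tmp_path, patients100):
        path = tmp_path / "patients.tsv"
        write_clinical_table(patients100, path)
        back = read_clinical_table(path)
        assert back == patients100

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "patients.tsv"
        path.write_text(
            "patient_id\tsex\tage_at_dx\nP1\tmale\t60\nP2\tother\t50\n"
        )
        with pytest.raises(TableFormatError, match="row 3"):
            read_clinical_table(path)
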