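"""Variant-table I/O: fixture integrity, round-trips, dialects, errors."""

import pytest

from oligodsd.predictors import ConsensusCounts
from oligodsd.variant_io import (
    AnnotatedVariant,
    FixtureIntegrityError,
    PatientVariantSet,
    VariantTableError,
    load_cohort_fixture,
    read_variant_table,
    write_candidates,
)


def make_variant(**kw):
    defaults = dict(
        patient_id="1", gene="RET", chrom="10", pos=43609955, ref="C", alt="T",
        var_type="snv", consequence="missense", hgvs_c="c.1907C>T",
        maf_gnomad=1e-5, depth=100, quality=60.0, ad_ref=50, ad_alt=50,
        consensus=ConsensusCounts(cadd_phred=23.0, functional_deleterious=6,
                                  conservation_conserved=6, splicing_db_altered=0),
    )
    defaults.update(kw)
    return AnnotatedVariant(**defaults)


class TestCohortFixture:
    def test_eight_patients_with_printed_record_counts(self, cohort):
        assert [p.patient_id for p in cohort] == [str(i) for i in range(1, 9)]
        assert [len(p) for p in cohort] == [9, 1, 2, 4, 6, 16, 5, 14]
        assert sum(len(p) for p in cohort) == 57

    def test_karyotypes_and_index_variants(self, cohort):
        assert [p.karyotype for p in cohort] == ["46,XY"] * 7 + ["46,XX"]
        assert all(p.mamld1_variant for p in cohort)
        assert cohort[6].mamld1_variant.endswith("c.1503_1504dupCAGCAG")

    def test_patient6_maml3_record_unconfirmed(self, cohort):
        patient6 = cohort[5]
        maml3 = [v for v in patient6.variants if v.gene == "MAML3"]
        assert len(maml3) == 1 and maml3[0].confirmed is False
        others = [v for p in cohort for v in p.variants if v.gene != "MAML3" or v.patient_id != "6"]
        assert all(v.confirmed for v in others)

    def test_nd_and_zero_frequencies_are_distinct(self, cohort):
        ret = next(v for v in cohort[0].variants if v.gene == "RET")
        assert ret.maf_cohort == 0.0  # observed-absent, not missing
        cyp = next(v for v in cohort[0].variants if v.gene == "CYP1A1")
        assert cyp.maf_gnomad is None and cyp.maf_cohort is None

    def test_exactly_two_cross_patient_duplicate_records(self, cohort):
        keys = [v.variant_key for p in cohort for v in p.variants]
        assert len(keys) - len(set(keys)) == 2

    def test_synonymous_consequence_parsed(self, cohort):
        evc_syn = next(
            v for p in cohort for v in p.variants
            if v.gene == "EVC" and v.hgvs_c.endswith("c.1653G>A")
        )
        assert evc_syn.consequence == "synonymous"

    def test_checksum_guard_detects_tampering(self, monkeypatch, tmp_path):
        import oligodsd.variant_io as vio

        real = vio._data_path

        def tampered(name):
            if name == "cohort_variants.tsv":
                bad = tmp_path / name
                bad.write_text(real(name).read_text().replace("RET", "RAT"))
                return bad
            return real(name)

        monkeypatch.setattr(vio, "_data_path", tampered)
        with pytest.raises(FixtureIntegrityError, match="checksum"):
            load_cohort_fixture()


class TestRoundTrip:
    def test_cohort_fixture_round_trips_field_by_field(self, cohort, tmp_path):
        records = [v for p in cohort for v in p.variants]
        path = tmp_path / "rt.tsv"
        write_candidates(records, path)
        back = read_variant_table(path, patient_id=None)
        # read_variant_table returns one patient; reread raw for all
        from oligodsd.variant_io import _read_simple_rows

        again = _read_simple_rows(path)
        assert again == records

    def test_delins_description_survives_verbatim(self, cohort, tmp_path):
        delins = next(
            v for v in cohort[7].variants
            if v.hgvs_c.endswith("c.1798-7_1798-6delCCinsAT")
        )
        path = tmp_path / "one.tsv"
        write_candidates([delins], path)
        back = read_variant_table(path).variants[0]
        assert back.hgvs_c == delins.hgvs_c
        assert back == delins

    def test_empty_record_list_writes_header_only(self, tmp_path):
        path = tmp_path / "empty.tsv"
        write_candidates([], path)
        assert len(path.read_text().splitlines()) == 1
        assert len(read_variant_table(path).variants) == 0

    def test_raw_predictor_columns_round_trip(self, tmp_path):
        from oligodsd.predictors import profile_from_columns

        profile = profile_from_columns(
            {"SIFT": 0.01, "GERP++": 4.2, "dbscSNV_ADA": 0.9, "SSF": -0.2},
            cadd_phred=25.1,
        )
        v = make_variant(consensus=None, predictor_profile=profile)
        path = tmp_path / "raw.tsv"
        write_candidates([v], path)
        back = read_variant_table(path).variants[0]
        assert back.predictor_profile == profile
        assert back == v


class TestParsingErrors:
    def test_non_numeric_maf_rejected(self, tmp_path, cohort):
        path = tmp_path / "bad.tsv"
        write_candidates([make_variant()], path)
        text = path.read_text().replace("1e-05", "lots")
        path.write_text(text)
        with pytest.raises(VariantTableError, match="non-numeric MAF"):
            read_variant_table(path)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "short.tsv"
        path.write_text("patient_id\tgene\n1\tRET\n")
        with pytest.raises(VariantTableError, match="missing required columns"):
            read_variant_table(path)

    def test_snv_with_equal_alleles_rejected(self):
        with pytest.raises(VariantTableError, match="ref == alt"):
            make_variant(ref="C", alt="C")

    def test_maf_outside_unit_interval_rejected(self):
        with pytest.raises(VariantTableError, match="outside"):
            make_variant(maf_gnomad=1.5)

    def test_variant_in_wrong_patient_set_rejected(self):
        with pytest.raises(VariantTableError, match="does not belong"):
            PatientVariantSet(patient_id="2", variants=[make_variant()])


class TestVcfAdapter:
    VCF_TEXT = (
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n'
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
        "##contig=<ID=10>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
        "10\t43609955\t.\tC\tT\t60\tPASS\t.\tGT:DP:AD\t0/1:100:52,48\n"
        "10\t43610000\t.\tAT\tA\t45\tPASS\t.\tGT:DP:AD\t1/1:80:2,78\n"
    )

    def test_minimal_vcf_ingestion(self, tmp_path):
        pytest.importorskip("cyvcf2")
        from oligodsd.variant_io import read_vcf

        path = tmp_path / "mini.vcf"
        path.write_text(self.VCF_TEXT)
        ps = read_vcf(path)
        assert ps.patient_id == "S1" and len(ps) == 2
        snv, deletion = ps.variants
        assert (snv.chrom, snv.pos, snv.ref, snv.alt) == ("10", 43609955, "C", "T")
        assert snv.zygosity == "het" and snv.depth == 100
        assert (snv.ad_ref, snv.ad_alt) == (52, 48)
        assert deletion.var_type == "deletion" and deletion.zygosity == "hom"
        # annotation fields are deliberately empty: annotation happens upstream
        assert snv.gene == "" and snv.consensus is None


class TestAnnovarDialect:
    HEADER = ("Chr\tStart\tRef\tAlt\tFunc_refGene\tExonicFunc_refGene\tGene_refGene\t"
              "HGVSc\tHGVSp\tavsnp\tgnomAD_AF\tcohort_AF\tDP\tGQ\tAD_ref\tAD_alt")

    def test_consequence_vocabulary_mapped(self, tmp_path):
        path = tmp_path / "anno.tsv"
        path.write_text(
            self.HEADER + "\n"
            "chr10\t43609955\tC\tT\texonic\tnonsynonymous SNV\tRET\tc.1907C>T\t"
            "p.T636M\trs1035958105\t0.00001\tND\t100\t60\t50\t50\n"
        )
        ps = read_variant_table(path, dialect="annovar_tsv", patient_id="p1")
        v = ps.variants[0]
        assert v.consequence == "missense"
        assert v.chrom == "10" and v.var_type == "snv"
        assert v.maf_gnomad == pytest.approx(1e-5) and v.maf_cohort is None

    def test_unmappable_consequence_token_named_in_error(self, tmp_path):
        path = tmp_path / "anno.tsv"
        path.write_text(
            self.HEADER + "\n"
            "chr1\t100\tA\tG\texonic\tweird_token\tRET\tc.1A>G\t\t\tND\tND\t10\t30\t5\t5\n"
        )
        with pytest.raises(VariantTableError, match="weird_token"):
            read_variant_table(path, dialect="annovar_tsv")

    def test_zero_row_file_gives_empty_set(self, tmp_path):
        path = tmp_path / "anno.tsv"
        path.write_text(self.HEADER + "\n")
        assert len(read_variant_table(path, dialect="annovar_tsv", patient_id="p")) == 0
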