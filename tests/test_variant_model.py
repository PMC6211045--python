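"""Domain types, the flat variant-table dialect, and annotated-VCF input."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hboc_triage.classifier import ClassifiedVariant, Disposition, Label, classify_variant
from hboc_triage.variant_model import (
    AnnotationBundle,
    ClinvarStatus,
    Consequence,
    DuplicateRecordError,
    PolyphenCall,
    SiftCall,
    VariantRecord,
    VariantTableError,
    Zygosity,
    most_severe_consequence,
    parse_clinvar_status,
    parse_consequence,
    read_annotated_vcf,
    read_variant_table,
    write_classification_report,
    write_variant_table,
)

VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=chr17,length=83257441>
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=CSQ,Number=A,Type=String,Description="Consequence">
##INFO=<ID=CLNSIG,Number=1,Type=String,Description="ClinVar significance">
##INFO=<ID=AF_EXAC,Number=A,Type=Float,Description="ExAC AF">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tP1
"""

FIELD_MAP = {
    "gene": "GENE",
    "consequence": "CSQ",
    "clinvar": "CLNSIG",
    "af_exac": "AF_EXAC",
}


def write_vcf(tmp_path, body):
    path = tmp_path / "test.vcf"
    path.write_text(VCF_HEADER + body)
    return path


class TestReadAnnotatedVcf:
    def test_biallelic_het_site_copies_depths(self, tmp_path):
        path = write_vcf(
            tmp_path,
            "chr17\t100\t.\tG\tA\t.\t.\tGENE=BRCA1;CSQ=missense;CLNSIG=Pathogenic;"
            "AF_EXAC=0.0000247\tGT:DP:AD\t0/1:50:30,20\n",
        )
        out = read_annotated_vcf(path, FIELD_MAP)
        assert len(out) == 1
        record, bundle = out[0]
        assert (record.depth, record.alt_depth) == (50, 20)
        assert record.zygosity is Zygosity.HETEROZYGOUS
        assert bundle.clinvar_status is ClinvarStatus.PATHOGENIC
        assert bundle.af_exac == pytest.approx(2.47e-5)
        # unmapped fields are explicit missing markers, never defaults
        assert bundle.sift is SiftCall.MISSING
        assert bundle.af_1000g is None

    def test_multiallelic_site_splits_with_allele_depths(self, tmp_path):
        path = write_vcf(
            tmp_path,
            "chr17\t200\t.\tG\tA,T\t.\t.\tGENE=BRCA1;CSQ=missense,stop_gained\t"
            "GT:DP:AD\t1/2:60:10,20,30\n",
        )
        out = read_annotated_vcf(path, FIELD_MAP)
        assert len(out) == 2
        (rec_a, _), (rec_t, _) = out
        assert (rec_a.pos, rec_a.ref) == (rec_t.pos, rec_t.ref) == (200, "G")
        assert {rec_a.alt: rec_a.alt_depth, rec_t.alt: rec_t.alt_depth} == {
            "A": 20,
            "T": 30,
        }
        assert rec_t.consequence is Consequence.STOP_GAIN

    def test_missing_clinvar_key_maps_to_absent(self, tmp_path):
        path = write_vcf(
            tmp_path,
            "chr17\t300\t.\tC\tT\t.\t.\tGENE=TP53;CSQ=missense\t"
            "GT:DP:AD\t1/1:40:2,38\n",
        )
        (record, bundle), = read_annotated_vcf(path, FIELD_MAP)
        assert bundle.clinvar_status is ClinvarStatus.ABSENT
        assert record.zygosity is Zygosity.HOMOZYGOUS

    def test_unmapped_required_field_is_configuration_error(self, tmp_path):
        from hboc_triage.variant_model import ConfigurationError

        path = write_vcf(tmp_path, "")
        with pytest.raises(ConfigurationError):
            read_annotated_vcf(path, {"gene": "GENE"})  # no consequence mapping


class TestVariantTableDialect:
    def test_header_only_file_gives_empty_list(self, tmp_path):
        path = tmp_path / "t.tsv"
        write_variant_table([], path)
        assert read_variant_table(path) == []

    def test_unknown_consequence_token_lists_vocabulary(self):
        with pytest.raises(VariantTableError, match="missense"):
            parse_consequence("gibberish")

    @given(
        st.lists(
            st.tuples(
                st.integers(1, 10_000),
                st.sampled_from(list(Consequence)),
                st.integers(0, 500),
                st.sampled_from(list(ClinvarStatus)),
                st.one_of(st.none(), st.floats(0, 1, allow_nan=False, width=32)),
                st.sampled_from(list(SiftCall)),
                st.sampled_from(list(PolyphenCall)),
                st.one_of(st.none(), st.integers(1, 50)),
            ),
            max_size=12,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_round_trip_read_write(self, tmp_path_factory, rows):
        """read(write(X)) == X for randomized records."""
        records = []
        for i, (pos, cons, depth, clinvar, af, sift, poly, run) in enumerate(rows):
            records.append(
                (
                    VariantRecord(
                        patient_id=f"P{i}",
                        chrom="chr2",
                        pos=pos,
                        ref="A",
                        alt="T",
                        gene="ATM",
                        consequence=cons,
                        zygosity=Zygosity.HETEROZYGOUS,
                        depth=depth,
                        alt_depth=depth // 2,
                    ),
                    AnnotationBundle(
                        clinvar_status=clinvar,
                        af_exac=float(af) if af is not None else None,
                        sift=sift,
                        polyphen=poly,
                        homopolymer_run=run,
                    ),
                )
            )
        path = tmp_path_factory.mktemp("rt") / "t.tsv"
        write_variant_table(records, path)
        assert read_variant_table(path) == records

    def test_empty_string_means_missing(self, tmp_path):
        path = tmp_path / "t.tsv"
        record = VariantRecord(
            patient_id="P1", chrom="chr1", pos=5, ref="A", alt="G", gene="NBN",
            consequence=Consequence.MISSENSE, zygosity=Zygosity.HETEROZYGOUS,
            depth=30, alt_depth=15,
        )
        write_variant_table([(record, AnnotationBundle())], path)
        (_, bundle), = read_variant_table(path)
        assert bundle.sift is SiftCall.MISSING
        assert bundle.af_exac is None
        assert bundle.clinvar_status is ClinvarStatus.ABSENT


class TestClassificationReport:
    @staticmethod
    def _classified(pos=100, patient="P1"):
        record = VariantRecord(
            patient_id=patient, chrom="chr13", pos=pos, ref="CT", alt="C",
            gene="BRCA2", consequence=Consequence.FRAMESHIFT,
            zygosity=Zygosity.HETEROZYGOUS, depth=80, alt_depth=40,
        )
        return classify_variant(record, AnnotationBundle(af_exac=1e-5))

    def test_pathogenic_frameshift_row_round_trips_with_trace(self, tmp_path):
        from hboc_triage.pipeline import read_classification_report

        cv = self._classified()
        path = tmp_path / "report.tsv"
        write_classification_report([cv], None, path)
        (back,) = read_classification_report(path)
        assert back.label is Label.PATHOGENIC
        assert "null_variant_pathogenic" in back.rule_trace
        assert back.variant == cv.variant
        # variant columns also parse under the plain table reader
        (record, _), = read_variant_table(path)
        assert record == cv.variant

    def test_same_input_twice_is_byte_identical(self, tmp_path):
        cvs = [self._classified(pos=p) for p in (300, 100, 200)]
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_classification_report(cvs, None, p1)
        write_classification_report(cvs, None, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_duplicate_key_raises(self, tmp_path):
        cv = self._classified()
        with pytest.raises(DuplicateRecordError):
            write_classification_report([cv, cv], None, tmp_path / "r.tsv")

    def test_empty_input_writes_header_only(self, tmp_path):
        path = tmp_path / "r.tsv"
        write_classification_report([], None, path)
        assert len(path.read_text().splitlines()) == 1


class TestInvariantsAndMappings:
    def test_alt_depth_cannot_exceed_depth(self):
        with pytest.raises(ValueError):
            VariantRecord(
                patient_id="P", chrom="1", pos=1, ref="A", alt="T", gene="G",
                consequence=Consequence.MISSENSE, zygosity=Zygosity.HETEROZYGOUS,
                depth=10, alt_depth=11,
            )

    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("Pathogenic", ClinvarStatus.PATHOGENIC),
            ("Pathogenic/Likely_pathogenic", ClinvarStatus.LIKELY_PATHOGENIC),
            ("Likely_pathogenic", ClinvarStatus.LIKELY_PATHOGENIC),
            ("Conflicting_interpretations_of_pathogenicity", ClinvarStatus.CONFLICTING),
            ("Benign/Pathogenic", ClinvarStatus.CONFLICTING),
            ("Likely_benign", ClinvarStatus.LIKELY_BENIGN),
            ("Benign", ClinvarStatus.BENIGN),
            ("Uncertain_significance", ClinvarStatus.UNCERTAIN),
            ("", ClinvarStatus.ABSENT),
            (None, ClinvarStatus.ABSENT),
            ("drug_response", ClinvarStatus.UNCERTAIN),
        ],
    )
    def test_clinvar_vocabulary_mapping(self, raw, expected):
        assert parse_clinvar_status(raw) is expected

    def test_most_severe_consequence_prefers_truncating_then_longest_cds(self):
        assert most_severe_consequence(
            [(Consequence.SYNONYMOUS, 3000), (Consequence.FRAMESHIFT, 1000)]
        ) == (Consequence.FRAMESHIFT, 1000)
        # severity tie between two truncating classes: longest cds wins
        assert most_severe_consequence(
            [(Consequence.STOP_GAIN, 1000), (Consequence.SPLICE_DONOR, 2000)]
        ) == (Consequence.SPLICE_DONOR, 2000)
        assert most_severe_consequence(
            [(Consequence.MISSENSE, None), (Consequence.INFRAME_INDEL, 5000)]
        )[0] is Consequence.MISSENSE
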