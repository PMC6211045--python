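"""Rarity gate and five-tier classification cascade."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hboc_triage.classifier import (
    ClassifierConfig,
    Disposition,
    Label,
    classify_variant,
    is_null_variant,
    is_rare,
    near_3prime_end,
)
from hboc_triage.variant_model import (
    AnnotationBundle,
    ClinvarStatus,
    Consequence,
    PolyphenCall,
    SiftCall,
    VariantRecord,
    Zygosity,
)


def make_record(consequence=Consequence.MISSENSE):
    return VariantRecord(
        patient_id="P1", chrom="chr17", pos=1000, ref="C", alt="T", gene="BRCA1",
        consequence=consequence, zygosity=Zygosity.HETEROZYGOUS, depth=70,
        alt_depth=35,
    )


class TestPredicates:
    @pytest.mark.parametrize(
        "consequence, expected",
        [
            (Consequence.FRAMESHIFT, True),
            (Consequence.STOP_GAIN, True),
            (Consequence.STOP_LOSS, True),
            (Consequence.SPLICE_DONOR, True),
            (Consequence.SPLICE_ACCEPTOR, True),
            (Consequence.MISSENSE, False),
            (Consequence.SYNONYMOUS, False),
            (Consequence.INFRAME_INDEL, False),
            (Consequence.OTHER, False),
        ],
    )
    def test_null_variant_classes(self, consequence, expected):
        assert is_null_variant(consequence) is expected

    def test_rarity_over_all_presence_patterns(self):
        """Brute force over the 2^3 presence patterns: rare iff every
        present frequency is below threshold."""
        rare_af, common_af = 2.47e-5, 0.0012
        for mask in itertools.product([None, rare_af], repeat=3):
            bundle = AnnotationBundle(af_exac=mask[0], af_1000g=mask[1], af_esp=mask[2])
            assert is_rare(bundle, 0.001) is True
        for present in itertools.product([None, rare_af, common_af], repeat=3):
            bundle = AnnotationBundle(
                af_exac=present[0], af_1000g=present[1], af_esp=present[2]
            )
            expected = all(af is None or af < 0.001 for af in present)
            assert is_rare(bundle, 0.001) is expected

    def test_rare_single_exac_frequency(self):
        assert is_rare(AnnotationBundle(af_exac=2.47e-5), 0.001) is True
        assert is_rare(AnnotationBundle(af_exac=9e-4, af_esp=1.2e-3), 0.001) is False

    @pytest.mark.parametrize(
        "cds_pos, cds_len, expected",
        [(990, 1000, True), (500, 1000, False), (950, 1000, False)],
    )
    def test_three_prime_end_strict_boundary(self, cds_pos, cds_len, expected):
        assert near_3prime_end(cds_pos, cds_len, 0.95) is expected

    def test_three_prime_end_missing_coordinates_false(self):
        assert near_3prime_end(None, 1000) is False
        assert near_3prime_end(990, None) is False

    def test_three_prime_end_invariant_violation(self):
        with pytest.raises(ValueError):
            near_3prime_end(1001, 1000)


class TestCascadeExamples:
    def test_recurrent_stop_gain_is_pathogenic(self):
        cv = classify_variant(
            make_record(Consequence.STOP_GAIN),
            AnnotationBundle(
                clinvar_status=ClinvarStatus.PATHOGENIC, af_exac=1e-5,
                cds_pos=7480, cds_len=10257,
            ),
        )
        assert cv.label is Label.PATHOGENIC
        assert "null_variant_pathogenic" in cv.rule_trace

    def test_novel_frameshift_with_rare_exac_is_pathogenic(self):
        cv = classify_variant(
            make_record(Consequence.FRAMESHIFT),
            AnnotationBundle(af_exac=2.47e-5),
        )
        assert cv.label is Label.PATHOGENIC

    def test_3prime_null_with_conflicting_clinvar_is_vus(self):
        cv = classify_variant(
            make_record(Consequence.STOP_GAIN),
            AnnotationBundle(
                clinvar_status=ClinvarStatus.CONFLICTING, cds_pos=990, cds_len=1000,
            ),
        )
        assert cv.label is Label.VUS
        assert "null_3prime_conflicting_vus" in cv.rule_trace

    def test_rare_predicted_deleterious_missense_is_vus(self):
        cv = classify_variant(
            make_record(Consequence.MISSENSE),
            AnnotationBundle(af_exac=1e-4, sift=SiftCall.DELETERIOUS),
        )
        assert cv.label is Label.VUS
        assert "missense_predicted_deleterious_vus" in cv.rule_trace

    def test_common_missense_is_excluded(self):
        cv = classify_variant(
            make_record(Consequence.MISSENSE), AnnotationBundle(af_1000g=0.05)
        )
        assert cv.disposition is Disposition.EXCLUDED_COMMON
        assert cv.label is Label.NONE

    def test_benign_frameshift_stays_pathogenic_with_warning(self):
        cv = classify_variant(
            make_record(Consequence.FRAMESHIFT),
            AnnotationBundle(clinvar_status=ClinvarStatus.BENIGN),
        )
        assert cv.label is Label.PATHOGENIC
        assert "warning_clinvar_benign_conflict" in cv.rule_trace

    def test_novel_allele_notes_missing_population_data(self):
        cv = classify_variant(make_record(Consequence.MISSENSE), AnnotationBundle())
        assert "no_population_data" in cv.rule_trace


def oracle_label(consequence, clinvar, rare, at_3prime, sift, polyphen):
    """Independent flat decision table for the cascade (the oracle is a
    direct transcription of the rules, not a call into the classifier)."""
    if not rare:
        return ("excluded_common", "none")
    null = consequence in {
        Consequence.FRAMESHIFT, Consequence.STOP_GAIN, Consequence.STOP_LOSS,
        Consequence.SPLICE_DONOR, Consequence.SPLICE_ACCEPTOR,
    }
    if null and at_3prime and clinvar is ClinvarStatus.CONFLICTING:
        return ("retained", "vus")
    if null:
        return ("retained", "pathogenic")
    if consequence is Consequence.MISSENSE and clinvar is ClinvarStatus.PATHOGENIC:
        return ("retained", "pathogenic")
    if consequence is Consequence.MISSENSE and clinvar is ClinvarStatus.LIKELY_PATHOGENIC:
        return ("retained", "likely_pathogenic")
    if consequence is Consequence.MISSENSE and (
        sift is SiftCall.DELETERIOUS or polyphen is PolyphenCall.PROBABLY_DAMAGING
    ):
        return ("retained", "vus")
    if clinvar is ClinvarStatus.BENIGN:
        return ("retained", "benign")
    if clinvar is ClinvarStatus.LIKELY_BENIGN:
        return ("retained", "likely_benign")
    return ("retained", "vus")


class TestCascadeProperties:
    def test_exhaustive_truth_table_agreement(self):
        """The cascade matches the flat decision table on the full
        enumeration of consequence x ClinVar x rarity x 3'-end x
        predictor-call combinations."""
        for consequence, clinvar, rare, at_3prime, sift, polyphen in itertools.product(
            Consequence, ClinvarStatus, [True, False], [True, False, None],
            SiftCall, PolyphenCall,
        ):
            bundle = AnnotationBundle(
                clinvar_status=clinvar,
                af_exac=1e-5 if rare else 0.01,
                sift=sift,
                polyphen=polyphen,
                cds_pos={True: 990, False: 500, None: None}[at_3prime],
                cds_len=None if at_3prime is None else 1000,
            )
            cv = classify_variant(make_record(consequence), bundle)
            expected = oracle_label(
                consequence, clinvar, rare, bool(at_3prime), sift, polyphen
            )
            assert (cv.disposition.value, cv.label.value) == expected, (
                consequence, clinvar, rare, at_3prime, sift, polyphen,
            )

    def test_determinism_identical_traces(self):
        bundle = AnnotationBundle(af_exac=1e-4, sift=SiftCall.DELETERIOUS)
        first = classify_variant(make_record(), bundle)
        second = classify_variant(make_record(), bundle)
        assert first.rule_trace == second.rule_trace
        assert first.label is second.label

    @given(
        afs=st.tuples(
            *[st.one_of(st.none(), st.floats(0, 0.5, allow_nan=False))] * 3
        ),
        drop=st.integers(0, 2),
        factor=st.floats(0.0, 1.0, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotonicity_rarer_never_becomes_excluded(self, afs, drop, factor):
        """Lowering any allele frequency never moves a variant from
        retained to excluded_common."""
        base = AnnotationBundle(af_exac=afs[0], af_1000g=afs[1], af_esp=afs[2])
        before = classify_variant(make_record(), base)
        lowered = dict(zip(("af_exac", "af_1000g", "af_esp"), afs))
        key = list(lowered)[drop]
        if lowered[key] is not None:
            lowered[key] = lowered[key] * factor
        after = classify_variant(make_record(), AnnotationBundle(**lowered))
        if before.disposition is Disposition.RETAINED:
            assert after.disposition is Disposition.RETAINED

    def test_pathogenic_labels_only_for_rare_variants(self):
        """Rarity is a gate: no P/LP label co-occurs with a common AF."""
        for clinvar in ClinvarStatus:
            for consequence in Consequence:
                cv = classify_variant(
                    make_record(consequence),
                    AnnotationBundle(clinvar_status=clinvar, af_exac=0.02),
                )
                assert cv.label not in (Label.PATHOGENIC, Label.LIKELY_PATHOGENIC)
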