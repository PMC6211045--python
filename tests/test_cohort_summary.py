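"""Carrier status, cohort summarization and univariate association."""

import math

import numpy as np
import pytest

from hboc_triage.classifier import (
    ClassifiedVariant,
    Disposition,
    Label,
    classify_variant,
)
from hboc_triage.cohort_summary import (
    DegenerateFitError,
    carrier_status,
    percent,
    summarize_cohort,
    table2_breakdown,
    univariate_association,
)
from hboc_triage.synthetic_cohort import (
    fixture_classified_variants,
    fixture_from_paper_counts,
)
from hboc_triage.variant_model import (
    AnnotationBundle,
    ClinvarStatus,
    Consequence,
    Group,
    Patient,
    VariantRecord,
    Zygosity,
)


def classified(patient_id, gene, consequence, label_kwargs=None, pos=100):
    record = VariantRecord(
        patient_id=patient_id, chrom="chr1", pos=pos, ref="CT", alt="C",
        gene=gene, consequence=consequence, zygosity=Zygosity.HETEROZYGOUS,
        depth=70, alt_depth=35,
    )
    bundle = AnnotationBundle(**(label_kwargs or {"af_exac": 1e-5}))
    return classify_variant(record, bundle)


class TestCarrierStatus:
    def test_pathogenic_frameshift_confers_status(self):
        assert carrier_status([classified("P1", "BRCA1", Consequence.FRAMESHIFT)])

    def test_vus_only_does_not(self):
        from hboc_triage.variant_model import SiftCall

        vus = classified(
            "P1", "ATM", Consequence.MISSENSE,
            {"af_exac": 1e-5, "sift": SiftCall.DELETERIOUS},
        )
        assert vus.label is Label.VUS
        assert not carrier_status([vus])

    def test_empty_list(self):
        assert not carrier_status([])


class TestSummarizeCohort:
    def test_study_fixture_reproduces_printed_percentages(self, panel):
        """The in-study carrier structure (46/300 + 6/27) yields the
        published pooled, BRCA and share percentages."""
        patients, assignments = fixture_from_paper_counts()
        cvs = fixture_classified_variants(patients, assignments, panel)
        summary = summarize_cohort(patients, cvs, panel)
        assert summary.carriers_total == 52
        assert summary.carrier_pct() == 15.9            # 52/327
        assert summary.carrier_pct(decimals=0) == 16.0
        assert summary.carrier_pct(Group.CANCER) == 15.3
        assert summary.carrier_pct(Group.HIGH_RISK) == 22.2
        assert summary.brca_carriers == 24
        assert summary.brca_carrier_pct() == 7.3        # 24/327
        assert summary.non_brca_share_pct() == 53.8     # 28/52
        assert summary.brca_share_pct() == 46.2

    def test_recurrence_table_counts_distinct_patients(self, panel):
        patients, assignments = fixture_from_paper_counts()
        cvs = fixture_classified_variants(patients, assignments, panel)
        summary = summarize_cohort(patients, cvs, panel)
        recurrent = {r.display: r.n_patients for r in summary.recurrent_alleles()}
        assert recurrent["c.682delG"] == 5       # recurrent BRCA1 frameshift
        assert recurrent["c.del_exon9_12"] == 5  # founder deletion
        assert recurrent["c.7480C>T"] == 2       # recurrent BRCA2 stop gain
        brca1 = next(gc for gc in summary.gene_counts if gc.gene == "BRCA1")
        assert (brca1.cancer, brca1.high_risk, brca1.total) == (15, 2, 17)
        assert percent(5, 17, decimals=0) == 29.0

    def test_group_decomposition_and_count_conservation(self, panel):
        patients, assignments = fixture_from_paper_counts()
        cvs = fixture_classified_variants(patients, assignments, panel)
        summary = summarize_cohort(patients, cvs, panel)
        assert summary.carriers_total == sum(summary.carriers.values())
        assert sum(gc.total for gc in summary.gene_counts) >= summary.carriers_total
        assert summary.brca_carriers + summary.non_brca_carriers == summary.carriers_total
        for group in Group:
            assert (
                summary.carriers[group]
                + summary.vus_only_patients[group]
                + summary.negative_patients[group]
                == summary.n_patients[group]
            )

    def test_no_variants_no_division_by_zero(self):
        patients = [Patient(patient_id="P1", group=Group.CANCER)]
        summary = summarize_cohort(patients, [], None)
        assert summary.carriers_total == 0
        assert summary.carrier_pct() == 0.0
        assert summary.brca_share_pct() == 0.0

    def test_orphan_patient_id_is_referential_error(self):
        patients = [Patient(patient_id="P1", group=Group.CANCER)]
        cv = classified("GHOST", "BRCA1", Consequence.FRAMESHIFT)
        with pytest.raises(ValueError, match="referential"):
            summarize_cohort(patients, [cv], None)

    def test_percent_rounds_half_away_from_zero(self):
        assert percent(1, 8) == 12.5
        assert percent(1, 16, decimals=1) == 6.3     # 6.25 -> 6.3
        assert percent(46, 300) == 15.3
        assert percent(187, 300) == 62.3


class TestTable2Breakdown:
    def test_fixture_reproduces_clinical_margins(self):
        patients, _ = fixture_from_paper_counts()
        cancer = [p for p in patients if p.group is Group.CANCER]
        table = table2_breakdown(cancer)
        bmi = {cat: (count, pct) for cat, count, pct in table["bmi"]}
        assert bmi["overweight"] == (118, 39.3)
        assert bmi["obese"] == (66, 22.0)
        assert bmi["extreme_obese"] == (3, 1.0)
        combined = bmi["overweight"][0] + bmi["obese"][0] + bmi["extreme_obese"][0]
        assert percent(combined, len(cancer)) == 62.3
        alcohol = {cat: count for cat, count, _ in table["alcohol"]}
        assert alcohol == {"no": 278, "yes": 16, "missing": 6}

    def test_all_missing_is_its_own_category(self):
        patients = [Patient(patient_id=f"P{i}", group=Group.CANCER) for i in range(4)]
        table = table2_breakdown(patients)
        assert ("missing", 4, 100.0) in table["bmi"]

    def test_single_patient_is_100_percent(self):
        patient = Patient(patient_id="P1", group=Group.CANCER, alcohol="yes")
        table = table2_breakdown([patient])
        assert ("yes", 1, 100.0) in table["alcohol"]

    def test_percentages_match_count_ratios(self):
        patients, _ = fixture_from_paper_counts()
        cancer = [p for p in patients if p.group is Group.CANCER]
        for rows in table2_breakdown(cancer).values():
            assert sum(count for _, count, _ in rows) == len(cancer)
            for _, count, pct in rows:
                assert pct == percent(count, len(cancer))


class TestUnivariateAssociation:
    def test_recovers_planted_age_effect_within_2se(self):
        """Parameter recovery: logit p = -3 + 0.08 * (40 - age) at
        n = 2000 recovers the age coefficient within +/- 2 SE."""
        rng = np.random.default_rng(2024)
        age = rng.normal(41.0, 7.3, size=2000)
        logit = -3.0 + 0.08 * (40.0 - age)
        carrier = rng.random(2000) < 1.0 / (1.0 + np.exp(-logit))
        result = univariate_association(list(age), list(carrier))
        assert result.n_used == 2000
        assert abs(result.coef - (-0.08)) <= 2 * result.se
        assert result.odds_ratio == pytest.approx(math.exp(result.coef))
        assert result.significant

    def test_missing_continuous_rows_are_dropped(self):
        rng = np.random.default_rng(3)
        age = [float(a) for a in rng.normal(41, 7, 200)]
        carrier = [bool(rng.random() < 0.3) for _ in age]
        age[0] = None
        age[5] = None
        result = univariate_association(age, carrier)
        assert result.n_used == 198

    def test_constant_covariate_is_degenerate(self):
        with pytest.raises(DegenerateFitError):
            univariate_association([5.0] * 50, [i % 2 == 0 for i in range(50)])

    def test_complete_separation_is_flagged_not_raised(self):
        x = [float(i) for i in range(40)]
        y = [i >= 20 for i in range(40)]
        result = univariate_association(x, y)
        assert result.separated
        assert math.isinf(result.odds_ratio)
        assert math.isnan(result.p_value)

    def test_categorical_with_missing_level(self):
        rng = np.random.default_rng(4)
        values = ["yes"] * 120 + ["no"] * 100 + [None] * 30
        carrier = [bool(rng.random() < (0.4 if v == "yes" else 0.1)) for v in values]
        result = univariate_association(values, carrier)
        assert result.covariate_type == "categorical"
        assert result.n_used == 250
        assert set(result.per_level) <= {"yes", "no", "missing"}

    def test_null_covariate_usually_not_significant(self):
        rng = np.random.default_rng(5)
        hits = 0
        for _ in range(60):
            x = rng.normal(0, 1, 400)
            y = rng.random(400) < 0.2
            if univariate_association(list(x), list(y)).significant:
                hits += 1
        assert hits <= 10  # ~5% expected; generous bound for 60 reps
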