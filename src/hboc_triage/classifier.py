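"""Population-rarity filter and five-tier classification cascade.

The cascade operationalises the ACMG-style triage used in germline
hereditary-cancer panel screens:

1.  a variant common in any population database that reports it
    (minor allele frequency >= ``maf_threshold`` in ExAC, 1000 Genomes
    or ESP6500) is dismissed as natural variation (``excluded_common``);
2.  a null variant (stop gain/loss, frameshift, canonical splice) at
    the 3' extreme end of the coding sequence with a conflicting ClinVar
    record is downgraded to VUS;
3.  any other null variant is unequivocally pathogenic;
4-5. a missense variant asserted pathogenic / likely pathogenic in
    ClinVar takes that label;
6.  a rare missense variant called deleterious by SIFT or probably
    damaging by PolyPhen-2, with no further evidence, is a VUS;
7.  a benign-side ClinVar assertion yields benign / likely benign;
8.  everything else is a VUS by default.

Each rule evaluation is appended to an auditable ``rule_trace``.
Rarity is a gate: pathogenic and likely-pathogenic labels are only ever
assigned to rare variants.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

from hboc_triage.variant_model import (
    AnnotationBundle,
    ClinvarStatus,
    Consequence,
    PolyphenCall,
    SiftCall,
    VariantRecord,
)

__all__ = [
    "Disposition",
    "Label",
    "ClassifiedVariant",
    "ClassifierConfig",
    "is_null_variant",
    "is_rare",
    "near_3prime_end",
    "classify_variant",
    "NULL_CONSEQUENCES",
]


class Disposition(enum.Enum):
    RETAINED = "retained"
    EXCLUDED_QC = "excluded_qc"
    EXCLUDED_COMMON = "excluded_common"


class Label(enum.Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    VUS = "vus"
    LIKELY_BENIGN = "likely_benign"
    BENIGN = "benign"
    NONE = "none"


#: Loss-of-function consequence classes: protein-truncating plus
#: canonical splice-site disruption.
NULL_CONSEQUENCES = frozenset(
    {
        Consequence.FRAMESHIFT,
        Consequence.STOP_GAIN,
        Consequence.STOP_LOSS,
        Consequence.SPLICE_DONOR,
        Consequence.SPLICE_ACCEPTOR,
    }
)


@dataclass(frozen=True)
class ClassifiedVariant:
    """A variant plus its triage disposition, five-tier label and the
    ordered trace of rules evaluated. ``label`` is ``NONE`` exactly when
    the record was not retained."""

    variant: VariantRecord
    annotations: AnnotationBundle
    disposition: Disposition
    label: Label
    rule_trace: tuple[str, ...]

    def __post_init__(self) -> None:
        if (self.label is Label.NONE) != (self.disposition is not Disposition.RETAINED):
            raise ValueError(
                "label must be 'none' exactly when the record is not retained "
                f"(got label={self.label.value}, disposition={self.disposition.value})"
            )
        if self.disposition is Disposition.RETAINED and not self.rule_trace:
            raise ValueError("retained records must carry a non-empty rule trace")


@dataclass(frozen=True)
class ClassifierConfig:
    """Cascade parameters.

    ``maf_threshold`` (default 0.001): a variant is rare iff every
    population database that reports it gives a frequency strictly below
    this. ``three_prime_fraction`` (default 0.95): the "3' extreme end"
    of a gene is the terminal fraction of its coding sequence, i.e.
    cds_pos / cds_len strictly greater than this.
    """

    maf_threshold: float = 0.001
    three_prime_fraction: float = 0.95

    def __post_init__(self) -> None:
        if not (0.0 < self.maf_threshold < 1.0):
            raise ValueError("maf_threshold must lie in (0, 1)")
        if not (0.0 < self.three_prime_fraction < 1.0):
            raise ValueError("three_prime_fraction must lie in (0, 1)")


def is_null_variant(consequence: Consequence) -> bool:
    """True for loss-of-function classes: stop gain/loss, frameshift
    indels, and canonical splice donor/acceptor disruption."""
    return consequence in NULL_CONSEQUENCES


def is_rare(annotations: AnnotationBundle, maf_threshold: float = 0.001) -> bool:
    """True iff every *present* population frequency (ExAC, 1000G,
    ESP6500) is strictly below ``maf_threshold``.

    An allele absent from all three databases is treated as novel and
    rare (the caller notes ``no_population_data`` in the trace). This is
    the strict reading of rarity "in either database": an allele common
    in any panel that reports it is natural variation.
    """
    present = [
        af for af in annotations.population_frequencies.values() if af is not None
    ]
    return all(af < maf_threshold for af in present)


def near_3prime_end(
    cds_pos: Optional[int],
    cds_len: Optional[int],
    three_prime_fraction: float = 0.95,
) -> bool:
    """True iff cds_pos / cds_len > ``three_prime_fraction`` (strict).

    Missing coordinates return False: without a position the 3'-end
    rescue rule cannot fire and a null variant falls through to the
    default pathogenic rule.
    """
    if cds_pos is None or cds_len is None:
        return False
    if cds_pos > cds_len:
        raise ValueError(f"cds_pos ({cds_pos}) exceeds cds_len ({cds_len})")
    if cds_pos < 1 or cds_len < 1:
        raise ValueError("cds coordinates are 1-based and must be >= 1")
    return cds_pos / cds_len > three_prime_fraction


def classify_variant(
    record: VariantRecord,
    annotations: AnnotationBundle,
    config: ClassifierConfig = ClassifierConfig(),
) -> ClassifiedVariant:
    """Run the rarity gate and five-tier cascade on one QC-passed record.

    Deterministic and total: every input receives exactly one label (or
    the ``excluded_common`` disposition) and an ordered rule trace
    recording each predicate evaluated. The disposition of QC-failed
    records is assigned by the pipeline driver, not here.
    """
    trace: list[str] = []

    # Gate: population rarity.
    present_afs = [
        af for af in annotations.population_frequencies.values() if af is not None
    ]
    if not present_afs:
        trace.append("no_population_data")
    if not is_rare(annotations, config.maf_threshold):
        trace.append("common_in_population")
        return ClassifiedVariant(
            variant=record,
            annotations=annotations,
            disposition=Disposition.EXCLUDED_COMMON,
            label=Label.NONE,
            rule_trace=tuple(trace),
        )
    trace.append("rarity_pass")

    null = is_null_variant(record.consequence)
    clinvar = annotations.clinvar_status

    # Rule 2: 3'-end null variant with conflicting ClinVar record -> VUS.
    if null:
        if annotations.cds_pos is None or annotations.cds_len is None:
            trace.append("cds_coordinates_missing")
            at_3prime = False
        else:
            at_3prime = near_3prime_end(
                annotations.cds_pos, annotations.cds_len, config.three_prime_fraction
            )
        if at_3prime and clinvar is ClinvarStatus.CONFLICTING:
            trace.append("null_3prime_conflicting_vus")
            return _retained(record, annotations, Label.VUS, trace)
        # Rule 3: null variants are unequivocally pathogenic.
        trace.append("null_variant_pathogenic")
        if clinvar in (ClinvarStatus.BENIGN, ClinvarStatus.LIKELY_BENIGN):
            # Auditability: the LoF rule overrides a benign assertion.
            trace.append("warning_clinvar_benign_conflict")
        return _retained(record, annotations, Label.PATHOGENIC, trace)

    if record.consequence is Consequence.MISSENSE:
        # Rule 4/5: ClinVar-asserted missense.
        if clinvar is ClinvarStatus.PATHOGENIC:
            trace.append("missense_clinvar_pathogenic")
            return _retained(record, annotations, Label.PATHOGENIC, trace)
        if clinvar is ClinvarStatus.LIKELY_PATHOGENIC:
            trace.append("missense_clinvar_likely_pathogenic")
            return _retained(record, annotations, Label.LIKELY_PATHOGENIC, trace)
        # Rule 6: in-silico deleterious missense with no further evidence.
        if (
            annotations.sift is SiftCall.DELETERIOUS
            or annotations.polyphen is PolyphenCall.PROBABLY_DAMAGING
        ):
            trace.append("missense_predicted_deleterious_vus")
            return _retained(record, annotations, Label.VUS, trace)

    # Rule 7: benign-side ClinVar assertion.
    if clinvar is ClinvarStatus.BENIGN:
        trace.append("clinvar_benign")
        return _retained(record, annotations, Label.BENIGN, trace)
    if clinvar is ClinvarStatus.LIKELY_BENIGN:
        trace.append("clinvar_likely_benign")
        return _retained(record, annotations, Label.LIKELY_BENIGN, trace)

    # Rule 8: default.
    trace.append("default_uncertain")
    return _retained(record, annotations, Label.VUS, trace)


def _retained(
    record: VariantRecord,
    annotations: AnnotationBundle,
    label: Label,
    trace: list[str],
) -> ClassifiedVariant:
    return ClassifiedVariant(
        variant=record,
        annotations=annotations,
        disposition=Disposition.RETAINED,
        label=label,
        rule_trace=tuple(trace),
    )
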