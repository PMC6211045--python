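"""Domain types for annotated germline variants, patients and panels.

Variants are represented post-annotation: the pipeline's contract starts
where an upstream caller/annotator (e.g. GATK + ANNOVAR) ends, with one
:class:`VariantRecord` per (patient, alt allele) and an
:class:`AnnotationBundle` carrying the external evidence used by the
filters and the classification cascade.

Two on-disk representations are supported: annotated VCF 4.x (annotation
INFO keys are configurable) and a flat tab-separated "variant table"
dialect with a fixed header, used for all intermediate pipeline files.
Missing values are always represented explicitly (empty string on disk,
``None`` / ``*_MISSING`` enum members in memory) — a record missing a
field is distinguishable from any real value.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "Consequence",
    "Zygosity",
    "ClinvarStatus",
    "SiftCall",
    "PolyphenCall",
    "VariantRecord",
    "AnnotationBundle",
    "PanelGene",
    "RiskCategory",
    "Inheritance",
    "Patient",
    "Group",
    "VariantTableError",
    "VcfParseError",
    "ConfigurationError",
    "DuplicateRecordError",
    "TABLE_COLUMNS",
    "parse_clinvar_status",
    "parse_consequence",
    "most_severe_consequence",
    "read_annotated_vcf",
    "read_variant_table",
    "write_variant_table",
    "write_classification_report",
]


class VariantTableError(ValueError):
    """Malformed row or unknown token in the flat variant-table dialect."""


class VcfParseError(ValueError):
    """Malformed VCF input."""


class ConfigurationError(ValueError):
    """A required annotation field is not mapped, or a config value is invalid."""


class DuplicateRecordError(ValueError):
    """Two records collide on the (patient_id, chrom, pos, alt) key."""


class Consequence(enum.Enum):
    """Coding consequence of a variant on its transcript."""

    FRAMESHIFT = "frameshift"
    STOP_GAIN = "stop_gain"
    STOP_LOSS = "stop_loss"
    SPLICE_DONOR = "splice_donor"
    SPLICE_ACCEPTOR = "splice_acceptor"
    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    INFRAME_INDEL = "inframe_indel"
    OTHER = "other"


#: Severity ranks used to collapse multi-transcript annotations: all
#: protein-truncating / canonical-splice classes rank equal and above
#: missense; ties are broken by the longest coding sequence.
_SEVERITY_RANK = {
    Consequence.FRAMESHIFT: 4,
    Consequence.STOP_GAIN: 4,
    Consequence.STOP_LOSS: 4,
    Consequence.SPLICE_DONOR: 4,
    Consequence.SPLICE_ACCEPTOR: 4,
    Consequence.MISSENSE: 3,
    Consequence.INFRAME_INDEL: 2,
    Consequence.SYNONYMOUS: 1,
    Consequence.OTHER: 0,
}

# Accepted consequence spellings (annotator vocabularies differ).
_CONSEQUENCE_ALIASES = {
    "frameshift": Consequence.FRAMESHIFT,
    "frameshift_variant": Consequence.FRAMESHIFT,
    "frameshift_insertion": Consequence.FRAMESHIFT,
    "frameshift_deletion": Consequence.FRAMESHIFT,
    "stop_gain": Consequence.STOP_GAIN,
    "stop_gained": Consequence.STOP_GAIN,
    "stopgain": Consequence.STOP_GAIN,
    "nonsense": Consequence.STOP_GAIN,
    "stop_loss": Consequence.STOP_LOSS,
    "stop_lost": Consequence.STOP_LOSS,
    "stoploss": Consequence.STOP_LOSS,
    "splice_donor": Consequence.SPLICE_DONOR,
    "splice_donor_variant": Consequence.SPLICE_DONOR,
    "splice_acceptor": Consequence.SPLICE_ACCEPTOR,
    "splice_acceptor_variant": Consequence.SPLICE_ACCEPTOR,
    "missense": Consequence.MISSENSE,
    "missense_variant": Consequence.MISSENSE,
    "nonsynonymous_snv": Consequence.MISSENSE,
    "synonymous": Consequence.SYNONYMOUS,
    "synonymous_variant": Consequence.SYNONYMOUS,
    "synonymous_snv": Consequence.SYNONYMOUS,
    "inframe_indel": Consequence.INFRAME_INDEL,
    "inframe_insertion": Consequence.INFRAME_INDEL,
    "inframe_deletion": Consequence.INFRAME_INDEL,
    "nonframeshift_insertion": Consequence.INFRAME_INDEL,
    "nonframeshift_deletion": Consequence.INFRAME_INDEL,
    "other": Consequence.OTHER,
}


def parse_consequence(token: str) -> Consequence:
    """Map a consequence token to the internal enum.

    Raises :class:`VariantTableError` for unknown tokens, listing the
    accepted vocabulary.
    """
    key = token.strip().lower()
    try:
        return _CONSEQUENCE_ALIASES[key]
    except KeyError:
        accepted = ", ".join(sorted(set(_CONSEQUENCE_ALIASES)))
        raise VariantTableError(
            f"unknown consequence token {token!r}; accepted: {accepted}"
        ) from None


def most_severe_consequence(
    transcripts: Sequence[tuple[Consequence, Optional[int]]],
) -> tuple[Consequence, Optional[int]]:
    """Collapse per-transcript (consequence, cds_len) pairs to one.

    Keeps the most severe consequence under the ordering
    truncating/splice > missense > inframe_indel > synonymous > other;
    ties are broken by the longest coding sequence (missing length sorts
    last).
    """
    if not transcripts:
        raise ValueError("no transcript annotations supplied")
    return max(
        transcripts,
        key=lambda tc: (_SEVERITY_RANK[tc[0]], tc[1] if tc[1] is not None else -1),
    )


class Zygosity(enum.Enum):
    HETEROZYGOUS = "heterozygous"
    HOMOZYGOUS = "homozygous"


class ClinvarStatus(enum.Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    UNCERTAIN = "uncertain"
    CONFLICTING = "conflicting"
    LIKELY_BENIGN = "likely_benign"
    BENIGN = "benign"
    ABSENT = "absent"


class SiftCall(enum.Enum):
    DELETERIOUS = "deleterious"
    TOLERATED = "tolerated"
    MISSING = "missing"


class PolyphenCall(enum.Enum):
    PROBABLY_DAMAGING = "probably_damaging"
    POSSIBLY_DAMAGING = "possibly_damaging"
    BENIGN = "benign"
    MISSING = "missing"


def parse_clinvar_status(raw: Optional[str]) -> ClinvarStatus:
    """Normalise a free-text ClinVar clinical-significance string.

    The classification rules only consume {pathogenic, likely_pathogenic,
    conflicting, benign-side, other}, so the mapping is deliberately
    coarse: a string asserting both pathogenic and benign significance,
    or containing "conflicting", maps to ``CONFLICTING``;
    "pathogenic/likely pathogenic" maps to ``LIKELY_PATHOGENIC``; empty
    or "." means no ClinVar record (``ABSENT``); any other recognised
    ClinVar annotation (not_provided, drug_response, ...) maps to
    ``UNCERTAIN``.
    """
    if raw is None:
        return ClinvarStatus.ABSENT
    text = raw.strip().lower().replace("_", " ").replace("|", "/")
    if text in ("", ".", "absent", "na", "none"):
        return ClinvarStatus.ABSENT
    has_path = "pathogenic" in text
    has_benign = "benign" in text
    if "conflicting" in text or (has_path and has_benign):
        return ClinvarStatus.CONFLICTING
    if has_path:
        # "pathogenic/likely pathogenic" and plain "likely pathogenic"
        # both carry the weaker assertion.
        if "likely pathogenic" in text:
            return ClinvarStatus.LIKELY_PATHOGENIC
        return ClinvarStatus.PATHOGENIC
    if has_benign:
        if "likely benign" in text:
            return ClinvarStatus.LIKELY_BENIGN
        return ClinvarStatus.BENIGN
    if "uncertain" in text or "vus" in text:
        return ClinvarStatus.UNCERTAIN
    return ClinvarStatus.UNCERTAIN


@dataclass(frozen=True)
class VariantRecord:
    """One called variant in one patient (single alt allele).

    Multi-allelic sites are split upstream of this type; ``depth`` and
    ``alt_depth`` are the total and alternate-supporting read counts
    from which the mutant allele fraction is recomputed at filter time.
    """

    patient_id: str
    chrom: str
    pos: int  # 1-based position of the first reference base
    ref: str
    alt: str
    gene: str
    consequence: Consequence
    zygosity: Zygosity
    depth: int
    alt_depth: int
    hgvs_c: Optional[str] = None
    hgvs_p: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.depth < 0 or self.alt_depth < 0:
            raise ValueError("read depths must be non-negative")
        if self.alt_depth > self.depth:
            raise ValueError(
                f"alt_depth ({self.alt_depth}) exceeds depth ({self.depth})"
            )
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical ({self.ref!r})")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")

    @property
    def key(self) -> tuple[str, str, int, str, str]:
        """Genomic identity key (patient, chrom, pos, ref, alt)."""
        return (self.patient_id, self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class AnnotationBundle:
    """External evidence attached to one variant.

    Population allele frequencies come from three databases (ExAC,
    1000 Genomes, ESP6500); ``None`` means the database does not report
    the allele. ``homopolymer_run`` is the length of the longest
    single-base reference run containing or immediately flanking the
    variant position, used to filter indel artifacts of amplicon
    sequencing.
    """

    clinvar_status: ClinvarStatus = ClinvarStatus.ABSENT
    af_exac: Optional[float] = None
    af_1000g: Optional[float] = None
    af_esp: Optional[float] = None
    sift: SiftCall = SiftCall.MISSING
    polyphen: PolyphenCall = PolyphenCall.MISSING
    cds_pos: Optional[int] = None
    cds_len: Optional[int] = None
    homopolymer_run: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("af_exac", "af_1000g", "af_esp"):
            af = getattr(self, name)
            if af is not None and not (0.0 <= af <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {af}")
        if self.cds_pos is not None and self.cds_pos < 1:
            raise ValueError("cds_pos is 1-based and must be >= 1")
        if self.cds_len is not None and self.cds_len < 1:
            raise ValueError("cds_len must be >= 1")
        if (
            self.cds_pos is not None
            and self.cds_len is not None
            and self.cds_pos > self.cds_len
        ):
            raise ValueError(
                f"cds_pos ({self.cds_pos}) exceeds cds_len ({self.cds_len})"
            )
        if self.homopolymer_run is not None and self.homopolymer_run < 1:
            raise ValueError("homopolymer_run must be >= 1")

    @property
    def population_frequencies(self) -> dict[str, Optional[float]]:
        return {
            "af_exac": self.af_exac,
            "af_1000g": self.af_1000g,
            "af_esp": self.af_esp,
        }


class RiskCategory(enum.Enum):
    HIGH = "high"
    MODERATE = "moderate"
    NOT_ESTABLISHED = "not_established"
    NOVEL = "novel"
    UNKNOWN = "unknown"


class Inheritance(enum.Enum):
    AD = "AD"
    AR = "AR"
    AD_AR = "AD_AR"
    XLR = "XLR"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class PanelGene:
    """Per-gene panel metadata: breast-cancer risk tier, ACMG secondary-
    finding reportability, and inheritance pattern."""

    symbol: str
    risk_category: RiskCategory = RiskCategory.UNKNOWN
    acmg_reportable: bool = False
    inheritance: Inheritance = Inheritance.UNKNOWN


class Group(enum.Enum):
    CANCER = "cancer"
    HIGH_RISK = "high_risk"


#: Categorical vocabularies for patient metadata (clinical/epidemiological
#: table). ``None`` (missing) is always additionally allowed.
PATIENT_VOCABULARY: dict[str, frozenset[str]] = {
    "stage": frozenset({"I", "II", "III", "IV"}),
    "histology": frozenset({"DCIS", "LCIS", "IDC", "ILC", "MC"}),
    "er_status": frozenset({"negative", "positive"}),
    "pr_status": frozenset({"negative", "positive"}),
    "her2_status": frozenset({"negative", "positive"}),
    "family_history": frozenset({"yes", "no"}),
    "pregnancy": frozenset({"yes", "no"}),
    "oral_contraceptive_use": frozenset({"yes", "no"}),
    "alcohol": frozenset({"yes", "no"}),
    "tobacco": frozenset({"yes", "no"}),
}


@dataclass(frozen=True)
class Patient:
    """One enrolled individual: group membership plus the clinical and
    epidemiological covariates used in cohort summaries and the
    univariate association tests."""

    patient_id: str
    group: Group
    age_at_diagnosis: Optional[float] = None
    bmi: Optional[float] = None
    stage: Optional[str] = None
    histology: Optional[str] = None
    er_status: Optional[str] = None
    pr_status: Optional[str] = None
    her2_status: Optional[str] = None
    family_history: Optional[str] = None
    pregnancy: Optional[str] = None
    oral_contraceptive_use: Optional[str] = None
    alcohol: Optional[str] = None
    tobacco: Optional[str] = None

    def __post_init__(self) -> None:
        for field_name, vocab in PATIENT_VOCABULARY.items():
            value = getattr(self, field_name)
            if value is not None and value not in vocab:
                raise ValueError(
                    f"{field_name}={value!r} not in vocabulary {sorted(vocab)} "
                    "(use None for missing)"
                )


# ---------------------------------------------------------------------------
# Flat variant-table dialect
# ---------------------------------------------------------------------------

#: Fixed column order of the tab-separated variant-table dialect.
TABLE_COLUMNS = (
    "patient_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "consequence",
    "zygosity",
    "depth",
    "alt_depth",
    "clinvar",
    "af_exac",
    "af_1000g",
    "af_esp",
    "sift",
    "polyphen",
    "cds_pos",
    "cds_len",
    "homopolymer_run",
)

#: Optional columns tolerated (and, for hgvs, consumed) by the reader.
_OPTIONAL_COLUMNS = ("hgvs_c", "hgvs_p")


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, enum.Enum):
        return str(value.value)
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _parse_float(token: str, column: str, line_no: int) -> Optional[float]:
    if token == "":
        return None
    try:
        return float(token)
    except ValueError:
        raise VariantTableError(
            f"line {line_no}: column {column!r}: not a number: {token!r}"
        ) from None


def _parse_int(token: str, column: str, line_no: int, required: bool = False) -> Optional[int]:
    if token == "":
        if required:
            raise VariantTableError(f"line {line_no}: column {column!r} is required")
        return None
    try:
        return int(token)
    except ValueError:
        raise VariantTableError(
            f"line {line_no}: column {column!r}: not an integer: {token!r}"
        ) from None


def _row_to_record(
    row: Mapping[str, str], line_no: int
) -> tuple[VariantRecord, AnnotationBundle]:
    zyg_token = row["zygosity"].strip().lower()
    try:
        zygosity = Zygosity(zyg_token)
    except ValueError:
        raise VariantTableError(
            f"line {line_no}: unknown zygosity {row['zygosity']!r}; accepted: "
            f"{[z.value for z in Zygosity]}"
        ) from None
    sift_token = row["sift"].strip().lower()
    sift = SiftCall.MISSING if sift_token == "" else SiftCall(sift_token)
    poly_token = row["polyphen"].strip().lower()
    polyphen = PolyphenCall.MISSING if poly_token == "" else PolyphenCall(poly_token)
    try:
        record = VariantRecord(
            patient_id=row["patient_id"],
            chrom=row["chrom"],
            pos=_parse_int(row["pos"], "pos", line_no, required=True),
            ref=row["ref"],
            alt=row["alt"],
            gene=row["gene"],
            consequence=parse_consequence(row["consequence"]),
            zygosity=zygosity,
            depth=_parse_int(row["depth"], "depth", line_no, required=True),
            alt_depth=_parse_int(row["alt_depth"], "alt_depth", line_no, required=True),
            hgvs_c=row.get("hgvs_c") or None,
            hgvs_p=row.get("hgvs_p") or None,
        )
        bundle = AnnotationBundle(
            clinvar_status=parse_clinvar_status(row["clinvar"]),
            af_exac=_parse_float(row["af_exac"], "af_exac", line_no),
            af_1000g=_parse_float(row["af_1000g"], "af_1000g", line_no),
            af_esp=_parse_float(row["af_esp"], "af_esp", line_no),
            sift=sift,
            polyphen=polyphen,
            cds_pos=_parse_int(row["cds_pos"], "cds_pos", line_no),
            cds_len=_parse_int(row["cds_len"], "cds_len", line_no),
            homopolymer_run=_parse_int(row["homopolymer_run"], "homopolymer_run", line_no),
        )
    except ValueError as exc:
        if isinstance(exc, VariantTableError):
            raise
        raise VariantTableError(f"line {line_no}: {exc}") from exc
    return record, bundle


def read_variant_table(path) -> list[tuple[VariantRecord, AnnotationBundle]]:
    """Read the tab-separated variant-table dialect.

    Empty strings are missing values. Extra columns (e.g. the
    classification-report columns) are ignored except ``hgvs_c`` /
    ``hgvs_p``, which populate the record when present.
    """
    path = Path(path)
    out: list[tuple[VariantRecord, AnnotationBundle]] = []
    with path.open("r", encoding="utf-8", newline="") as handle:
        header_line = handle.readline()
        if header_line == "":
            raise VariantTableError(f"{path}: empty file (expected a header line)")
        header = header_line.rstrip("\n").split("\t")
        missing = [c for c in TABLE_COLUMNS if c not in header]
        if missing:
            raise VariantTableError(f"{path}: missing required columns {missing}")
        for line_no, line in enumerate(handle, start=2):
            line = line.rstrip("\n")
            if line == "":
                continue
            fields = line.split("\t")
            if len(fields) != len(header):
                raise VariantTableError(
                    f"{path}: line {line_no}: expected {len(header)} fields, "
                    f"got {len(fields)}"
                )
            row = dict(zip(header, fields))
            out.append(_row_to_record(row, line_no))
    return out


def _record_row(record: VariantRecord, bundle: AnnotationBundle) -> list[str]:
    values = {
        "patient_id": record.patient_id,
        "chrom": record.chrom,
        "pos": record.pos,
        "ref": record.ref,
        "alt": record.alt,
        "gene": record.gene,
        "consequence": record.consequence,
        "zygosity": record.zygosity,
        "depth": record.depth,
        "alt_depth": record.alt_depth,
        "clinvar": (
            ""
            if bundle.clinvar_status is ClinvarStatus.ABSENT
            else bundle.clinvar_status
        ),
        "af_exac": bundle.af_exac,
        "af_1000g": bundle.af_1000g,
        "af_esp": bundle.af_esp,
        "sift": "" if bundle.sift is SiftCall.MISSING else bundle.sift,
        "polyphen": "" if bundle.polyphen is PolyphenCall.MISSING else bundle.polyphen,
        "cds_pos": bundle.cds_pos,
        "cds_len": bundle.cds_len,
        "homopolymer_run": bundle.homopolymer_run,
    }
    return [_fmt(values[c]) for c in TABLE_COLUMNS]


def write_variant_table(
    records: Iterable[tuple[VariantRecord, AnnotationBundle]],
    path,
    include_hgvs: bool = False,
) -> None:
    """Write records in the variant-table dialect (deterministic order of
    the input iterable; callers sort if needed)."""
    path = Path(path)
    columns = TABLE_COLUMNS + (_OPTIONAL_COLUMNS if include_hgvs else ())
    with path.open("w", encoding="utf-8", newline="") as handle:
        handle.write("\t".join(columns) + "\n")
        for record, bundle in records:
            row = _record_row(record, bundle)
            if include_hgvs:
                row += [_fmt(record.hgvs_c), _fmt(record.hgvs_p)]
            handle.write("\t".join(row) + "\n")


def write_classification_report(classified_variants, patients, path) -> None:
    """Write the per-variant classification report.

    One row per classified variant, sorted by (patient_id, chrom, pos,
    alt); the variant-table columns round-trip through
    :func:`read_variant_table`, and three extra columns carry the
    disposition, the five-tier label and the fired-rule trace
    (semicolon-joined). ``patients`` is used for referential-integrity
    checking only.

    Raises :class:`DuplicateRecordError` on a (patient, chrom, pos, alt)
    collision.
    """
    path = Path(path)
    known_patients = {p.patient_id for p in patients} if patients is not None else None
    ordered = sorted(
        classified_variants,
        key=lambda cv: (cv.variant.patient_id, cv.variant.chrom, cv.variant.pos, cv.variant.alt),
    )
    seen: set[tuple[str, str, int, str]] = set()
    columns = TABLE_COLUMNS + _OPTIONAL_COLUMNS + ("disposition", "label", "rule_trace")
    with path.open("w", encoding="utf-8", newline="") as handle:
        handle.write("\t".join(columns) + "\n")
        for cv in ordered:
            rec = cv.variant
            key = (rec.patient_id, rec.chrom, rec.pos, rec.alt)
            if key in seen:
                raise DuplicateRecordError(
                    f"duplicate record for patient={key[0]} at {key[1]}:{key[2]} alt={key[3]}"
                )
            seen.add(key)
            if known_patients is not None and rec.patient_id not in known_patients:
                raise ValueError(
                    f"variant references unknown patient_id {rec.patient_id!r}"
                )
            row = _record_row(rec, cv.annotations)
            row += [
                _fmt(rec.hgvs_c),
                _fmt(rec.hgvs_p),
                cv.disposition.value,
                cv.label.value,
                ";".join(cv.rule_trace),
            ]
            handle.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Patient metadata table
# ---------------------------------------------------------------------------

PATIENT_COLUMNS = (
    "patient_id",
    "group",
    "age_at_diagnosis",
    "bmi",
    "stage",
    "histology",
    "er_status",
    "pr_status",
    "her2_status",
    "family_history",
    "pregnancy",
    "oral_contraceptive_use",
    "alcohol",
    "tobacco",
)


def read_patient_table(path) -> list[Patient]:
    """Read the tab-separated patient-metadata dialect (empty = missing)."""
    path = Path(path)
    patients: list[Patient] = []
    with path.open("r", encoding="utf-8", newline="") as handle:
        header_line = handle.readline()
        if header_line == "":
            raise VariantTableError(f"{path}: empty file (expected a header line)")
        header = header_line.rstrip("\n").split("\t")
        missing = [c for c in PATIENT_COLUMNS if c not in header]
        if missing:
            raise VariantTableError(f"{path}: missing required columns {missing}")
        for line_no, line in enumerate(handle, start=2):
            line = line.rstrip("\n")
            if line == "":
                continue
            fields = line.split("\t")
            if len(fields) != len(header):
                raise VariantTableError(
                    f"{path}: line {line_no}: expected {len(header)} fields, "
                    f"got {len(fields)}"
                )
            row = dict(zip(header, fields))
            try:
                patients.append(
                    Patient(
                        patient_id=row["patient_id"],
                        group=Group(row["group"]),
                        age_at_diagnosis=_parse_float(
                            row["age_at_diagnosis"], "age_at_diagnosis", line_no
                        ),
                        bmi=_parse_float(row["bmi"], "bmi", line_no),
                        **{
                            name: (row[name] or None)
                            for name in PATIENT_VOCABULARY
                        },
                    )
                )
            except ValueError as exc:
                if isinstance(exc, VariantTableError):
                    raise
                raise VariantTableError(f"{path}: line {line_no}: {exc}") from exc
    return patients


def write_patient_table(patients: Iterable[Patient], path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as handle:
        handle.write("\t".join(PATIENT_COLUMNS) + "\n")
        for p in patients:
            row = [
                p.patient_id,
                p.group.value,
                _fmt(p.age_at_diagnosis),
                _fmt(p.bmi),
            ] + [_fmt(getattr(p, name)) for name in PATIENT_VOCABULARY]
            handle.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Annotated VCF input
# ---------------------------------------------------------------------------

#: AnnotationBundle fields that read_annotated_vcf can populate from INFO.
_VCF_ANNOTATION_FIELDS = (
    "gene",
    "consequence",
    "clinvar",
    "af_exac",
    "af_1000g",
    "af_esp",
    "sift",
    "polyphen",
    "cds_pos",
    "cds_len",
    "homopolymer_run",
    "hgvs_c",
    "hgvs_p",
)
_REQUIRED_VCF_FIELDS = ("gene", "consequence")


def _info_value(info, key: str, alt_index: int, n_alts: int):
    """Fetch an INFO value, resolving per-allele (Number=A) tuples."""
    if key not in info:
        return None
    value = info[key]
    if isinstance(value, (tuple, list)):
        if len(value) == n_alts:
            value = value[alt_index]
        elif len(value) == 1:
            value = value[0]
        else:
            return None
    if isinstance(value, bytes):
        value = value.decode()
    if value in (None, ".", ""):
        return None
    return value


def read_annotated_vcf(
    path, annotation_field_map: Mapping[str, str]
) -> list[tuple[VariantRecord, AnnotationBundle]]:
    """Read an annotated VCF 4.x into (VariantRecord, AnnotationBundle) pairs.

    ``annotation_field_map`` names the INFO keys carrying each annotation
    (keys of ``_VCF_ANNOTATION_FIELDS``; ``gene`` and ``consequence`` are
    required). One output record is produced per (sample, alt allele)
    carried by that sample's genotype; multi-allelic sites are split with
    allele-specific AD depths. Unmapped or absent optional annotations
    become explicit missing values, never defaults.
    """
    import pysam

    for required in _REQUIRED_VCF_FIELDS:
        if required not in annotation_field_map:
            raise ConfigurationError(
                f"annotation_field_map must map {required!r} to an INFO key"
            )
    unknown = set(annotation_field_map) - set(_VCF_ANNOTATION_FIELDS)
    if unknown:
        raise ConfigurationError(
            f"unknown annotation fields {sorted(unknown)}; "
            f"accepted: {list(_VCF_ANNOTATION_FIELDS)}"
        )

    path = str(path)
    try:
        vcf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise VcfParseError(f"{path}: cannot parse VCF: {exc}") from exc

    out: list[tuple[VariantRecord, AnnotationBundle]] = []
    with vcf:
        for rec in vcf:
            if rec.alts is None:
                continue
            n_alts = len(rec.alts)

            def ann(field: str, alt_index: int):
                key = annotation_field_map.get(field)
                if key is None:
                    return None
                return _info_value(rec.info, key, alt_index, n_alts)

            for sample_name, call in rec.samples.items():
                gt = call.get("GT")
                if gt is None or all(a is None for a in gt):
                    continue
                called = [a for a in gt if a is not None and a > 0]
                for alt_number in sorted(set(called)):
                    alt_index = alt_number - 1
                    alt = rec.alts[alt_index]
                    zygosity = (
                        Zygosity.HOMOZYGOUS
                        if all(a == alt_number for a in gt if a is not None)
                        and len([a for a in gt if a is not None]) > 1
                        else Zygosity.HETEROZYGOUS
                    )
                    ad = call.get("AD")
                    depth = call.get("DP")
                    alt_depth = None
                    if ad is not None and len(ad) > alt_number and ad[alt_number] is not None:
                        alt_depth = int(ad[alt_number])
                    if depth is None and ad is not None:
                        depth = sum(int(a) for a in ad if a is not None)
                    if depth is None or alt_depth is None:
                        raise VcfParseError(
                            f"{path}: {rec.chrom}:{rec.pos} sample {sample_name}: "
                            "FORMAT DP/AD depths are required"
                        )
                    gene = ann("gene", alt_index)
                    cons_token = ann("consequence", alt_index)
                    if gene is None or cons_token is None:
                        raise VcfParseError(
                            f"{path}: {rec.chrom}:{rec.pos}: record lacks the "
                            "mapped gene/consequence annotation"
                        )
                    sift_raw = ann("sift", alt_index)
                    poly_raw = ann("polyphen", alt_index)

                    def _maybe_int(v):
                        return None if v is None else int(v)

                    def _maybe_float(v):
                        return None if v is None else float(v)

                    record = VariantRecord(
                        patient_id=sample_name,
                        chrom=str(rec.chrom),
                        pos=int(rec.pos),
                        ref=str(rec.ref),
                        alt=str(alt),
                        gene=str(gene),
                        consequence=parse_consequence(str(cons_token)),
                        zygosity=zygosity,
                        depth=int(depth),
                        alt_depth=alt_depth,
                        hgvs_c=ann("hgvs_c", alt_index),
                        hgvs_p=ann("hgvs_p", alt_index),
                    )
                    bundle = AnnotationBundle(
                        clinvar_status=parse_clinvar_status(
                            None
                            if (cv := ann("clinvar", alt_index)) is None
                            else str(cv)
                        ),
                        af_exac=_maybe_float(ann("af_exac", alt_index)),
                        af_1000g=_maybe_float(ann("af_1000g", alt_index)),
                        af_esp=_maybe_float(ann("af_esp", alt_index)),
                        sift=(
                            SiftCall.MISSING
                            if sift_raw is None
                            else SiftCall(str(sift_raw).lower())
                        ),
                        polyphen=(
                            PolyphenCall.MISSING
                            if poly_raw is None
                            else PolyphenCall(str(poly_raw).lower())
                        ),
                        cds_pos=_maybe_int(ann("cds_pos", alt_index)),
                        cds_len=_maybe_int(ann("cds_len", alt_index)),
                        homopolymer_run=_maybe_int(ann("homopolymer_run", alt_index)),
                    )
                    out.append((record, bundle))
    return out
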