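"""Synthetic annotated cohorts with planted, known-class variants.

The generator emulates the statistical structure a germline panel
triage assumes downstream of calling and annotation: a two-group cohort
(default 300 cancer cases + 27 unaffected high-risk individuals) in
which each patient carries

* pathogenic variants planted per-gene at configurable prevalence
  (defaults mirror the carrier structure of a Mexican HBOC panel
  screen: BRCA1 ~5% and BRCA2 ~2% of cases, a tail of rarer genes),
  all rare (AF < 0.001) nulls or ClinVar-pathogenic missense;
* a rare-VUS background: rare missense with deleterious in-silico
  calls and no ClinVar assertion;
* common polymorphisms (>= 1 population AF >= 0.001);
* QC artifacts, each violating exactly one threshold (low depth, low
  allele fraction, homopolymer context, or synonymous).

A truth table records every planted variant's intended class and each
patient's intended carrier status, so filter + classifier recovery is
exactly checkable. Random streams are split per patient (keyed by seed,
group and patient index), so enlarging a cohort never perturbs
previously generated patients. Annotation fields are planted directly;
no read-level simulation is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from hboc_triage.classifier import ClassifiedVariant, classify_variant
from hboc_triage.founder_deletion import Locus, PrimerAssay, apply_deletion, simulate_pcr
from hboc_triage.panel import default_panel
from hboc_triage.variant_model import (
    AnnotationBundle,
    ClinvarStatus,
    Consequence,
    Group,
    PanelGene,
    Patient,
    PolyphenCall,
    SiftCall,
    VariantRecord,
    Zygosity,
)

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "generate_cohort",
    "generate_founder_locus",
    "fixture_from_paper_counts",
    "fixture_classified_variants",
    "DEFAULT_PREVALENCE_CANCER",
    "DEFAULT_PREVALENCE_HIGH_RISK",
]

_BASES = "ACGT"
_AA = "ARNDCQEGHILKMFPSTWYV"

# Per-gene pathogenic prevalence defaults. The cancer-group vector mirrors
# the per-gene carrier fractions of the study cohort (46 carriers / 300
# cases overall: BRCA1 15, BRCA2 6, two-carrier genes at 2/300, a tail of
# singletons at 1/300); the high-risk vector mirrors its 6/27 carriers.
DEFAULT_PREVALENCE_CANCER: dict[str, float] = {
    "BRCA1": 15 / 300,
    "BRCA2": 6 / 300,
    "ATM": 2 / 300,
    "FANCI": 2 / 300,
    "ERCC3": 2 / 300,
    "MSR1": 2 / 300,
    "LIG4": 2 / 300,
    "PDE11A": 2 / 300,
    "PTEN": 1 / 300,
    "CHEK2": 1 / 300,
    "NBN": 1 / 300,
    "ATR": 1 / 300,
    "FANCB": 1 / 300,
    "FANCC": 1 / 300,
    "FANCF": 1 / 300,
    "FANCL": 1 / 300,
    "FANCM": 1 / 300,
    "MLH1": 1 / 300,
    "RAD51C": 1 / 300,
    "POLH": 1 / 300,
    "RECQL4": 1 / 300,
    "SDHB": 1 / 300,
    "WRN": 1 / 300,
}

DEFAULT_PREVALENCE_HIGH_RISK: dict[str, float] = {
    "BRCA1": 2 / 27,
    "BRCA2": 1 / 27,
    "FANCF": 1 / 27,
    "PDE11A": 1 / 27,
    "POLH": 1 / 27,
}

# Clinical covariate margins used for metadata sampling (proportions of
# the cancer group in the study's descriptive table).
_AGE_MEAN, _AGE_SD, _AGE_MIN, _AGE_MAX = 41.0, 7.3, 23.0, 69.0
_AGE_MISSING = 16 / 300
_BMI_CATEGORIES = (
    # (probability, low, high)
    (1 / 300, 15.0, 18.5),
    (107 / 300, 18.5, 25.0),
    (118 / 300, 25.0, 30.0),
    (66 / 300, 30.0, 40.0),
    (3 / 300, 40.0, 45.0),
    (5 / 300, None, None),  # missing
)
_CATEGORICAL_MARGINS: dict[str, tuple[tuple[Optional[str], float], ...]] = {
    "alcohol": (("no", 278 / 300), ("yes", 16 / 300), (None, 6 / 300)),
    "tobacco": (("no", 84 / 300), ("yes", 74 / 300), (None, 142 / 300)),
    "pregnancy": (("yes", 256 / 300), ("no", 43 / 300), (None, 1 / 300)),
    "oral_contraceptive_use": (("yes", 115 / 300), ("no", 179 / 300), (None, 6 / 300)),
    "family_history": (("yes", 214 / 300), ("no", 80 / 300), (None, 6 / 300)),
    "histology": (
        ("DCIS", 43 / 300),
        ("LCIS", 18 / 300),
        ("IDC", 189 / 300),
        ("ILC", 16 / 300),
        ("MC", 3 / 300),
        (None, 31 / 300),
    ),
    "stage": (
        ("I", 51 / 300),
        ("II", 115 / 300),
        ("III", 86 / 300),
        ("IV", 10 / 300),
        (None, 38 / 300),
    ),
    "er_status": (("negative", 38 / 300), ("positive", 20 / 300), (None, 242 / 300)),
    "pr_status": (("negative", 135 / 300), ("positive", 22 / 300), (None, 143 / 300)),
    "her2_status": (("negative", 7 / 300), ("positive", 45 / 300), (None, 248 / 300)),
}
_TUMOR_FIELDS = ("histology", "stage", "er_status", "pr_status", "her2_status")

_DEPTH_MEAN, _DEPTH_SD = 70.3, 21.35  # target panel sequencing depth


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of a simulated cohort.

    Rates are expected counts per patient (Poisson); prevalences are
    per-patient carrier probabilities per gene. ``founder_fraction`` is
    the fraction of BRCA1 carriers whose pathogenic allele is the
    founder exon-9-12-style deletion; ``carrier_age_shift`` plants an
    age-carrier association by lowering carriers' mean age at diagnosis
    (years).
    """

    n_cancer: int = 300
    n_high_risk: int = 27
    panel: Optional[tuple[PanelGene, ...]] = None
    prevalence_cancer: Optional[dict[str, float]] = None
    prevalence_high_risk: Optional[dict[str, float]] = None
    vus_rate: float = 0.13
    common_rate: float = 2.0
    artifact_rates: Optional[dict[str, float]] = None
    founder_fraction: float = 5 / 17
    carrier_age_shift: float = 3.0
    seed: int = 0

    def resolved_panel(self) -> list[PanelGene]:
        return list(self.panel) if self.panel is not None else default_panel()

    def resolved_prevalence(self, group: Group) -> dict[str, float]:
        if group is Group.CANCER:
            custom = self.prevalence_cancer
            return dict(DEFAULT_PREVALENCE_CANCER) if custom is None else dict(custom)
        custom = self.prevalence_high_risk
        return dict(DEFAULT_PREVALENCE_HIGH_RISK) if custom is None else dict(custom)

    def resolved_artifact_rates(self) -> dict[str, float]:
        default = {"low_depth": 0.05, "low_vaf": 0.05, "homopolymer": 0.05, "synonymous": 0.10}
        if self.artifact_rates is not None:
            unknown = set(self.artifact_rates) - set(default)
            if unknown:
                raise ValueError(f"unknown artifact kinds {sorted(unknown)}")
            default.update(self.artifact_rates)
        return default

    def validate(self) -> None:
        if self.n_cancer < 0 or self.n_high_risk < 0:
            raise ValueError("cohort sizes must be non-negative")
        if self.vus_rate < 0 or self.common_rate < 0:
            raise ValueError("per-patient rates must be non-negative")
        if not (0.0 <= self.founder_fraction <= 1.0):
            raise ValueError("founder_fraction must lie in [0, 1]")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        panel_symbols = {g.symbol for g in self.resolved_panel()}
        for group in Group:
            prev = self.resolved_prevalence(group)
            for gene, p in prev.items():
                if not (0.0 <= p <= 1.0):
                    raise ValueError(f"prevalence for {gene} must lie in [0, 1]")
                if gene not in panel_symbols:
                    raise ValueError(f"prevalence gene {gene!r} not in panel")
        for kind, rate in self.resolved_artifact_rates().items():
            if rate < 0:
                raise ValueError(f"artifact rate {kind} must be non-negative")

    def expected_carrier_probability(self, group: Group) -> float:
        """Planted per-patient carrier probability 1 - prod(1 - pi_g)."""
        p = 1.0
        for prev in self.resolved_prevalence(group).values():
            p *= 1.0 - prev
        return 1.0 - p


@dataclass
class TruthTable:
    """Planted ground truth: intended class per variant key
    (pathogenic / vus / common / artifact), intended carrier status per
    patient, and the set of founder-deletion carriers."""

    variant_classes: dict[tuple, str] = field(default_factory=dict)
    patient_carrier: dict[str, bool] = field(default_factory=dict)
    founder_carriers: set[str] = field(default_factory=set)


# ---------------------------------------------------------------------------
# Per-gene pseudo-loci and allele helpers
# ---------------------------------------------------------------------------


def _gene_locus(gene_index: int) -> tuple[str, int]:
    return f"chr{(gene_index % 22) + 1}", (gene_index + 1) * 1_000_000


def _snv_alleles(rng: np.random.Generator) -> tuple[str, str]:
    ref = _BASES[rng.integers(4)]
    alt = _BASES[rng.integers(4)]
    while alt == ref:
        alt = _BASES[rng.integers(4)]
    return ref, alt


def _depth_pair(rng: np.random.Generator, homozygous: bool = False) -> tuple[int, int]:
    """(depth, alt_depth) passing the depth and VAF filters."""
    depth = max(10, int(round(rng.normal(_DEPTH_MEAN, _DEPTH_SD))))
    if homozygous:
        alt_depth = depth - int(rng.integers(0, max(1, depth // 20)))
    else:
        alt_depth = int(rng.binomial(depth, 0.5))
        floor = int(np.ceil(0.25 * depth))
        alt_depth = min(depth, max(alt_depth, floor))
    return depth, alt_depth


def _rare_afs(rng: np.random.Generator) -> dict[str, Optional[float]]:
    """AFs all < 0.001 (each database missing with probability 0.4)."""
    out: dict[str, Optional[float]] = {}
    for key in ("af_exac", "af_1000g", "af_esp"):
        if rng.random() < 0.4:
            out[key] = None
        else:
            out[key] = float(10 ** rng.uniform(-6.0, -3.2))
    return out


def _mid_cds(rng: np.random.Generator) -> tuple[int, int]:
    """cds coordinates clear of the 3'-extreme-end region."""
    cds_len = int(rng.integers(900, 8000))
    cds_pos = int(rng.integers(1, int(0.9 * cds_len)))
    return cds_pos, cds_len


def _unique_position(
    rng: np.random.Generator, base: int, used: set[tuple[str, int]], chrom: str
) -> int:
    for _ in range(200):
        pos = base + int(rng.integers(0, 300_000))
        if (chrom, pos) not in used:
            used.add((chrom, pos))
            return pos
    raise RuntimeError("could not place a unique variant position")


_PATHOGENIC_KINDS = (
    (Consequence.FRAMESHIFT, 0.45),
    (Consequence.STOP_GAIN, 0.25),
    (Consequence.STOP_LOSS, 0.03),
    (Consequence.SPLICE_DONOR, 0.09),
    (Consequence.SPLICE_ACCEPTOR, 0.09),
    (Consequence.MISSENSE, 0.09),  # ClinVar-pathogenic missense
)


def _sample_pathogenic_kind(rng: np.random.Generator) -> Consequence:
    r = rng.random()
    acc = 0.0
    for consequence, w in _PATHOGENIC_KINDS:
        acc += w
        if r < acc:
            return consequence
    return Consequence.MISSENSE


# Each gene gets one fixed "recurrent" pathogenic allele (same genomic key
# across patients) used with some probability, so cohorts show allele
# recurrence as real panels do.
_RECURRENT_USE_PROB = 0.3


def _recurrent_allele(gene_index: int) -> tuple[int, str, str, Consequence, str]:
    chrom, base = _gene_locus(gene_index)
    pos = base + 600_000 + gene_index
    return pos, "CT", "C", Consequence.FRAMESHIFT, f"c.{gene_index + 1}del"


_FOUNDER_REF = "G" + "ATC" * 8  # representational deletion allele (25 bp)


def _founder_allele(gene_index: int) -> tuple[int, str, str]:
    _, base = _gene_locus(gene_index)
    return base + 400_000, _FOUNDER_REF, "G"


# ---------------------------------------------------------------------------
# Patient-level generation
# ---------------------------------------------------------------------------


def _sample_age(rng: np.random.Generator, mean: float) -> float:
    while True:
        age = rng.normal(mean, _AGE_SD)
        if _AGE_MIN <= age <= _AGE_MAX:
            return float(round(age, 1))


def _sample_categorical(rng: np.random.Generator, margins) -> Optional[str]:
    r = rng.random()
    acc = 0.0
    for value, p in margins:
        acc += p
        if r < acc:
            return value
    return margins[-1][0]


def _sample_bmi(rng: np.random.Generator) -> Optional[float]:
    r = rng.random()
    acc = 0.0
    for p, low, high in _BMI_CATEGORIES:
        acc += p
        if r < acc:
            if low is None:
                return None
            return float(round(rng.uniform(low, high), 1))
    return None


def _make_patient(
    rng: np.random.Generator,
    patient_id: str,
    group: Group,
    is_carrier: bool,
    carrier_age_shift: float,
) -> Patient:
    age_mean = _AGE_MEAN - (carrier_age_shift if is_carrier else 0.0)
    age = None if rng.random() < _AGE_MISSING else _sample_age(rng, age_mean)
    fields = {
        name: _sample_categorical(rng, margins)
        for name, margins in _CATEGORICAL_MARGINS.items()
    }
    if group is Group.HIGH_RISK:
        for name in _TUMOR_FIELDS:
            fields[name] = None
    return Patient(
        patient_id=patient_id,
        group=group,
        age_at_diagnosis=age,
        bmi=_sample_bmi(rng),
        **fields,
    )


def _pathogenic_record(
    rng: np.random.Generator,
    patient_id: str,
    gene: str,
    gene_index: int,
    used: set[tuple[str, int]],
    is_founder: bool,
) -> tuple[VariantRecord, AnnotationBundle]:
    chrom, base = _gene_locus(gene_index)
    afs = _rare_afs(rng)
    cds_pos, cds_len = _mid_cds(rng)
    homozygous = rng.random() < 0.03

    if is_founder:
        pos, ref, alt = _founder_allele(gene_index)
        used.add((chrom, pos))
        consequence = Consequence.FRAMESHIFT
        hgvs_c = "c.del_exon9_12"
        clinvar = ClinvarStatus.PATHOGENIC
    elif rng.random() < _RECURRENT_USE_PROB:
        pos, ref, alt, consequence, hgvs_c = _recurrent_allele(gene_index)
        used.add((chrom, pos))
        clinvar = ClinvarStatus.PATHOGENIC
    else:
        consequence = _sample_pathogenic_kind(rng)
        pos = _unique_position(rng, base, used, chrom)
        if consequence in (Consequence.FRAMESHIFT,):
            ref, alt = "AC", "A"
        else:
            ref, alt = _snv_alleles(rng)
        hgvs_c = f"c.{cds_pos}{ref}>{alt}"
        if consequence is Consequence.MISSENSE:
            clinvar = ClinvarStatus.PATHOGENIC  # rule requires the assertion
        else:
            r = rng.random()
            clinvar = (
                ClinvarStatus.PATHOGENIC
                if r < 0.45
                else ClinvarStatus.ABSENT
                if r < 0.9
                else ClinvarStatus.UNCERTAIN
            )
    depth, alt_depth = _depth_pair(rng, homozygous)
    record = VariantRecord(
        patient_id=patient_id,
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        gene=gene,
        consequence=consequence,
        zygosity=Zygosity.HOMOZYGOUS if homozygous else Zygosity.HETEROZYGOUS,
        depth=depth,
        alt_depth=alt_depth,
        hgvs_c=hgvs_c,
    )
    bundle = AnnotationBundle(
        clinvar_status=clinvar,
        sift=SiftCall.MISSING,
        polyphen=PolyphenCall.MISSING,
        cds_pos=cds_pos,
        cds_len=cds_len,
        homopolymer_run=int(rng.integers(1, 6)),
        **afs,
    )
    return record, bundle


def _protein_substitution(rng: np.random.Generator, cds_pos: int) -> str:
    ref = _AA[rng.integers(len(_AA))]
    alt = _AA[rng.integers(len(_AA))]
    while alt == ref:
        alt = _AA[rng.integers(len(_AA))]
    return f"p.{ref}{max(1, cds_pos // 3)}{alt}"


def _vus_record(
    rng, patient_id: str, gene: str, gene_index: int, used
) -> tuple[VariantRecord, AnnotationBundle]:
    chrom, base = _gene_locus(gene_index)
    pos = _unique_position(rng, base, used, chrom)
    ref, alt = _snv_alleles(rng)
    cds_pos, cds_len = _mid_cds(rng)
    depth, alt_depth = _depth_pair(rng)
    # at least one deleterious in-silico call
    sift = SiftCall.DELETERIOUS if rng.random() < 0.7 else SiftCall.TOLERATED
    polyphen = (
        PolyphenCall.PROBABLY_DAMAGING
        if (sift is not SiftCall.DELETERIOUS or rng.random() < 0.5)
        else PolyphenCall.MISSING
    )
    record = VariantRecord(
        patient_id=patient_id,
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        gene=gene,
        consequence=Consequence.MISSENSE,
        zygosity=Zygosity.HETEROZYGOUS,
        depth=depth,
        alt_depth=alt_depth,
        hgvs_c=f"c.{cds_pos}{ref}>{alt}",
        hgvs_p=_protein_substitution(rng, cds_pos),
    )
    bundle = AnnotationBundle(
        clinvar_status=(
            ClinvarStatus.UNCERTAIN if rng.random() < 0.3 else ClinvarStatus.ABSENT
        ),
        sift=sift,
        polyphen=polyphen,
        cds_pos=cds_pos,
        cds_len=cds_len,
        homopolymer_run=int(rng.integers(1, 6)),
        **_rare_afs(rng),
    )
    return record, bundle


def _common_record(
    rng, patient_id: str, gene: str, gene_index: int, used
) -> tuple[VariantRecord, AnnotationBundle]:
    chrom, base = _gene_locus(gene_index)
    pos = _unique_position(rng, base, used, chrom)
    ref, alt = _snv_alleles(rng)
    cds_pos, cds_len = _mid_cds(rng)
    depth, alt_depth = _depth_pair(rng, homozygous=rng.random() < 0.2)
    af = float(rng.uniform(0.002, 0.4))
    record = VariantRecord(
        patient_id=patient_id,
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        gene=gene,
        consequence=Consequence.MISSENSE,
        zygosity=Zygosity.HETEROZYGOUS,
        depth=depth,
        alt_depth=alt_depth,
        hgvs_c=f"c.{cds_pos}{ref}>{alt}",
    )
    bundle = AnnotationBundle(
        clinvar_status=(
            ClinvarStatus.BENIGN if rng.random() < 0.5 else ClinvarStatus.ABSENT
        ),
        af_exac=af,
        af_1000g=float(min(0.5, af * rng.uniform(0.5, 2.0))),
        af_esp=None if rng.random() < 0.5 else float(min(0.5, af * rng.uniform(0.5, 2.0))),
        sift=SiftCall.TOLERATED,
        polyphen=PolyphenCall.BENIGN,
        cds_pos=cds_pos,
        cds_len=cds_len,
        homopolymer_run=int(rng.integers(1, 6)),
    )
    return record, bundle


def _artifact_record(
    rng, patient_id: str, gene: str, gene_index: int, used, kind: str
) -> tuple[VariantRecord, AnnotationBundle]:
    """One artifact violating exactly the named QC threshold."""
    chrom, base = _gene_locus(gene_index)
    pos = _unique_position(rng, base, used, chrom)
    ref, alt = _snv_alleles(rng)
    cds_pos, cds_len = _mid_cds(rng)
    consequence = Consequence.MISSENSE
    run = int(rng.integers(1, 6))
    if kind == "low_depth":
        depth = int(rng.integers(0, 5))
        alt_depth = depth  # VAF 1.0 (or undefined at depth 0): only depth fires
    elif kind == "low_vaf":
        depth, _ = _depth_pair(rng)
        depth = max(depth, 20)
        alt_depth = max(0, int(np.floor(rng.uniform(0.02, 0.19) * depth)))
        if alt_depth / depth >= 0.2:  # guard against rounding up
            alt_depth = int(np.floor(0.19 * depth))
    elif kind == "homopolymer":
        depth, alt_depth = _depth_pair(rng)
        run = int(rng.integers(9, 15))
        ref, alt = "AC", "A"  # indel in a homopolymer tract
        consequence = Consequence.FRAMESHIFT
    elif kind == "synonymous":
        depth, alt_depth = _depth_pair(rng)
        consequence = Consequence.SYNONYMOUS
    else:
        raise ValueError(f"unknown artifact kind {kind!r}")
    record = VariantRecord(
        patient_id=patient_id,
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        gene=gene,
        consequence=consequence,
        zygosity=Zygosity.HETEROZYGOUS,
        depth=depth,
        alt_depth=alt_depth,
    )
    bundle = AnnotationBundle(
        clinvar_status=ClinvarStatus.ABSENT,
        sift=SiftCall.MISSING,
        polyphen=PolyphenCall.MISSING,
        cds_pos=cds_pos,
        cds_len=cds_len,
        homopolymer_run=run,
        **_rare_afs(rng),
    )
    return record, bundle


def generate_cohort(
    config: SimulationConfig = SimulationConfig(),
) -> tuple[list[Patient], list[tuple[VariantRecord, AnnotationBundle]], TruthTable]:
    """Generate (patients, variant table, truth table).

    Reproducible given ``config.seed``; per-patient substreams keyed by
    (seed, group, index). Raises before any sampling on an invalid
    config.
    """
    config.validate()
    panel = config.resolved_panel()
    gene_index = {g.symbol: i for i, g in enumerate(panel)}
    artifact_rates = config.resolved_artifact_rates()

    patients: list[Patient] = []
    table: list[tuple[VariantRecord, AnnotationBundle]] = []
    truth = TruthTable()

    groups = [(Group.CANCER, config.n_cancer, "CA"), (Group.HIGH_RISK, config.n_high_risk, "HR")]
    for group_code, (group, n, prefix) in enumerate(groups):
        prevalence = config.resolved_prevalence(group)
        for i in range(n):
            rng = np.random.default_rng([config.seed, group_code, i])
            patient_id = f"{prefix}{i + 1:04d}"
            carried = [g for g, p in prevalence.items() if rng.random() < p]
            is_founder = "BRCA1" in carried and rng.random() < config.founder_fraction
            patient = _make_patient(
                rng, patient_id, group, bool(carried), config.carrier_age_shift
            )
            patients.append(patient)
            truth.patient_carrier[patient_id] = bool(carried)
            if is_founder:
                truth.founder_carriers.add(patient_id)

            used: set[tuple[str, int]] = set()
            for gene in carried:
                rec, bundle = _pathogenic_record(
                    rng, patient_id, gene, gene_index[gene], used,
                    is_founder and gene == "BRCA1",
                )
                table.append((rec, bundle))
                truth.variant_classes[rec.key] = "pathogenic"
            for _ in range(int(rng.poisson(config.vus_rate))):
                gene = panel[int(rng.integers(len(panel)))].symbol
                rec, bundle = _vus_record(rng, patient_id, gene, gene_index[gene], used)
                table.append((rec, bundle))
                truth.variant_classes[rec.key] = "vus"
            for _ in range(int(rng.poisson(config.common_rate))):
                gene = panel[int(rng.integers(len(panel)))].symbol
                rec, bundle = _common_record(rng, patient_id, gene, gene_index[gene], used)
                table.append((rec, bundle))
                truth.variant_classes[rec.key] = "common"
            for kind in sorted(artifact_rates):
                for _ in range(int(rng.poisson(artifact_rates[kind]))):
                    gene = panel[int(rng.integers(len(panel)))].symbol
                    rec, bundle = _artifact_record(
                        rng, patient_id, gene, gene_index[gene], used, kind
                    )
                    table.append((rec, bundle))
                    truth.variant_classes[rec.key] = "artifact"
    return patients, table, truth


# ---------------------------------------------------------------------------
# Founder-assay locus generation
# ---------------------------------------------------------------------------


def generate_founder_locus(
    seed: int,
    n_individuals: int = 20,
    carrier_probability: float = 0.3,
) -> tuple[Locus, PrimerAssay, list[bool]]:
    """Build a synthetic assay locus mirroring the three-primer design.

    P1 binds upstream of the deletion, P2 inside it, P3 downstream such
    that P1-P3 only amplifies once the deletion collapses the distance
    below ``max_amplicon``. Also draws carrier flags for
    ``n_individuals`` (carriers hold one wild-type and one deleted
    allele). The construction is verified by in-silico PCR before being
    returned; sequences differ by seed but guarantees are structural.
    """
    rng = np.random.default_rng([seed, 97])
    primer_len = 20
    length = 3200
    p1_at, del_start, p2_at, del_end, p3_at = 100, 200, 1000, 2600, 2700
    max_amplicon = 2000
    for _ in range(50):
        seq = "".join(_BASES[b] for b in rng.integers(0, 4, size=length))
        p1 = seq[p1_at : p1_at + primer_len]
        # reverse primers: the template carries their reverse complement
        from Bio.Seq import reverse_complement

        p2 = reverse_complement(seq[p2_at : p2_at + primer_len])
        p3 = reverse_complement(seq[p3_at : p3_at + primer_len])
        try:
            assay = PrimerAssay(p1=p1, p2=p2, p3=p3, max_amplicon=max_amplicon)
        except ValueError:
            continue
        locus = Locus(sequence=seq, deletion_start=del_start, deletion_end=del_end)
        deleted = apply_deletion(locus)
        wt_ok = (
            len(simulate_pcr(seq, p1, p2, max_amplicon)) == 1
            and simulate_pcr(seq, p1, p3, max_amplicon) == []
        )
        del_ok = (
            len(simulate_pcr(deleted, p1, p3, max_amplicon)) == 1
            and simulate_pcr(deleted, p1, p2, max_amplicon) == []
        )
        if wt_ok and del_ok:
            flags = [bool(rng.random() < carrier_probability) for _ in range(n_individuals)]
            return locus, assay, flags
    raise RuntimeError("could not construct a valid founder locus")


# ---------------------------------------------------------------------------
# Deterministic in-study fixture
# ---------------------------------------------------------------------------

# Per-gene carrier counts of the study. The per-gene lists printed for
# the two groups over-count the stated totals (46 + 6 carriers) when the
# "both groups" genes are apportioned, so the group totals take
# precedence: the cancer-group counts below sum to exactly 46.
_FIXTURE_CANCER_GENES: tuple[tuple[str, int], ...] = (
    ("BRCA1", 15),
    ("BRCA2", 6),
    ("PTEN", 1),
    ("ATM", 2),
    ("CHEK2", 1),
    ("NBN", 1),
    ("FANCI", 2),
    ("ERCC3", 2),
    ("ATR", 1),
    ("FANCB", 1),
    ("FANCC", 1),
    ("FANCF", 1),
    ("FANCL", 1),
    ("FANCM", 1),
    ("MLH1", 1),
    ("RAD51C", 1),
    ("POLH", 1),
    ("RECQL4", 1),
    ("SDHB", 1),
    ("WRN", 1),
    ("MSR1", 2),
    ("LIG4", 1),
    ("PDE11A", 1),
)
_FIXTURE_HIGH_RISK_GENES: tuple[tuple[str, int], ...] = (
    ("BRCA1", 2),
    ("BRCA2", 1),
    ("FANCF", 1),
    ("PDE11A", 1),
    ("POLH", 1),
)


def _fixture_metadata(index: int) -> dict:
    """Deterministic cancer-group covariates whose marginal counts
    reproduce the study's clinical table exactly (each field assigned
    independently by patient index)."""

    def pick(spans: Sequence[tuple[object, int]]):
        i = index
        for value, count in spans:
            if i < count:
                return value
            i -= count
        return None

    return {
        "age_at_diagnosis": pick([(35.0, 125), (45.0, 135), (55.0, 24), (None, 16)]),
        "bmi": pick([(17.0, 1), (22.0, 107), (27.0, 118), (33.0, 66), (42.0, 3), (None, 5)]),
        "alcohol": pick([("no", 278), ("yes", 16), (None, 6)]),
        "tobacco": pick([("no", 84), ("yes", 74), (None, 142)]),
        "pregnancy": pick([("yes", 256), ("no", 43), (None, 1)]),
        "oral_contraceptive_use": pick([("yes", 115), ("no", 179), (None, 6)]),
        "family_history": pick([("yes", 214), ("no", 80), (None, 6)]),
        "histology": pick([("DCIS", 43), ("LCIS", 18), ("IDC", 189), ("ILC", 16), ("MC", 3), (None, 31)]),
        "stage": pick([("I", 51), ("II", 115), ("III", 86), ("IV", 10), (None, 38)]),
        "er_status": pick([("negative", 38), ("positive", 20), (None, 242)]),
        "pr_status": pick([("negative", 135), ("positive", 22), (None, 143)]),
        "her2_status": pick([("negative", 7), ("positive", 45), (None, 248)]),
    }


def fixture_from_paper_counts() -> tuple[list[Patient], dict[str, list[str]]]:
    """Deterministic 300 + 27 patient fixture.

    Cancer-group covariate margins reproduce the study's clinical table;
    per-gene carrier assignments reproduce the printed per-gene counts
    under the group carrier totals (46 cancer, 6 high-risk). Returns
    (patients, patient_id -> list of carried genes).
    """
    patients: list[Patient] = []
    assignments: dict[str, list[str]] = {}

    cancer_genes: list[str] = []
    for gene, count in _FIXTURE_CANCER_GENES:
        cancer_genes += [gene] * count
    for i in range(300):
        pid = f"CA{i + 1:04d}"
        patients.append(Patient(patient_id=pid, group=Group.CANCER, **_fixture_metadata(i)))
        assignments[pid] = [cancer_genes[i]] if i < len(cancer_genes) else []

    hr_genes: list[str] = []
    for gene, count in _FIXTURE_HIGH_RISK_GENES:
        hr_genes += [gene] * count
    for i in range(27):
        pid = f"HR{i + 1:04d}"
        patients.append(
            Patient(patient_id=pid, group=Group.HIGH_RISK, age_at_diagnosis=38.0,
                    family_history="yes")
        )
        assignments[pid] = [hr_genes[i]] if i < len(hr_genes) else []
    return patients, assignments


# Recurrent alleles of the fixture: five BRCA1 p.G228fs carriers and five
# BRCA1 founder-deletion carriers (each 5 of the 17 BRCA1 carriers), and
# one recurrent BRCA2 stop gain in two patients.
_G228FS = ("c.682delG", "p.G228fs")
_R2494X = ("c.7480C>T", "p.R2494X")


def fixture_classified_variants(
    patients: Sequence[Patient],
    assignments: dict[str, list[str]],
    panel: Optional[Sequence[PanelGene]] = None,
) -> list[ClassifiedVariant]:
    """Build and classify one deterministic pathogenic variant per
    fixture gene assignment, with the study's recurrent alleles planted
    (shared genomic keys for the recurrent BRCA1/2 mutations)."""
    panel = list(panel) if panel is not None else default_panel()
    gene_index = {g.symbol: i for i, g in enumerate(panel)}
    classified: list[ClassifiedVariant] = []
    brca1_seen = 0
    brca2_seen = 0
    for patient in patients:
        for gene in assignments.get(patient.patient_id, []):
            gi = gene_index[gene]
            chrom, base = _gene_locus(gi)
            consequence = Consequence.FRAMESHIFT
            ref, alt = "CA", "C"
            hgvs_c = hgvs_p = None
            if gene == "BRCA1":
                if brca1_seen < 5:  # shared p.G228fs allele
                    pos = base + 682
                    hgvs_c, hgvs_p = _G228FS
                elif brca1_seen < 10:  # shared founder deletion allele
                    pos, ref, alt = _founder_allele(gi)
                    hgvs_c = "c.del_exon9_12"
                else:
                    pos = base + 10_000 + brca1_seen
                brca1_seen += 1
            elif gene == "BRCA2":
                if brca2_seen < 2:  # shared stop gain
                    pos = base + 7480
                    ref, alt = "C", "T"
                    consequence = Consequence.STOP_GAIN
                    hgvs_c, hgvs_p = _R2494X
                else:
                    pos = base + 10_000 + brca2_seen
                brca2_seen += 1
            else:
                # unique allele per carrier within the gene
                pos = base + 10_000 + sum(
                    1 for cv in classified if cv.variant.gene == gene
                )
            record = VariantRecord(
                patient_id=patient.patient_id,
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                gene=gene,
                consequence=consequence,
                zygosity=Zygosity.HETEROZYGOUS,
                depth=70,
                alt_depth=35,
                hgvs_c=hgvs_c,
                hgvs_p=hgvs_p,
            )
            bundle = AnnotationBundle(
                clinvar_status=ClinvarStatus.PATHOGENIC,
                af_exac=1e-5,
                cds_pos=500,
                cds_len=3000,
                homopolymer_run=1,
            )
            classified.append(classify_variant(record, bundle))
    return classified
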