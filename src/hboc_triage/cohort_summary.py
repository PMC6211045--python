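"""Cohort-level summarization and univariate association tests.

Mutational (carrier) status of a patient is the presence of at least one
pathogenic or likely pathogenic variant in any panel gene; VUS never
confer carrier status and patients with only VUS are counted separately.
The summary reports group and pooled carrier fractions, per-gene carrier
counts, the split of carriers between BRCA1/2 and other genes, a
recurrence table over genomic alleles, and clinical/epidemiological
breakdowns. Association of carrier status with a single covariate uses
an unadjusted maximum-likelihood logistic regression with Wald tests
(significance at p < 0.05).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

import numpy as np

from hboc_triage.classifier import ClassifiedVariant, Label
from hboc_triage.variant_model import Group, PanelGene, Patient

__all__ = [
    "CohortSummary",
    "GeneCount",
    "RecurrenceEntry",
    "AssociationResult",
    "carrier_status",
    "summarize_cohort",
    "table2_breakdown",
    "univariate_association",
    "percent",
]

#: Genes whose carriers form the "BRCA" share of the cohort.
BRCA_GENES = frozenset({"BRCA1", "BRCA2"})

_CARRIER_LABELS = frozenset({Label.PATHOGENIC, Label.LIKELY_PATHOGENIC})


def percent(count: int, denominator: int, decimals: int = 1) -> float:
    """count / denominator as a percentage, rounded half away from zero
    to ``decimals`` places. Zero denominator yields 0.0."""
    count, denominator = int(count), int(denominator)
    if denominator == 0:
        return 0.0
    raw = Decimal(count) / Decimal(denominator) * Decimal(100)
    quantum = Decimal(1).scaleb(-decimals)
    return float(raw.quantize(quantum, rounding=ROUND_HALF_UP))


def carrier_status(patient_classified_variants: Iterable[ClassifiedVariant]) -> bool:
    """True iff the patient has >= 1 pathogenic or likely pathogenic
    variant. VUS (and excluded records) never confer carrier status."""
    return any(cv.label in _CARRIER_LABELS for cv in patient_classified_variants)


@dataclass(frozen=True)
class GeneCount:
    gene: str
    cancer: int
    high_risk: int

    @property
    def total(self) -> int:
        return self.cancer + self.high_risk


@dataclass(frozen=True)
class RecurrenceEntry:
    """Distinct-carrier count for one genomic allele."""

    key: str  # chrom:pos:ref:alt
    gene: str
    display: str  # hgvs_c when available, else the genomic key
    n_patients: int

    @property
    def recurrent(self) -> bool:
        return self.n_patients >= 2


@dataclass
class CohortSummary:
    """Cohort-level quantities computed by :func:`summarize_cohort`."""

    n_patients: dict[Group, int]
    carriers: dict[Group, int]
    vus_only_patients: dict[Group, int]
    negative_patients: dict[Group, int]
    gene_counts: list[GeneCount]
    brca_carriers: int
    non_brca_carriers: int
    recurrence: list[RecurrenceEntry]

    # -- derived quantities -------------------------------------------------
    @property
    def n_total(self) -> int:
        return sum(self.n_patients.values())

    @property
    def carriers_total(self) -> int:
        return sum(self.carriers.values())

    def carrier_pct(self, group: Optional[Group] = None, decimals: int = 1) -> float:
        if group is None:
            return percent(self.carriers_total, self.n_total, decimals)
        return percent(self.carriers[group], self.n_patients[group], decimals)

    def brca_carrier_pct(self, decimals: int = 1) -> float:
        """BRCA1/2 carriers as a percentage of the full cohort."""
        return percent(self.brca_carriers, self.n_total, decimals)

    def brca_share_pct(self, decimals: int = 1) -> float:
        """BRCA1/2 carriers as a percentage of all carriers."""
        return percent(self.brca_carriers, self.carriers_total, decimals)

    def non_brca_share_pct(self, decimals: int = 1) -> float:
        return percent(self.non_brca_carriers, self.carriers_total, decimals)

    def recurrent_alleles(self) -> list[RecurrenceEntry]:
        return [r for r in self.recurrence if r.recurrent]

    def to_text(self) -> str:
        lines = ["Cohort summary", "=============="]
        for group in Group:
            n = self.n_patients.get(group, 0)
            c = self.carriers.get(group, 0)
            v = self.vus_only_patients.get(group, 0)
            neg = self.negative_patients.get(group, 0)
            lines.append(
                f"{group.value}: n={n}, carriers={c} ({percent(c, n)}%), "
                f"VUS-only={v} ({percent(v, n)}%), negative={neg} ({percent(neg, n)}%)"
            )
        lines.append(
            f"pooled: n={self.n_total}, carriers={self.carriers_total} "
            f"({self.carrier_pct()}%)"
        )
        lines.append(
            f"BRCA1/2 carriers: {self.brca_carriers} "
            f"({self.brca_carrier_pct()}% of cohort, {self.brca_share_pct()}% of carriers)"
        )
        lines.append(
            f"non-BRCA carriers: {self.non_brca_carriers} "
            f"({self.non_brca_share_pct()}% of carriers)"
        )
        lines.append("")
        lines.append("Per-gene carrier counts (cancer / high-risk):")
        for gc in self.gene_counts:
            lines.append(f"  {gc.gene}: {gc.cancer} / {gc.high_risk}")
        recurrent = self.recurrent_alleles()
        if recurrent:
            lines.append("")
            lines.append("Recurrent alleles (>= 2 distinct carriers):")
            for r in recurrent:
                lines.append(f"  {r.gene} {r.display}: {r.n_patients} patients")
        return "\n".join(lines) + "\n"


def summarize_cohort(
    patients: Sequence[Patient],
    classified_variants: Sequence[ClassifiedVariant],
    panel: Optional[Sequence[PanelGene]] = None,
) -> CohortSummary:
    """Compute the cohort summary from classified variants.

    Per-gene counts are distinct patients per gene; the recurrence table
    counts distinct patients per genomic allele (chrom:pos:ref:alt, with
    hgvs_c as display alias). Carriers are partitioned once into BRCA1/2
    vs other genes, with priority to the BRCA genes for patients
    carrying both. Raises on a variant whose patient_id is not in
    ``patients``.
    """
    by_id = {p.patient_id: p for p in patients}
    if len(by_id) != len(patients):
        raise ValueError("duplicate patient_id in patients")
    panel_genes = {g.symbol for g in panel} if panel is not None else None

    per_patient: dict[str, list[ClassifiedVariant]] = {pid: [] for pid in by_id}
    for cv in classified_variants:
        pid = cv.variant.patient_id
        if pid not in by_id:
            raise ValueError(
                f"variant references unknown patient_id {pid!r} "
                "(referential-integrity error)"
            )
        if panel_genes is not None and cv.variant.gene not in panel_genes:
            raise ValueError(
                f"variant gene {cv.variant.gene!r} is not in the panel"
            )
        per_patient[pid].append(cv)

    n_patients = {g: 0 for g in Group}
    carriers = {g: 0 for g in Group}
    vus_only = {g: 0 for g in Group}
    negative = {g: 0 for g in Group}
    gene_to_patients: dict[str, dict[Group, set[str]]] = {}
    allele_carriers: dict[tuple[str, int, str, str], dict] = {}
    brca_carriers = 0
    non_brca_carriers = 0

    for patient in patients:
        group = patient.group
        n_patients[group] += 1
        cvs = per_patient[patient.patient_id]
        carrier_variants = [cv for cv in cvs if cv.label in _CARRIER_LABELS]
        if carrier_variants:
            carriers[group] += 1
            genes = {cv.variant.gene for cv in carrier_variants}
            if genes & BRCA_GENES:
                brca_carriers += 1
            else:
                non_brca_carriers += 1
            for cv in carrier_variants:
                rec = cv.variant
                gene_to_patients.setdefault(rec.gene, {g: set() for g in Group})[
                    group
                ].add(rec.patient_id)
                akey = (rec.chrom, rec.pos, rec.ref, rec.alt)
                entry = allele_carriers.setdefault(
                    akey, {"gene": rec.gene, "display": None, "patients": set()}
                )
                entry["patients"].add(rec.patient_id)
                if rec.hgvs_c and entry["display"] is None:
                    entry["display"] = rec.hgvs_c
        elif any(cv.label is Label.VUS for cv in cvs):
            vus_only[group] += 1
        else:
            negative[group] += 1

    gene_counts = [
        GeneCount(
            gene=gene,
            cancer=len(groups[Group.CANCER]),
            high_risk=len(groups[Group.HIGH_RISK]),
        )
        for gene, groups in sorted(gene_to_patients.items())
    ]
    gene_counts.sort(key=lambda gc: (-gc.total, gc.gene))

    recurrence = [
        RecurrenceEntry(
            key=f"{chrom}:{pos}:{ref}:{alt}",
            gene=entry["gene"],
            display=entry["display"] or f"{chrom}:{pos}:{ref}:{alt}",
            n_patients=len(entry["patients"]),
        )
        for (chrom, pos, ref, alt), entry in sorted(allele_carriers.items())
    ]
    recurrence.sort(key=lambda r: (-r.n_patients, r.gene, r.key))

    return CohortSummary(
        n_patients=n_patients,
        carriers=carriers,
        vus_only_patients=vus_only,
        negative_patients=negative,
        gene_counts=gene_counts,
        brca_carriers=brca_carriers,
        non_brca_carriers=non_brca_carriers,
        recurrence=recurrence,
    )


# ---------------------------------------------------------------------------
# Clinical/epidemiological breakdown
# ---------------------------------------------------------------------------

_AGE_BINS = (
    ("<40 years", lambda a: a <= 40),
    ("41-50 years", lambda a: 40 < a <= 50),
    (">50 years", lambda a: a > 50),
)
_BMI_BINS = (
    ("underweight", lambda b: b < 18.5),
    ("normal", lambda b: 18.5 <= b < 25.0),
    ("overweight", lambda b: 25.0 <= b < 30.0),
    ("obese", lambda b: 30.0 <= b <= 40.0),
    ("extreme_obese", lambda b: b > 40.0),
)

_CATEGORICAL_FIELDS = (
    "alcohol",
    "tobacco",
    "pregnancy",
    "oral_contraceptive_use",
    "family_history",
    "histology",
    "stage",
    "er_status",
    "pr_status",
    "her2_status",
)


def table2_breakdown(
    patients: Sequence[Patient],
) -> dict[str, list[tuple[str, int, float]]]:
    """Categorical breakdown of patient characteristics.

    Returns characteristic -> ordered (category, count, percent) rows;
    age and BMI are binned; missing is always its own category; the
    percentage denominator is the full patient list.
    """
    n = len(patients)
    out: dict[str, list[tuple[str, int, float]]] = {}

    def bin_numeric(name: str, attr: str, bins) -> None:
        counts = {label: 0 for label, _ in bins}
        counts["missing"] = 0
        for p in patients:
            value = getattr(p, attr)
            if value is None:
                counts["missing"] += 1
                continue
            for label, pred in bins:
                if pred(value):
                    counts[label] += 1
                    break
        out[name] = [(c, k, percent(k, n)) for c, k in counts.items()]

    bin_numeric("age", "age_at_diagnosis", _AGE_BINS)
    bin_numeric("bmi", "bmi", _BMI_BINS)

    from hboc_triage.variant_model import PATIENT_VOCABULARY

    for field_name in _CATEGORICAL_FIELDS:
        vocab = sorted(PATIENT_VOCABULARY[field_name])
        counts = {category: 0 for category in vocab}
        counts["missing"] = 0
        for p in patients:
            value = getattr(p, field_name)
            counts["missing" if value is None else value] += 1
        out[field_name] = [(c, k, percent(k, n)) for c, k in counts.items()]
    return out


# ---------------------------------------------------------------------------
# Univariate association
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AssociationResult:
    """Unadjusted logistic-regression association of carrier status with
    one covariate. For a categorical covariate, ``odds_ratio`` / Wald
    ``p_value`` refer to the largest-effect non-reference level and
    ``per_level`` carries every level."""

    odds_ratio: float
    p_value: float
    n_used: int
    coef: float
    se: float
    separated: bool = False
    covariate_type: str = "continuous"
    per_level: Optional[dict[str, tuple[float, float]]] = None

    @property
    def significant(self) -> bool:
        return (not math.isnan(self.p_value)) and self.p_value < 0.05


class DegenerateFitError(ValueError):
    """The covariate carries no information (constant, or no usable rows)."""


def _fit_logit(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    """ML logistic fit; returns (params, bse, separated)."""
    import statsmodels.api as sm

    separated = False
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = sm.Logit(y, X).fit(disp=0, maxiter=200)
        params, bse = np.asarray(result.params), np.asarray(result.bse)
    except Exception:
        return np.full(X.shape[1], np.nan), np.full(X.shape[1], np.nan), True
    converged = bool(result.mle_retvals.get("converged", True))
    if (
        not converged
        or np.any(~np.isfinite(params))
        or np.any(~np.isfinite(bse))
        or np.any(np.abs(params[1:]) > 25)
        or np.any(bse > 1e3)
    ):
        separated = True
    return params, bse, separated


def univariate_association(
    covariate_values: Sequence,
    carrier_flags: Sequence[bool],
) -> AssociationResult:
    """Fit carrier status on a single covariate by unadjusted logistic
    regression.

    Numeric covariates are continuous (rows with missing values are
    dropped; ``n_used`` reports the rows kept). String covariates are
    categorical with missing as its own level and the most frequent
    level as reference. Complete separation is flagged (infinite odds
    ratio, NaN p), never raised. A constant covariate raises
    :class:`DegenerateFitError`.
    """
    if len(covariate_values) != len(carrier_flags):
        raise ValueError("covariate and carrier flags differ in length")
    y_all = np.asarray([bool(f) for f in carrier_flags], dtype=float)

    is_numeric = all(
        v is None or isinstance(v, (int, float, np.integer, np.floating))
        for v in covariate_values
    )
    if is_numeric:
        x = np.array(
            [np.nan if v is None else float(v) for v in covariate_values], dtype=float
        )
        keep = ~np.isnan(x)
        x, y = x[keep], y_all[keep]
        n_used = int(keep.sum())
        if n_used == 0 or np.ptp(x) == 0:
            raise DegenerateFitError("covariate is constant or has no usable rows")
        if len(np.unique(y)) < 2:
            raise DegenerateFitError("carrier flags are constant in the usable rows")
        X = np.column_stack([np.ones_like(x), x])
        params, bse, separated = _fit_logit(y, X)
        coef, se = float(params[1]), float(bse[1])
        if separated:
            return AssociationResult(
                odds_ratio=math.inf,
                p_value=math.nan,
                n_used=n_used,
                coef=coef,
                se=se,
                separated=True,
            )
        from scipy import stats

        z = coef / se
        p = 2 * stats.norm.sf(abs(z))
        return AssociationResult(
            odds_ratio=math.exp(coef),
            p_value=float(p),
            n_used=n_used,
            coef=coef,
            se=se,
        )

    # Categorical: missing becomes its own level.
    levels_raw = ["missing" if v is None else str(v) for v in covariate_values]
    y = y_all
    n_used = len(levels_raw)
    unique, counts = np.unique(levels_raw, return_counts=True)
    if len(unique) < 2:
        raise DegenerateFitError("covariate is constant")
    reference = unique[np.argmax(counts)]
    others = [u for u in unique if u != reference]
    X = np.column_stack(
        [np.ones(n_used)]
        + [np.array([1.0 if lv == u else 0.0 for lv in levels_raw]) for u in others]
    )
    params, bse, separated = _fit_logit(y, X)
    if separated:
        return AssociationResult(
            odds_ratio=math.inf,
            p_value=math.nan,
            n_used=n_used,
            coef=math.nan,
            se=math.nan,
            separated=True,
            covariate_type="categorical",
        )
    from scipy import stats

    per_level: dict[str, tuple[float, float]] = {}
    best = None
    for i, level in enumerate(others, start=1):
        coef, se = float(params[i]), float(bse[i])
        p = float(2 * stats.norm.sf(abs(coef / se))) if se > 0 else math.nan
        per_level[level] = (math.exp(coef), p)
        if best is None or abs(coef) > abs(best[1]):
            best = (level, coef, se, p)
    _, coef, se, p = best
    return AssociationResult(
        odds_ratio=math.exp(coef),
        p_value=p,
        n_used=n_used,
        coef=coef,
        se=se,
        covariate_type="categorical",
        per_level=per_level,
    )
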