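"""Pre-classification quality-control filters.

Amplicon-based germline panels produce characteristic artifact classes:
under-covered sites, low mutant-allele-fraction calls, and indels in
homopolymeric tracts. Records failing any threshold are excluded before
classification, along with synonymous changes (which the triage never
reports). The default thresholds are the conventional ones for this
assay class: depth < 5.0x, mutant allele fraction < 20%, homopolymer
tract > 8 bp — all comparisons strict exactly as stated, so a record at
depth 5, VAF 0.20 or run 8 is retained.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional

from hboc_triage.variant_model import AnnotationBundle, Consequence, VariantRecord

__all__ = [
    "QcThresholds",
    "QcReason",
    "QcResult",
    "compute_vaf",
    "longest_homopolymer",
    "apply_qc",
]


@dataclass(frozen=True)
class QcThresholds:
    """Exclusion thresholds. A record is excluded iff it is synonymous
    (when ``exclude_synonymous``), or depth < ``min_depth``, or
    VAF < ``min_vaf``, or homopolymer run > ``max_homopolymer``."""

    min_depth: float = 5.0
    min_vaf: float = 0.20
    max_homopolymer: int = 8
    exclude_synonymous: bool = True

    def __post_init__(self) -> None:
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")
        if not (0.0 <= self.min_vaf <= 1.0):
            raise ValueError("min_vaf must lie in [0, 1]")
        if self.max_homopolymer < 1:
            raise ValueError("max_homopolymer must be >= 1")


class QcReason(enum.Enum):
    SYNONYMOUS = "synonymous"
    LOW_DEPTH = "low_depth"
    LOW_VAF = "low_vaf"
    HOMOPOLYMER = "homopolymer"


def compute_vaf(alt_depth: int, depth: int) -> Optional[float]:
    """Mutant allele fraction alt_depth / depth.

    Returns ``None`` (undefined) at depth 0 — such a record fails the
    depth filter anyway. Raises on the invariant violation
    alt_depth > depth.
    """
    if alt_depth < 0 or depth < 0:
        raise ValueError("read depths must be non-negative")
    if depth == 0:
        return None
    if alt_depth > depth:
        raise ValueError(f"alt_depth ({alt_depth}) exceeds depth ({depth})")
    return alt_depth / depth


def longest_homopolymer(context_sequence: str, variant_offset: int, window: int = 1) -> int:
    """Length of the longest single-base run overlapping the variant
    neighbourhood ``[variant_offset - window, variant_offset + window]``.

    ``context_sequence`` is uppercase A/C/G/T/N reference context; N is
    ambiguous and never extends a run (an all-N neighbourhood scores 0).
    """
    n = len(context_sequence)
    if not (0 <= variant_offset < n):
        raise ValueError(
            f"variant_offset {variant_offset} out of range for sequence of length {n}"
        )
    if window < 0:
        raise ValueError("window must be >= 0")
    lo = max(0, variant_offset - window)
    hi = min(n - 1, variant_offset + window)

    best = 0
    run_start = 0
    for i in range(1, n + 1):
        if i == n or context_sequence[i] != context_sequence[run_start]:
            # run is [run_start, i)
            if context_sequence[run_start] != "N" and run_start <= hi and i - 1 >= lo:
                best = max(best, i - run_start)
            run_start = i
    return best


@dataclass
class QcResult:
    """Partition of the input into retained and excluded records, with
    every failing reason recorded per excluded record."""

    retained: list[tuple[VariantRecord, AnnotationBundle]] = field(default_factory=list)
    excluded: list[tuple[VariantRecord, AnnotationBundle]] = field(default_factory=list)
    reasons: dict[tuple, frozenset[QcReason]] = field(default_factory=dict)

    def reasons_for(self, record: VariantRecord) -> frozenset[QcReason]:
        return self.reasons.get(record.key, frozenset())


def qc_reasons(
    record: VariantRecord,
    bundle: AnnotationBundle,
    thresholds: QcThresholds,
) -> frozenset[QcReason]:
    """All QC exclusion reasons firing for one record (empty = retained)."""
    fired: set[QcReason] = set()
    if thresholds.exclude_synonymous and record.consequence is Consequence.SYNONYMOUS:
        fired.add(QcReason.SYNONYMOUS)
    if record.depth < thresholds.min_depth:
        fired.add(QcReason.LOW_DEPTH)
    vaf = compute_vaf(record.alt_depth, record.depth)
    if vaf is not None and vaf < thresholds.min_vaf:
        fired.add(QcReason.LOW_VAF)
    if (
        bundle.homopolymer_run is not None
        and bundle.homopolymer_run > thresholds.max_homopolymer
    ):
        fired.add(QcReason.HOMOPOLYMER)
    return frozenset(fired)


def apply_qc(
    records: Iterable[tuple[VariantRecord, AnnotationBundle]],
    thresholds: QcThresholds = QcThresholds(),
) -> QcResult:
    """Partition records into retained / excluded under ``thresholds``.

    Count-conserving: every input record lands in exactly one partition;
    excluded records carry the full set of reasons that fired.
    """
    result = QcResult()
    for record, bundle in records:
        fired = qc_reasons(record, bundle, thresholds)
        if fired:
            result.excluded.append((record, bundle))
            result.reasons[record.key] = fired
        else:
            result.retained.append((record, bundle))
    return result
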