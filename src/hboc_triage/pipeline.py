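"""End-to-end pipeline driver: QC -> rarity/classification -> summary.

``run_pipeline`` composes the stage modules over the flat-file dialects
and writes the classification report, the cohort summary (human-readable
and delimited), and an audit log listing every excluded record with the
reasons that fired plus rule-fire counts. Partial-input failures
(missing files, referential-integrity errors) abort before any output
is written.
"""

from __future__ import annotations

import logging
from collections import Counter
from pathlib import Path

from hboc_triage.classifier import (
    ClassifiedVariant,
    Disposition,
    Label,
    classify_variant,
)
from hboc_triage.cohort_summary import CohortSummary, summarize_cohort
from hboc_triage.config import PipelineConfig
from hboc_triage.panel import default_panel, load_panel
from hboc_triage.qc_filters import apply_qc
from hboc_triage.variant_model import ConfigurationError

logger = logging.getLogger("hboc_triage")

__all__ = ["run_pipeline", "classify_table", "read_classification_report"]


def classify_table(records, qc_thresholds, clf_config) -> list[ClassifiedVariant]:
    """Apply QC then the cascade to (VariantRecord, AnnotationBundle)
    pairs; QC-failed records become ``excluded_qc`` with their reasons
    as the rule trace."""
    qc = apply_qc(records, qc_thresholds)
    classified: list[ClassifiedVariant] = []
    for record, bundle in qc.excluded:
        reasons = sorted(r.value for r in qc.reasons_for(record))
        classified.append(
            ClassifiedVariant(
                variant=record,
                annotations=bundle,
                disposition=Disposition.EXCLUDED_QC,
                label=Label.NONE,
                rule_trace=tuple(f"qc_{r}" for r in reasons),
            )
        )
    for record, bundle in qc.retained:
        classified.append(classify_variant(record, bundle, clf_config))
    return classified


def run_pipeline(config: PipelineConfig) -> tuple[list[ClassifiedVariant], CohortSummary]:
    """Run QC, classification and summarization per ``config``.

    Requires ``config.variants`` and ``config.patients``. Outputs are
    written to ``config.out_dir``: classification_report.tsv,
    summary.txt, summary_genes.tsv, audit.log. Raises
    :class:`ConfigurationError` (missing inputs) or ``ValueError``
    (referential integrity) before any output file is created.
    """
    from hboc_triage.variant_model import (
        read_patient_table,
        read_variant_table,
        write_classification_report,
    )

    if config.variants is None or config.patients is None:
        raise ConfigurationError("pipeline requires 'variants' and 'patients' paths")
    config.check_paths()

    records = read_variant_table(config.variants)
    patients = read_patient_table(config.patients)
    panel = load_panel(config.panel) if config.panel is not None else default_panel()

    classified = classify_table(records, config.qc, config.classifier)
    # Summarize first: referential-integrity failures abort before output.
    summary = summarize_cohort(patients, classified, panel)

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report_path = out_dir / "classification_report.tsv"
    write_classification_report(classified, patients, report_path)

    (out_dir / "summary.txt").write_text(summary.to_text(), encoding="utf-8")
    with (out_dir / "summary_genes.tsv").open("w", encoding="utf-8") as handle:
        handle.write("gene\tcancer_carriers\thigh_risk_carriers\ttotal\n")
        for gc in summary.gene_counts:
            handle.write(f"{gc.gene}\t{gc.cancer}\t{gc.high_risk}\t{gc.total}\n")

    rule_counts = Counter(step for cv in classified for step in cv.rule_trace)
    with (out_dir / "audit.log").open("w", encoding="utf-8") as handle:
        handle.write("# excluded records\n")
        for cv in classified:
            if cv.disposition is Disposition.RETAINED:
                continue
            rec = cv.variant
            handle.write(
                f"{rec.patient_id}\t{rec.chrom}:{rec.pos}:{rec.ref}:{rec.alt}\t"
                f"{cv.disposition.value}\t{';'.join(cv.rule_trace)}\n"
            )
        handle.write("# rule fire counts\n")
        for rule, count in sorted(rule_counts.items()):
            handle.write(f"{rule}\t{count}\n")
    logger.info(
        "pipeline: %d records, %d retained, carriers %d/%d (%.1f%%)",
        len(classified),
        sum(cv.disposition is Disposition.RETAINED for cv in classified),
        summary.carriers_total,
        summary.n_total,
        summary.carrier_pct(),
    )
    return classified, summary


def read_classification_report(path) -> list[ClassifiedVariant]:
    """Read a classification report back into :class:`ClassifiedVariant`
    objects (inverse of ``write_classification_report``)."""
    from hboc_triage.variant_model import TABLE_COLUMNS, _row_to_record

    path = Path(path)
    out: list[ClassifiedVariant] = []
    with path.open("r", encoding="utf-8", newline="") as handle:
        header = handle.readline().rstrip("\n").split("\t")
        required = set(TABLE_COLUMNS) | {"disposition", "label", "rule_trace"}
        missing = required - set(header)
        if missing:
            raise ValueError(f"{path}: missing report columns {sorted(missing)}")
        for line_no, line in enumerate(handle, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            row = dict(zip(header, line.split("\t")))
            record, bundle = _row_to_record(row, line_no)
            out.append(
                ClassifiedVariant(
                    variant=record,
                    annotations=bundle,
                    disposition=Disposition(row["disposition"]),
                    label=Label(row["label"]),
                    rule_trace=tuple(
                        t for t in row["rule_trace"].split(";") if t
                    ),
                )
            )
    return out
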