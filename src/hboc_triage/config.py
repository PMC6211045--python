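"""Pipeline configuration: flat key-value config file + CLI overrides.

The config file is YAML with flat keys mirroring the module defaults,
so parameter provenance is reproducible from logs:

.. code-block:: yaml

    min_depth: 5.0
    min_vaf: 0.20
    max_homopolymer: 8
    exclude_synonymous: true
    maf_threshold: 0.001
    three_prime_fraction: 0.95
    panel: panel_genes.tsv        # optional; default panel when absent
    site_table: phospho_sites.tsv # optional
    seed: 0
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from hboc_triage.classifier import ClassifierConfig
from hboc_triage.qc_filters import QcThresholds
from hboc_triage.variant_model import ConfigurationError

__all__ = ["PipelineConfig", "load_pipeline_config"]

_QC_KEYS = ("min_depth", "min_vaf", "max_homopolymer", "exclude_synonymous")
_CLF_KEYS = ("maf_threshold", "three_prime_fraction")
_PATH_KEYS = ("panel", "site_table", "variants", "patients", "out_dir")
_OTHER_KEYS = ("seed",)


@dataclass
class PipelineConfig:
    """Everything the end-to-end pipeline needs: thresholds, cascade
    parameters, input/output paths and the seed."""

    qc: QcThresholds = field(default_factory=QcThresholds)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    variants: Optional[Path] = None
    patients: Optional[Path] = None
    panel: Optional[Path] = None
    site_table: Optional[Path] = None
    out_dir: Path = Path("triage_out")
    seed: int = 0

    def check_paths(self) -> None:
        """Referenced input paths must exist before any stage runs."""
        for name in ("variants", "patients", "panel", "site_table"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise ConfigurationError(f"{name} file not found: {path}")


def load_pipeline_config(path=None, overrides: Optional[dict] = None) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file plus overrides
    (CLI flags win over config-file values; both win over defaults).
    Unknown keys are a configuration error."""
    values: dict = {}
    if path is not None:
        with Path(path).open("r", encoding="utf-8") as handle:
            loaded = yaml.safe_load(handle) or {}
        if not isinstance(loaded, dict):
            raise ConfigurationError(f"{path}: config must be a flat mapping")
        values.update(loaded)
    if overrides:
        values.update({k: v for k, v in overrides.items() if v is not None})

    known = set(_QC_KEYS) | set(_CLF_KEYS) | set(_PATH_KEYS) | set(_OTHER_KEYS)
    unknown = set(values) - known
    if unknown:
        raise ConfigurationError(
            f"unknown config keys {sorted(unknown)}; accepted: {sorted(known)}"
        )

    try:
        qc = QcThresholds(
            **{k: values[k] for k in _QC_KEYS if k in values}
        )
        classifier = ClassifierConfig(
            **{k: values[k] for k in _CLF_KEYS if k in values}
        )
    except ValueError as exc:
        raise ConfigurationError(str(exc)) from exc

    paths = {
        k: (Path(values[k]) if values.get(k) is not None else None)
        for k in _PATH_KEYS
        if k in values
    }
    out_dir = paths.pop("out_dir", None)
    config = PipelineConfig(
        qc=qc,
        classifier=classifier,
        seed=int(values.get("seed", 0)),
        **paths,
    )
    if out_dir is not None:
        config.out_dir = out_dir
    return config
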