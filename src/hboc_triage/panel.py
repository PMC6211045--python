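"""Panel definitions: per-gene risk tier, ACMG reportability, inheritance.

The shipped fixture ``data/panel_genes.tsv`` covers the 23 genes in
which the triage rules have documented outcomes (risk tier, inheritance
and ACMG secondary-finding reportability). :func:`default_panel`
extends it to the full 143-gene panel: first with well-known
hereditary-cancer genes screened but without findings (TP53, PALB2,
CDH1, STK11, ...), then with synthetic filler symbols — the identity of
the remaining commercial panel content is not public, and filler genes
only serve as VUS/polymorphism background in simulations.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from hboc_triage.variant_model import Inheritance, PanelGene, RiskCategory

__all__ = ["load_panel", "default_panel", "PANEL_SIZE"]

PANEL_SIZE = 143

# Screened hereditary-cancer genes beyond the 23 with findings; risk
# annotations deliberately conservative (unknown unless well known).
_EXTRA_KNOWN = [
    ("TP53", RiskCategory.HIGH, True, Inheritance.AD),
    ("CDH1", RiskCategory.HIGH, False, Inheritance.AD),
    ("PALB2", RiskCategory.HIGH, False, Inheritance.AD),
    ("STK11", RiskCategory.HIGH, True, Inheritance.AD),
    ("APC", RiskCategory.UNKNOWN, True, Inheritance.AD),
    ("AIP", RiskCategory.UNKNOWN, False, Inheritance.AD),
    ("MSH2", RiskCategory.UNKNOWN, True, Inheritance.AD),
    ("MSH6", RiskCategory.UNKNOWN, True, Inheritance.AD),
    ("PMS2", RiskCategory.UNKNOWN, True, Inheritance.AR),
    ("EPCAM", RiskCategory.UNKNOWN, False, Inheritance.AD),
    ("MUTYH", RiskCategory.UNKNOWN, True, Inheritance.AR),
    ("BRIP1", RiskCategory.MODERATE, False, Inheritance.AD_AR),
    ("BARD1", RiskCategory.MODERATE, False, Inheritance.AD),
    ("RAD51D", RiskCategory.MODERATE, False, Inheritance.AD),
    ("RAD50", RiskCategory.UNKNOWN, False, Inheritance.AD),
    ("MRE11A", RiskCategory.UNKNOWN, False, Inheritance.AD_AR),
    ("NF1", RiskCategory.UNKNOWN, True, Inheritance.AD),
    ("FANCA", RiskCategory.UNKNOWN, False, Inheritance.AR),
    ("FANCD2", RiskCategory.UNKNOWN, False, Inheritance.AR),
    ("FANCE", RiskCategory.UNKNOWN, False, Inheritance.AR),
    ("FANCG", RiskCategory.UNKNOWN, False, Inheritance.AR),
    ("XRCC2", RiskCategory.UNKNOWN, False, Inheritance.AR),
]


def load_panel(path) -> list[PanelGene]:
    """Read a tab-separated panel table: symbol, risk_category,
    acmg_reportable (yes/no), inheritance. Symbols must be unique."""
    genes: list[PanelGene] = []
    seen: set[str] = set()
    with Path(path).open("r", encoding="utf-8") as handle:
        header = handle.readline().rstrip("\n").split("\t")
        expected = ["symbol", "risk_category", "acmg_reportable", "inheritance"]
        if header != expected:
            raise ValueError(f"{path}: expected header {expected}, got {header}")
        for line_no, line in enumerate(handle, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}: line {line_no}: expected 4 columns")
            symbol, risk, reportable, inheritance = parts
            if symbol in seen:
                raise ValueError(f"{path}: duplicate gene symbol {symbol!r}")
            seen.add(symbol)
            if reportable.lower() not in ("yes", "no"):
                raise ValueError(
                    f"{path}: line {line_no}: acmg_reportable must be yes/no"
                )
            genes.append(
                PanelGene(
                    symbol=symbol,
                    risk_category=RiskCategory(risk),
                    acmg_reportable=reportable.lower() == "yes",
                    inheritance=Inheritance(inheritance),
                )
            )
    return genes


def core_panel() -> list[PanelGene]:
    """The shipped 23-gene fixture (genes with documented findings)."""
    ref = resources.files("hboc_triage") / "data" / "panel_genes.tsv"
    with resources.as_file(ref) as path:
        return load_panel(path)


def default_panel(n_genes: int = PANEL_SIZE) -> list[PanelGene]:
    """The default panel: the shipped fixture, extended with known
    screened genes and deterministic filler symbols up to ``n_genes``."""
    genes = core_panel()
    if n_genes < len(genes):
        raise ValueError(f"n_genes must be >= {len(genes)}")
    for symbol, risk, reportable, inheritance in _EXTRA_KNOWN:
        if len(genes) >= n_genes:
            break
        genes.append(PanelGene(symbol, risk, reportable, inheritance))
    filler = 1
    while len(genes) < n_genes:
        genes.append(
            PanelGene(
                symbol=f"PANELG{filler:03d}",
                risk_category=RiskCategory.UNKNOWN,
                acmg_reportable=False,
                inheritance=Inheritance.UNKNOWN,
            )
        )
        filler += 1
    return genes
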