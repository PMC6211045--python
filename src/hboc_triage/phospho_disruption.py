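"""Phosphosite-disruption flagging of missense VUS.

Rare missense variants of uncertain significance are screened against a
table of annotated phosphorylation sites (protein, 1-based residue
position, acceptor residue S/T/Y). A substitution that replaces the
acceptor residue at an annotated site with a non-phospho-acceptor is a
``site_loss``; a substitution near a site (within ``window`` residues)
that is not a loss is a ``flanking_change`` — kinase recognition motifs
span a few residues on either side of the acceptor, so nearby changes
can rewire phosphorylation without removing the acceptor itself.
Acceptor-preserving substitutions at the site (e.g. S->T) keep the
phospho-acceptor chemistry and are not flagged.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

__all__ = [
    "PhosphoFlag",
    "PhosphoSiteTable",
    "PhosphoAssessment",
    "parse_missense_hgvs",
    "find_site_disruptions",
    "NotASubstitutionError",
]

_ACCEPTORS = frozenset("STY")

_AA3_TO_1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
}

# one-letter codes restricted to the 20 standard residues, so stop
# gains (X/*) and extension syntax never parse as substitutions
_AA1 = "ACDEFGHIKLMNPQRSTVWY"
_HGVS_SUB_1 = re.compile(rf"^(?:p\.)?([{_AA1}])(\d+)([{_AA1}])$")
_HGVS_SUB_3 = re.compile(r"^(?:p\.)?([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2})$")


class NotASubstitutionError(ValueError):
    """The protein HGVS string does not encode a simple substitution."""


def parse_missense_hgvs(hgvs_p: str) -> tuple[str, int, str]:
    """Parse a simple protein substitution, e.g. ``p.S2535G`` or
    ``p.Ser2535Gly``, into (ref_residue, position, alt_residue) with
    one-letter residue codes.

    Frameshift, extension, deletion and other non-substitution syntax
    raises :class:`NotASubstitutionError`.
    """
    text = hgvs_p.strip()
    m = _HGVS_SUB_1.match(text)
    if m:
        return m.group(1), int(m.group(2)), m.group(3)
    m = _HGVS_SUB_3.match(text)
    if m:
        ref3, pos, alt3 = m.group(1), int(m.group(2)), m.group(3)
        if ref3 not in _AA3_TO_1 or alt3 not in _AA3_TO_1:
            raise NotASubstitutionError(
                f"{hgvs_p!r}: unrecognised three-letter residue code"
            )
        return _AA3_TO_1[ref3], pos, _AA3_TO_1[alt3]
    raise NotASubstitutionError(
        f"{hgvs_p!r} is not a simple protein substitution (p.RefPosAlt)"
    )


@dataclass
class PhosphoSiteTable:
    """Annotated phosphorylation sites: protein identifier -> mapping of
    1-based residue position to acceptor residue (S, T or Y)."""

    sites: dict[str, dict[int, str]] = field(default_factory=dict)

    def add(self, protein: str, position: int, residue: str) -> None:
        residue = residue.upper()
        if residue not in _ACCEPTORS:
            raise ValueError(f"phospho-acceptor must be one of S/T/Y, got {residue!r}")
        if position < 1:
            raise ValueError("site positions are 1-based and must be >= 1")
        per_protein = self.sites.setdefault(protein, {})
        if position in per_protein and per_protein[position] != residue:
            raise ValueError(
                f"conflicting residues for {protein} position {position}"
            )
        per_protein[position] = residue

    def __contains__(self, protein: str) -> bool:
        return protein in self.sites

    def sites_for(self, protein: str) -> dict[int, str]:
        return self.sites.get(protein, {})

    @classmethod
    def from_tsv(cls, path) -> "PhosphoSiteTable":
        """Load a tab-separated table with columns protein, position,
        residue (header optional)."""
        table = cls()
        with Path(path).open("r", encoding="utf-8") as handle:
            for line_no, line in enumerate(handle, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 3:
                    raise ValueError(
                        f"{path}: line {line_no}: expected 3 columns "
                        "(protein, position, residue)"
                    )
                if line_no == 1 and parts[0].lower() == "protein":
                    continue
                table.add(parts[0], int(parts[1]), parts[2])
        return table


class PhosphoFlag(enum.Enum):
    SITE_LOSS = "site_loss"
    FLANKING_CHANGE = "flanking_change"
    NONE = "none"


@dataclass(frozen=True)
class PhosphoAssessment:
    """Flag for one missense substitution, with supporting notes (e.g.
    ``no_site_data`` when the protein is absent from the table, or a
    data-inconsistency warning when the observed reference residue
    contradicts the annotated site)."""

    protein: str
    hgvs_p: str
    flag: PhosphoFlag
    site_position: Optional[int] = None
    notes: tuple[str, ...] = ()


def _assess_one(
    protein: str,
    hgvs_p: str,
    site_table: PhosphoSiteTable,
    window: int,
) -> PhosphoAssessment:
    ref, pos, alt = parse_missense_hgvs(hgvs_p)
    if protein not in site_table:
        return PhosphoAssessment(protein, hgvs_p, PhosphoFlag.NONE, notes=("no_site_data",))
    notes: list[str] = []
    flanking_site: Optional[int] = None
    for site_pos, site_res in sorted(site_table.sites_for(protein).items()):
        if pos == site_pos:
            if ref != site_res:
                notes.append(
                    f"inconsistent_reference_residue:{ref}{pos}!={site_res}{site_pos}"
                )
                continue
            if alt not in _ACCEPTORS:
                return PhosphoAssessment(
                    protein, hgvs_p, PhosphoFlag.SITE_LOSS, site_pos, tuple(notes)
                )
            # S->T etc.: acceptor chemistry retained, not a loss and not
            # a flanking change either.
            notes.append(f"acceptor_preserved:{site_pos}")
        elif abs(pos - site_pos) <= window and flanking_site is None:
            flanking_site = site_pos
    if flanking_site is not None:
        return PhosphoAssessment(
            protein, hgvs_p, PhosphoFlag.FLANKING_CHANGE, flanking_site, tuple(notes)
        )
    return PhosphoAssessment(protein, hgvs_p, PhosphoFlag.NONE, notes=tuple(notes))


def find_site_disruptions(
    missense_vus_list: Iterable[tuple[str, str]],
    site_table: PhosphoSiteTable,
    window: int = 5,
) -> list[PhosphoAssessment]:
    """Flag each (protein, hgvs_p) missense VUS against the site table.

    Per-variant independent (the output order follows the input order
    and each flag depends only on that variant), so the flag
    distribution is stable under permutation of the input.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    return [
        _assess_one(protein, hgvs_p, site_table, window)
        for protein, hgvs_p in missense_vus_list
    ]
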