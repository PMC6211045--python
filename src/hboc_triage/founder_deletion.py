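"""In-silico three-primer PCR genotyping of a founder deletion.

Models the rapid PCR test used to genotype large founder deletions such
as the Mexican BRCA1 exon 9-12 deletion: a shared forward primer (P1)
pairs with a reverse primer inside the deleted interval (P2; wild-type
product) and with a reverse primer downstream of it (P3). On the intact
allele P1-P3 is too far apart to amplify; on the deleted allele the
junction brings P3 within range, so the two reactions together read out
the genotype.

Primer binding is exact-match (the assay is presence/absence; mismatch
thermodynamics is out of scope) and an amplicon forms whenever the
forward site lies 5' of the reverse-binding end and the product is no
longer than ``max_amplicon``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

from Bio.Seq import reverse_complement

__all__ = [
    "PrimerAssay",
    "Locus",
    "DeletionGenotype",
    "apply_deletion",
    "simulate_pcr",
    "call_deletion_genotype",
    "genotype_individual",
]

_VALID_BASES = frozenset("ACGT")


def _check_dna(seq: str, what: str) -> None:
    if not seq:
        raise ValueError(f"{what} must be a non-empty A/C/G/T string")
    if not set(seq) <= _VALID_BASES:
        raise ValueError(f"{what} contains non-ACGT characters")


@dataclass(frozen=True)
class PrimerAssay:
    """Three-primer deletion assay: P1 forward; P2 reverse inside the
    deleted interval (wild-type product with P1); P3 reverse downstream
    of the deletion (junction product with P1). Amplification succeeds
    only for products of at most ``max_amplicon`` bp."""

    p1: str
    p2: str
    p3: str
    max_amplicon: int = 2000

    def __post_init__(self) -> None:
        for name in ("p1", "p2", "p3"):
            _check_dna(getattr(self, name), f"primer {name}")
        if self.max_amplicon <= max(len(self.p1), len(self.p2), len(self.p3)):
            raise ValueError("max_amplicon must exceed the primer lengths")


@dataclass(frozen=True)
class Locus:
    """Reference sequence of the assay region with the deletion as a
    half-open 0-based interval [start, end)."""

    sequence: str
    deletion_start: int
    deletion_end: int

    def __post_init__(self) -> None:
        _check_dna(self.sequence, "locus sequence")
        if not (0 <= self.deletion_start < self.deletion_end <= len(self.sequence)):
            raise ValueError(
                f"deletion interval [{self.deletion_start}, {self.deletion_end}) "
                f"out of bounds for sequence of length {len(self.sequence)}"
            )

    @property
    def deletion_interval(self) -> tuple[int, int]:
        return (self.deletion_start, self.deletion_end)


class DeletionGenotype(enum.Enum):
    WILD_TYPE = "wild_type"
    HETEROZYGOUS_DELETION = "heterozygous_deletion"
    HOMOZYGOUS_DELETION = "homozygous_deletion"
    FAILED_ASSAY = "failed_assay"


def apply_deletion(locus: Locus) -> str:
    """Return the deleted allele sequence: the locus sequence with
    [deletion_start, deletion_end) removed."""
    return locus.sequence[: locus.deletion_start] + locus.sequence[locus.deletion_end :]


def _find_all(haystack: str, needle: str) -> list[int]:
    hits = []
    start = 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return hits
        hits.append(i)
        start = i + 1  # overlapping occurrences count


def simulate_pcr(
    template: str,
    forward_primer: str,
    reverse_primer: str,
    max_amplicon: int = 2000,
) -> list[int]:
    """Predict amplicon lengths under the exact-match binding model.

    The forward primer binds where the template contains it verbatim;
    the reverse primer binds where the template contains its reverse
    complement. One amplicon arises per (forward site, reverse site)
    pair with the forward start 5' of the reverse-binding end; its
    length is the distance from forward start to reverse-binding end,
    inclusive. Pairs longer than ``max_amplicon`` do not amplify.
    Returns sorted lengths; no binding gives an empty list.
    """
    _check_dna(template, "template")
    _check_dna(forward_primer, "forward primer")
    _check_dna(reverse_primer, "reverse primer")
    if max_amplicon < 1:
        raise ValueError("max_amplicon must be positive")
    fwd_sites = _find_all(template, forward_primer)
    rev_sites = _find_all(template, reverse_complement(reverse_primer))
    rev_len = len(reverse_primer)
    products = []
    for f in fwd_sites:
        for r in rev_sites:
            end = r + rev_len  # one past the reverse-binding end
            length = end - f
            if f < end and length <= max_amplicon:
                products.append(length)
    return sorted(products)


def call_deletion_genotype(
    wt_allele_products: Sequence[int],
    del_allele_products: Sequence[int],
) -> DeletionGenotype:
    """Call a genotype from the two PCR reactions of one individual.

    ``wt_allele_products``: amplicons of the P1/P2 (wild-type) reaction;
    ``del_allele_products``: amplicons of the P1/P3 (junction) reaction.
    Wild-type band only -> wild_type; both bands -> heterozygous
    deletion; junction band only -> homozygous deletion; no band ->
    failed assay.
    """
    has_wt = len(wt_allele_products) > 0
    has_del = len(del_allele_products) > 0
    if has_wt and has_del:
        return DeletionGenotype.HETEROZYGOUS_DELETION
    if has_wt:
        return DeletionGenotype.WILD_TYPE
    if has_del:
        return DeletionGenotype.HOMOZYGOUS_DELETION
    return DeletionGenotype.FAILED_ASSAY


def genotype_individual(
    alleles: Sequence[str], assay: PrimerAssay
) -> DeletionGenotype:
    """Run both reactions over an individual's allele pool and call the
    genotype. Each allele is a template; products pool across alleles as
    they would in one tube."""
    wt_products: list[int] = []
    del_products: list[int] = []
    for allele in alleles:
        wt_products += simulate_pcr(allele, assay.p1, assay.p2, assay.max_amplicon)
        del_products += simulate_pcr(allele, assay.p1, assay.p3, assay.max_amplicon)
    return call_deletion_genotype(wt_products, del_products)
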