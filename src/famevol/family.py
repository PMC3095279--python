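"""Family membership, subfamily classification, and pseudogene detection.

Membership is decided by the presence of two well-separated catalytic
HxKxxxxD (HKD) motifs in the protein sequence; subfamilies come from a
supplied domain-annotation table (C2 / PX+PH / signal peptide); a gene is
flagged as a pseudogene when its CDS carries a premature in-frame stop.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .kaks import GENETIC_CODE, STOP_CODONS

__all__ = [
    "AMINO_ALPHABET",
    "HKD_PATTERN",
    "ProteinRecord",
    "DomainAnnotation",
    "FamilyAssignment",
    "scan_hkd",
    "qualify_member",
    "classify_subfamily",
]

AMINO_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*")

#: the catalytic motif: H, any, K, four any, D (8 residues)
HKD_PATTERN = re.compile(r"H.K....D")

SUBFAMILIES = ("C2", "PXPH", "SP", "unclassified")
DOMAIN_NAMES = frozenset({"C2", "PX", "PH", "SignalPeptide"})


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    sequence: str
    species: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.id}: empty protein sequence")
        bad = set(self.sequence.upper()) - AMINO_ALPHABET
        if bad:
            raise ValueError(f"{self.id}: invalid residues {sorted(bad)}")


@dataclass(frozen=True)
class DomainAnnotation:
    gene_id: str
    domain_name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.domain_name not in DOMAIN_NAMES:
            raise ValueError(f"unknown domain name {self.domain_name!r}")
        if not (1 <= self.start <= self.end):
            raise ValueError(f"{self.gene_id}: bad domain span {self.start}..{self.end}")


@dataclass(frozen=True)
class FamilyAssignment:
    gene_id: str
    is_member: bool
    subfamily: str
    hkd_hits: tuple[tuple[int, int], ...]
    pseudogene: bool


def scan_hkd(sequence: str) -> list[tuple[int, int]]:
    """Left-to-right non-overlapping HxKxxxxD matches as 1-based spans."""
    seq = sequence.upper()
    return [(m.start() + 1, m.end()) for m in HKD_PATTERN.finditer(seq)]


def _separated_hits(hits: Sequence[tuple[int, int]], min_separation: int) -> list[tuple[int, int]]:
    kept: list[tuple[int, int]] = []
    for hit in hits:
        if not kept or hit[0] - kept[-1][0] >= min_separation:
            kept.append(hit)
    return kept


def has_premature_stop(cds: str) -> bool:
    """True iff the CDS has an in-frame stop codon before its final codon.

    A trailing partial codon is trimmed; invalid characters are an error
    naming the offending position.
    """
    cds = cds.upper()
    for i, base in enumerate(cds):
        if base not in "ACGTN":
            raise ValueError(f"invalid CDS character {base!r} at position {i + 1}")
    usable = len(cds) - len(cds) % 3
    for i in range(0, usable - 3, 3):
        if cds[i : i + 3] in STOP_CODONS:
            return True
    return False


def qualify_member(
    protein: ProteinRecord,
    cds: Optional[str] = None,
    *,
    min_separation: int = 50,
) -> FamilyAssignment:
    """Decide membership (>= 2 separated HKD hits) and pseudogene status.

    ``min_separation`` is the minimum distance between accepted hit starts,
    so one catalytic region is never counted twice.  Subfamily is left
    'unclassified' here; see :func:`classify_subfamily`.
    """
    hits = _separated_hits(scan_hkd(protein.sequence), min_separation)
    is_member = len(hits) >= 2
    pseudo = has_premature_stop(cds) if cds is not None else False
    return FamilyAssignment(
        gene_id=protein.id,
        is_member=is_member,
        subfamily="unclassified",
        hkd_hits=tuple(hits),
        pseudogene=pseudo,
    )


def classify_subfamily(annotations: Iterable[DomainAnnotation]) -> str:
    """Subfamily from one gene's domain set, precedence C2 > PXPH > SP."""
    anns = list(annotations)
    genes = {a.gene_id for a in anns}
    if len(genes) > 1:
        raise ValueError(f"annotations span multiple genes: {sorted(genes)}")
    names = {a.domain_name for a in anns}
    has_c2 = "C2" in names
    has_pxph = {"PX", "PH"} <= names
    has_sp = "SignalPeptide" in names
    if has_c2 and has_pxph:
        warnings.warn(
            f"gene {genes.pop() if genes else '?'}: conflicting domain set {sorted(names)}; "
            "applying precedence C2 > PXPH > SP",
            stacklevel=2,
        )
    if has_c2:
        return "C2"
    if has_pxph:
        return "PXPH"
    if has_sp and not ({"PX", "PH"} & names):
        return "SP"
    return "unclassified"
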