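"""Regex motif scanning, three-region partition, and shared-motif reports.

Proteins are scanned with user-supplied regular-expression motifs; hits
are partitioned relative to the two catalytic HKD domains into N-terminal
(before the first), middle (in and between the two), and C-terminal
(after the second) regions; presence matrices compare motif repertoires
between subfamilies.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "MotifDefinition",
    "MotifHit",
    "MotifArchitecture",
    "scan_motifs",
    "partition_regions",
    "presence_matrix",
    "shared_motifs",
]

REGIONS = ("N-terminal", "middle", "C-terminal", "unpartitioned")


@dataclass(frozen=True)
class MotifDefinition:
    motif_id: str
    pattern: str

    def compiled(self) -> re.Pattern:
        try:
            return re.compile(self.pattern)
        except re.error as exc:
            raise ValueError(f"motif {self.motif_id!r}: invalid pattern {self.pattern!r}: {exc}") from exc


@dataclass(frozen=True)
class MotifHit:
    motif_id: str
    start: int  # 1-based inclusive
    end: int
    region: str = "unpartitioned"


@dataclass(frozen=True)
class MotifArchitecture:
    protein_id: str
    hits: tuple[MotifHit, ...]  # sorted by start


def scan_motifs(sequence: str, defs: Sequence[MotifDefinition]) -> list[MotifHit]:
    """All leftmost non-overlapping matches of each motif, 1-based spans."""
    hits = []
    for d in defs:
        pattern = d.compiled()
        for m in pattern.finditer(sequence):
            hits.append(MotifHit(motif_id=d.motif_id, start=m.start() + 1, end=m.end()))
    hits.sort(key=lambda h: (h.start, h.end, h.motif_id))
    return hits


def partition_regions(
    hits: Iterable[MotifHit],
    hkd1: Optional[tuple[int, int]],
    hkd2: Optional[tuple[int, int]],
) -> list[MotifHit]:
    """Tag each hit N-terminal / middle / C-terminal relative to the HKD spans.

    N-terminal: hit ends before the first HKD starts; middle: hit overlaps
    the interval from the first HKD start to the second HKD end;
    C-terminal: hit starts after the second HKD ends.  Missing spans leave
    every hit 'unpartitioned'.
    """
    hits = list(hits)
    if hkd1 is None or hkd2 is None:
        return [MotifHit(h.motif_id, h.start, h.end, "unpartitioned") for h in hits]
    if hkd1[1] >= hkd2[0]:
        raise ValueError(f"first HKD span {hkd1} must end before the second {hkd2} starts")
    lo, hi = hkd1[0], hkd2[1]
    out = []
    for h in hits:
        if h.end < lo:
            region = "N-terminal"
        elif h.start > hi:
            region = "C-terminal"
        else:
            region = "middle"
        out.append(MotifHit(h.motif_id, h.start, h.end, region))
    return out


def presence_matrix(
    architectures: Iterable[MotifArchitecture],
    motif_ids: Sequence[str],
    groups: Mapping[str, str],
) -> pd.DataFrame:
    """Proteins x motifs boolean presence, with a 'group' column."""
    rows = {}
    for arch in architectures:
        present = {h.motif_id for h in arch.hits}
        rows[arch.protein_id] = {m: (m in present) for m in motif_ids}
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(motif_ids)).fillna(False)
    df["group"] = [groups.get(p, "unclassified") for p in df.index]
    return df


def shared_motifs(
    matrix: pd.DataFrame,
    group_a: str,
    group_b: str,
    threshold: float = 0.5,
) -> dict[str, list[str]]:
    """Split motifs into shared / A-specific / B-specific / neither.

    A motif is present in a group when its within-group prevalence is at
    least ``threshold``; shared means present in both groups.
    """
    sub_a = matrix[matrix["group"] == group_a]
    sub_b = matrix[matrix["group"] == group_b]
    if sub_a.empty or sub_b.empty:
        raise ValueError(f"empty group: {group_a if sub_a.empty else group_b!r}")
    motif_cols = [c for c in matrix.columns if c != "group"]
    out: dict[str, list[str]] = {"shared": [], "a_specific": [], "b_specific": [], "neither": []}
    for m in motif_cols:
        in_a = sub_a[m].mean() >= threshold
        in_b = sub_b[m].mean() >= threshold
        if in_a and in_b:
            out["shared"].append(m)
        elif in_a:
            out["a_specific"].append(m)
        elif in_b:
            out["b_specific"].append(m)
        else:
            out["neither"].append(m)
    return out
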