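"""Pairwise Ka/Ks estimation by the Nei-Gojobori (1986) counting method.

Synonymous and nonsynonymous sites are counted fractionally per codon,
differences between codon pairs are averaged over all mutational pathways
that avoid stop codons, and proportions are corrected for multiple hits
with the Jukes-Cantor formula.  A sliding-window scan reuses the same
estimator on fixed-width nucleotide windows.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import permutations
from typing import Iterable, Sequence

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

__all__ = [
    "GENETIC_CODE",
    "SENSE_CODONS",
    "STOP_CODONS",
    "CodonAlignment",
    "KaKsResult",
    "SlidingWindowProfile",
    "codon_align",
    "ng86_site_counts",
    "ng86_codon_differences",
    "ng86_pair",
    "jukes_cantor",
    "sliding_window_omega",
    "mean_ks",
]

_BASES = "ACGT"

#: codon -> amino acid, stops mapped to '*' (standard code)
GENETIC_CODE: dict[str, str] = dict(standard_dna_table.forward_table)
GENETIC_CODE.update({c: "*" for c in standard_dna_table.stop_codons})

STOP_CODONS = frozenset(standard_dna_table.stop_codons)
SENSE_CODONS = tuple(sorted(set(GENETIC_CODE) - STOP_CODONS))


class SaturationError(ValueError):
    """Observed proportion of differences is beyond the correctable range."""


@dataclass(frozen=True)
class CodonAlignment:
    """A gap-free pair of codon sequences of equal length (multiple of 3)."""

    seq1: str
    seq2: str

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.seq2):
            raise ValueError("codon alignment rows differ in length")
        if len(self.seq1) % 3:
            raise ValueError("codon alignment length not a multiple of 3")
        for name, seq in (("seq1", self.seq1), ("seq2", self.seq2)):
            bad = next((i for i, b in enumerate(seq) if b not in _BASES), None)
            if bad is not None:
                raise ValueError(f"{name}: invalid base {seq[bad]!r} at position {bad + 1}")

    @property
    def n_codons(self) -> int:
        return len(self.seq1) // 3

    def codons(self) -> Iterable[tuple[str, str]]:
        for i in range(0, len(self.seq1), 3):
            yield self.seq1[i : i + 3], self.seq2[i : i + 3]

    def slice_codons(self, first: int, last: int) -> "CodonAlignment":
        """Sub-alignment of codon columns ``first:last`` (0-based, half-open)."""
        return CodonAlignment(self.seq1[3 * first : 3 * last], self.seq2[3 * first : 3 * last])


@dataclass(frozen=True)
class KaKsResult:
    """NG86 summary for one codon-aligned pair (or window thereof).

    ``nan`` marks undefined quantities (saturation, zero sites, or 0/0);
    ``inf`` marks omega with Ka > 0 but Ks = 0.
    """

    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    Ka: float
    Ks: float
    omega: float
    n_codons: int


@dataclass(frozen=True)
class SlidingWindowProfile:
    window_nt: int
    step_nt: int
    windows: tuple[tuple[int, int, KaKsResult], ...]  # (start, end) 1-based inclusive nt


def _translate(cds: str) -> str:
    return str(Seq(cds).translate())


def codon_align(
    aln_row1: str,
    aln_row2: str,
    cds1: str,
    cds2: str,
) -> CodonAlignment:
    """Back-translate an aligned protein pair to codons and drop bad columns.

    Each CDS must translate (standard code) to its ungapped protein row; a
    trailing stop codon is tolerated.  Codon columns containing a gap in
    either row, or any non-ACGT base, are removed.
    """
    pairs = []
    for row, cds, name in ((aln_row1, cds1, "first"), (aln_row2, cds2, "second")):
        prot = row.replace("-", "")
        cds = cds.upper()
        if len(cds) == 3 * len(prot) + 3:
            cds = cds[:-3]  # trailing stop codon
        if len(cds) != 3 * len(prot):
            raise ValueError(
                f"{name} CDS length {len(cds)} does not match {len(prot)} aligned residues"
            )
        trans = _translate(cds)
        for i, (a, b) in enumerate(zip(trans, prot)):
            if a != b and b != "X":
                raise ValueError(
                    f"{name} sequence: translation mismatch at residue {i + 1} "
                    f"({a!r} from CDS vs {b!r} in alignment)"
                )
        pairs.append((row, cds))

    out1, out2 = [], []
    i1 = i2 = 0
    for a, b in zip(pairs[0][0], pairs[1][0]):
        c1 = pairs[0][1][3 * i1 : 3 * i1 + 3] if a != "-" else None
        c2 = pairs[1][1][3 * i2 : 3 * i2 + 3] if b != "-" else None
        if a != "-":
            i1 += 1
        if b != "-":
            i2 += 1
        if c1 is None or c2 is None:
            continue
        if any(base not in _BASES for base in c1 + c2):
            continue
        out1.append(c1)
        out2.append(c2)
    return CodonAlignment("".join(out1), "".join(out2))


def _site_counts_uncached(codon: str) -> tuple[float, float]:
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon!r} has no site counts")
    aa = GENETIC_CODE[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        viable = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            mut = codon[:pos] + base + codon[pos + 1 :]
            if mut in STOP_CODONS:
                continue  # mutations to stops excluded from site counting
            viable += 1
            if GENETIC_CODE[mut] == aa:
                syn += 1
        if viable:
            s += syn / viable
    return s, 3.0 - s


_SITE_CACHE: dict[str, tuple[float, float]] = {}


def ng86_site_counts(codon: str) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) site counts of a sense codon.

    Per position, the synonymous fraction is the number of the three
    single-base changes that preserve the amino acid, among those that do
    not create a stop codon.  s + n = 3 for every codon.
    """
    codon = codon.upper()
    try:
        return _SITE_CACHE[codon]
    except KeyError:
        result = _site_counts_uncached(codon)
        _SITE_CACHE[codon] = result
        return result


def _pathway_steps(c1: str, c2: str, order: Sequence[int], allow_stops: bool):
    cur = c1
    syn = nonsyn = 0
    for pos in order:
        nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
        if nxt in STOP_CODONS and not allow_stops:
            return None
        if GENETIC_CODE[nxt] == GENETIC_CODE[cur] and nxt not in STOP_CODONS and cur not in STOP_CODONS:
            syn += 1
        else:
            nonsyn += 1
        cur = nxt
    return syn, nonsyn


_DIFF_CACHE: dict[tuple[str, str], tuple[float, float]] = {}


def ng86_codon_differences(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences for one codon pair.

    Multi-substitution codon pairs are scored by equal-weight averaging over
    every mutational pathway whose intermediates avoid stop codons; if every
    pathway is blocked, all pathways are used as a fallback.
    """
    key = (c1, c2)
    cached = _DIFF_CACHE.get(key)
    if cached is not None:
        return cached
    if c1 in STOP_CODONS or c2 in STOP_CODONS:
        raise ValueError("stop codon in codon pair")
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        result = (0.0, 0.0)
    else:
        tallies = [
            t
            for order in permutations(diff_pos)
            if (t := _pathway_steps(c1, c2, order, allow_stops=False)) is not None
        ]
        if not tallies:
            tallies = [_pathway_steps(c1, c2, order, allow_stops=True) for order in permutations(diff_pos)]
        sd = sum(t[0] for t in tallies) / len(tallies)
        nd = sum(t[1] for t in tallies) / len(tallies)
        result = (sd, nd)
    _DIFF_CACHE[key] = result
    return result


def jukes_cantor(p: float) -> float:
    """Jukes-Cantor multiple-hit correction d = -(3/4) ln(1 - 4p/3)."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        raise SaturationError(f"proportion {p} >= 3/4 is saturated")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def ng86_pair(aln: CodonAlignment) -> KaKsResult:
    """NG86 estimate of Ka, Ks and omega for one codon-aligned pair."""
    if aln.n_codons < 1:
        raise ValueError("empty codon alignment")
    s1 = n1 = s2 = n2 = 0.0
    sd = nd = 0.0
    for c1, c2 in aln.codons():
        a, b = ng86_site_counts(c1), ng86_site_counts(c2)
        s1 += a[0]
        n1 += a[1]
        s2 += b[0]
        n2 += b[1]
        d = ng86_codon_differences(c1, c2)
        sd += d[0]
        nd += d[1]
    S = (s1 + s2) / 2.0
    N = (n1 + n2) / 2.0
    pS = sd / S if S > 0 else math.nan
    pN = nd / N if N > 0 else math.nan

    def _correct(p: float) -> float:
        if math.isnan(p):
            return math.nan
        try:
            return jukes_cantor(p)
        except SaturationError:
            return math.nan

    Ks = _correct(pS)
    Ka = _correct(pN)
    if math.isnan(Ka) or math.isnan(Ks):
        omega = math.nan
    elif Ks == 0.0:
        omega = math.nan if Ka == 0.0 else math.inf
    else:
        omega = Ka / Ks
    return KaKsResult(S=S, N=N, Sd=sd, Nd=nd, pS=pS, pN=pN, Ka=Ka, Ks=Ks, omega=omega, n_codons=aln.n_codons)


def sliding_window_omega(
    aln: CodonAlignment,
    window_nt: int = 300,
    step_nt: int = 50,
) -> SlidingWindowProfile:
    """Score fixed-width nucleotide windows of the alignment with NG86.

    Windows start at offsets 0, step, 2*step, ... while a full window fits
    (count = floor((L - window)/step) + 1).  Windows are defined on
    nucleotide coordinates; partial codons at window edges are dropped from
    scoring.  An alignment shorter than the window is scored as one whole-
    alignment window, with a warning.
    """
    if window_nt < 3 or step_nt < 1:
        raise ValueError("window must be >= 3 nt and step >= 1 nt")
    L = len(aln.seq1)
    if L < window_nt:
        warnings.warn(
            f"alignment length {L} nt shorter than window {window_nt} nt; "
            "scoring a single whole-alignment window",
            stacklevel=2,
        )
        return SlidingWindowProfile(
            window_nt=window_nt,
            step_nt=step_nt,
            windows=((1, L, ng86_pair(aln)),),
        )
    windows = []
    for start in range(0, L - window_nt + 1, step_nt):
        end = start + window_nt  # half-open in nt
        first_codon = -(-start // 3)  # first codon fully inside
        last_codon = end // 3  # one past the last full codon
        result = ng86_pair(aln.slice_codons(first_codon, last_codon))
        windows.append((start + 1, end, result))
    return SlidingWindowProfile(window_nt=window_nt, step_nt=step_nt, windows=tuple(windows))


def mean_ks(values: Iterable[float], cutoff: float = 2.0) -> float:
    """Arithmetic mean of Ks values after discarding saturated ones (> cutoff).

    Undefined (NaN) entries are discarded with the saturated ones.  Returns
    NaN when nothing survives the filter; negative input is an error.
    """
    kept = []
    for v in values:
        if math.isnan(v):
            continue
        if v < 0:
            raise ValueError(f"negative Ks value {v}")
        if v <= cutoff:
            kept.append(v)
    if not kept:
        return math.nan
    return sum(kept) / len(kept)
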