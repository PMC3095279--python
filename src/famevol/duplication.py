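"""Paralog-pair extraction and duplication-mechanism classification.

Same-species cherries of the family tree are the candidate paralog pairs.
A pair is *tandem* when the two genes are adjacent (or nearly adjacent) in
one chromosome's gene order, and *segmental* when the gene neighborhoods
around the two copies share conserved protein-coding genes, measured as a
one-to-one matching over a fixed flanking window on each side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx

from .phylogeny import Tree

__all__ = [
    "GeneLocus",
    "GeneOrder",
    "HomologyMap",
    "DuplicationParams",
    "DuplicationCall",
    "terminal_paralog_pairs",
    "tandem_test",
    "flanking_conservation",
    "classify_duplication",
]


@dataclass(frozen=True)
class GeneLocus:
    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"
    rank: int = -1  # 0-based index in the chromosome's order, set by GeneOrder

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")


class GeneOrder:
    """Per-chromosome gene order ranked by start coordinate."""

    def __init__(self, loci: Iterable[GeneLocus]) -> None:
        by_chrom: dict[str, list[GeneLocus]] = {}
        for locus in loci:
            by_chrom.setdefault(locus.chromosome, []).append(locus)
        self.loci: dict[str, GeneLocus] = {}
        self.chromosomes: dict[str, list[str]] = {}
        for chrom, genes in by_chrom.items():
            genes.sort(key=lambda g: (g.start, g.gene_id))
            order = []
            for rank, g in enumerate(genes):
                ranked = GeneLocus(g.gene_id, g.chromosome, g.start, g.end, g.strand, rank)
                if g.gene_id in self.loci:
                    raise ValueError(f"duplicate gene id {g.gene_id}")
                self.loci[g.gene_id] = ranked
                order.append(g.gene_id)
            self.chromosomes[chrom] = order

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.loci

    def locus(self, gene_id: str) -> GeneLocus:
        return self.loci[gene_id]

    def flank(
        self,
        gene_id: str,
        side: str,
        window: int,
        exclude: frozenset = frozenset(),
    ) -> list[str]:
        """Up to ``window`` genes up- or downstream, skipping excluded ids.

        Truncated silently at chromosome ends.
        """
        locus = self.loci[gene_id]
        order = self.chromosomes[locus.chromosome]
        step = -1 if side == "up" else 1
        out: list[str] = []
        i = locus.rank + step
        while 0 <= i < len(order) and len(out) < window:
            gid = order[i]
            if gid not in exclude and gid != gene_id:
                out.append(gid)
            i += step
        return out


class HomologyMap:
    """Symmetric, irreflexive set of homologous gene-id pairs."""

    def __init__(self, pairs: Iterable[tuple[str, str]] = ()) -> None:
        self._pairs: set[frozenset] = set()
        for a, b in pairs:
            self.add(a, b)

    def add(self, a: str, b: str) -> None:
        if a == b:
            raise ValueError(f"self-homology for {a!r}")
        self._pairs.add(frozenset((a, b)))

    def homologous(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self._pairs

    def __len__(self) -> int:
        return len(self._pairs)

    def __iter__(self):
        for p in sorted(tuple(sorted(x)) for x in self._pairs):
            yield p


@dataclass(frozen=True)
class DuplicationParams:
    max_intervening: int = 1  # tandem: genes allowed between the pair
    min_conserved: int = 1  # segmental: minimum conserved flank count
    flank_window: int = 10  # genes examined on each side
    min_support: Optional[float] = None  # cherry bootstrap filter


@dataclass(frozen=True)
class DuplicationCall:
    pair: tuple[str, str]
    mechanism: str  # tandem | segmental | undetermined
    conserved_flank_count: Optional[int]
    mean_flanking_ks: float = math.nan


def terminal_paralog_pairs(
    tree: Tree,
    species_of: Mapping[str, str],
    min_support: Optional[float] = None,
) -> list[tuple[str, str]]:
    """Same-species cherries of the tree, optionally support-filtered."""
    missing = [leaf for leaf in tree.leaves if leaf not in species_of]
    if missing:
        raise ValueError(f"leaves without species tag: {missing}")
    pairs = []
    for a, b in tree.cherries():
        if species_of[a] != species_of[b]:
            continue
        if min_support is not None:
            support = tree.supports.get(tree.canonical_bipartition(frozenset((a, b))))
            if support is None or support < min_support:
                continue
        pairs.append((a, b))
    return pairs


def tandem_test(
    pair: tuple[str, str],
    gene_order: GeneOrder,
    max_intervening: int = 1,
) -> Optional[bool]:
    """True iff same chromosome with <= max_intervening genes between.

    Returns None when either gene is unplaced (undetermined signal).
    """
    a, b = pair
    if a not in gene_order or b not in gene_order:
        return None
    la, lb = gene_order.locus(a), gene_order.locus(b)
    if la.chromosome != lb.chromosome:
        return False
    return abs(la.rank - lb.rank) - 1 <= max_intervening


def flanking_conservation(
    pair: tuple[str, str],
    gene_order: GeneOrder,
    homology: HomologyMap,
    window: int = 10,
    exclude: Iterable[str] = (),
) -> int:
    """Count conserved protein-coding genes flanking a paralog pair.

    Takes up to ``window`` genes upstream and downstream of each paralog
    (skipping ids in ``exclude``, e.g. other family members), and returns
    the size of a maximum one-to-one matching of homologous pairs between
    the two flank sets (0..2*window).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    a, b = pair
    excluded = frozenset(exclude) | {a, b}
    flank_a = gene_order.flank(a, "up", window, excluded) + gene_order.flank(a, "down", window, excluded)
    flank_b = gene_order.flank(b, "up", window, excluded) + gene_order.flank(b, "down", window, excluded)
    graph = nx.Graph()
    for ga in flank_a:
        for gb in flank_b:
            if homology.homologous(ga, gb):
                graph.add_edge(("A", ga), ("B", gb))
    if graph.number_of_edges() == 0:
        return 0
    matching = nx.algorithms.matching.max_weight_matching(graph, maxcardinality=True)
    return len(matching)


def classify_duplication(
    pair: tuple[str, str],
    gene_order: GeneOrder,
    homology: HomologyMap,
    params: DuplicationParams = DuplicationParams(),
    exclude: Iterable[str] = (),
) -> DuplicationCall:
    """Tandem if adjacent; else segmental if flanks are conserved enough.

    Tandem takes precedence over segmental: physical adjacency is the
    stronger signal.  Unplaced genes yield 'undetermined'.
    """
    adjacency = tandem_test(pair, gene_order, params.max_intervening)
    if adjacency is None:
        return DuplicationCall(pair=pair, mechanism="undetermined", conserved_flank_count=None)
    if adjacency:
        count = flanking_conservation(pair, gene_order, homology, params.flank_window, exclude)
        return DuplicationCall(pair=pair, mechanism="tandem", conserved_flank_count=count)
    count = flanking_conservation(pair, gene_order, homology, params.flank_window, exclude)
    mechanism = "segmental" if count >= params.min_conserved else "undetermined"
    return DuplicationCall(pair=pair, mechanism=mechanism, conserved_flank_count=count)
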