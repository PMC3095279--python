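"""Neighbor-joining trees from protein alignments.

Distances are p-distances computed after complete deletion of gapped
columns; trees are built by the Saitou-Nei agglomeration with a
deterministic lexicographic tie-break, and edge supports come from
column-resampling bootstrap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from io import StringIO
from typing import Mapping, Sequence

import numpy as np
from Bio import Phylo

__all__ = [
    "ProteinAlignment",
    "DistanceMatrix",
    "Tree",
    "complete_deletion",
    "p_distance_matrix",
    "nj_tree",
    "bootstrap_supports",
    "assign_subgroups",
]


@dataclass(frozen=True)
class ProteinAlignment:
    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids")
        if self.rows:
            L = len(self.rows[0])
            if any(len(r) != L for r in self.rows):
                raise ValueError("alignment rows differ in length")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def subset_columns(self, cols: Sequence[int]) -> "ProteinAlignment":
        return ProteinAlignment(
            self.ids, tuple("".join(r[c] for c in cols) for r in self.rows)
        )


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix is not symmetric")
        if (d < 0).any():
            raise ValueError("distance matrix has negative entries")
        object.__setattr__(self, "d", d)


def complete_deletion(aln: ProteinAlignment) -> list[int]:
    """Indices (0-based, in order) of columns with no gap in any row."""
    if not aln.rows:
        raise ValueError("empty alignment")
    arr = np.frombuffer("".join(aln.rows).encode(), dtype="S1").reshape(aln.n_rows, aln.n_cols)
    keep = ~(arr == b"-").any(axis=0)
    cols = np.flatnonzero(keep).tolist()
    if not cols:
        raise ValueError("no comparable sites: every column contains a gap")
    return cols


def p_distance_matrix(aln: ProteinAlignment) -> DistanceMatrix:
    """Pairwise p-distances over the completely gap-free columns."""
    cols = complete_deletion(aln)
    arr = np.frombuffer("".join(aln.rows).encode(), dtype="S1").reshape(aln.n_rows, aln.n_cols)
    arr = arr[:, cols]
    n = aln.n_rows
    d = np.zeros((n, n))
    for i in range(n):
        diff = (arr[i] != arr[i + 1 :]).mean(axis=1)
        d[i, i + 1 :] = diff
        d[i + 1 :, i] = diff
    return DistanceMatrix(aln.ids, d)


class Tree:
    """Unrooted tree with named leaves, branch lengths, and edge supports.

    Internal nodes are integer ids; leaves are strings.  Supports are kept
    per bipartition (canonical frozenset of the side not containing the
    lexicographically smallest leaf).
    """

    def __init__(self) -> None:
        self.adj: dict[object, dict[object, float]] = {}
        self.supports: dict[frozenset, float] = {}
        self._next_internal = 0

    # -- construction -------------------------------------------------
    def add_node(self, node=None):
        if node is None:
            node = self._next_internal
            self._next_internal += 1
        self.adj.setdefault(node, {})
        return node

    def add_edge(self, a, b, length: float) -> None:
        self.add_node(a)
        self.add_node(b)
        self.adj[a][b] = length
        self.adj[b][a] = length

    # -- queries ------------------------------------------------------
    @property
    def leaves(self) -> list[str]:
        return sorted(n for n in self.adj if isinstance(n, str))

    def _side(self, a, b) -> frozenset:
        """Leaves reachable from ``b`` when edge (a, b) is removed."""
        seen = {a, b}
        stack = [b]
        out = set()
        while stack:
            node = stack.pop()
            if isinstance(node, str):
                out.add(node)
            for nb in self.adj[node]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return frozenset(out)

    def canonical_bipartition(self, side: frozenset) -> frozenset:
        all_leaves = frozenset(self.leaves)
        anchor = min(all_leaves)
        return all_leaves - side if anchor in side else side

    def bipartitions(self, include_trivial: bool = False) -> set[frozenset]:
        """Canonical bipartitions, one per edge (internal edges by default)."""
        out = set()
        seen_edges = set()
        for a in self.adj:
            for b in self.adj[a]:
                key = (a, b) if str(a) <= str(b) else (b, a)
                if key in seen_edges:
                    continue
                seen_edges.add(key)
                side = self._side(a, b)
                if not include_trivial and (len(side) < 2 or len(side) > len(self.leaves) - 2):
                    continue
                out.add(self.canonical_bipartition(side))
        return out

    def path_length_matrix(self, ids: Sequence[str]) -> np.ndarray:
        """Leaf-to-leaf path lengths, in the given leaf order."""
        index = {g: i for i, g in enumerate(ids)}
        n = len(ids)
        out = np.zeros((n, n))
        for src in ids:
            dist = {src: 0.0}
            stack = [src]
            while stack:
                node = stack.pop()
                for nb, w in self.adj[node].items():
                    if nb not in dist:
                        dist[nb] = dist[node] + w
                        stack.append(nb)
            for g in ids:
                out[index[src], index[g]] = dist[g]
        return out

    def cherries(self) -> list[tuple[str, str]]:
        """All two-leaf sister clades, each as a sorted leaf pair."""
        out = []
        for node, nbrs in self.adj.items():
            if isinstance(node, str):
                continue
            leaf_nbrs = sorted(n for n in nbrs if isinstance(n, str))
            if len(leaf_nbrs) == 2:
                out.append((leaf_nbrs[0], leaf_nbrs[1]))
        return sorted(out)

    # -- newick io ----------------------------------------------------
    def _newick_node(self, node, parent) -> str:
        if isinstance(node, str):
            return f"{node}:{self.adj[node][parent]:.10g}"
        parts = [self._newick_node(nb, node) for nb in sorted(self.adj[node], key=str) if nb != parent]
        label = ""
        if parent is not None:
            side = self._side(parent, node)
            support = self.supports.get(self.canonical_bipartition(side))
            if support is not None:
                label = f"{support:.10g}"
            return f"({','.join(parts)}){label}:{self.adj[node][parent]:.10g}"
        return f"({','.join(parts)}){label}"

    def to_newick(self) -> str:
        internal = [n for n in self.adj if not isinstance(n, str)]
        root = min(internal) if internal else self.leaves[0]
        return self._newick_node(root, None) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        """Parse Newick; internal node labels are read as bootstrap supports."""
        bio_tree = Phylo.read(StringIO(text), "newick")
        tree = cls()
        node_ids: dict[int, object] = {}

        def visit(clade):
            if clade.is_terminal():
                return tree.add_node(clade.name)
            node = tree.add_node()
            node_ids[id(clade)] = node
            for child in clade.clades:
                child_node = visit(child)
                length = child.branch_length if child.branch_length is not None else 0.0
                tree.add_edge(node, child_node, length)
            return node

        root = visit(bio_tree.root)
        # collapse a degree-2 root left by rooted newick
        if not isinstance(root, str) and len(tree.adj[root]) == 2:
            (a, la), (b, lb) = tree.adj[root].items()
            del tree.adj[a][root]
            del tree.adj[b][root]
            del tree.adj[root]
            tree.add_edge(a, b, la + lb)

        def collect_supports(clade):
            if clade.is_terminal():
                return
            conf = clade.confidence
            if conf is None and clade.name is not None:
                try:
                    conf = float(clade.name)
                except ValueError:
                    conf = None
            if conf is not None:
                side = frozenset(t.name for t in clade.get_terminals())
                if 2 <= len(side) <= len(tree.leaves) - 2:
                    tree.supports[tree.canonical_bipartition(side)] = float(conf)
            for child in clade.clades:
                collect_supports(child)

        collect_supports(bio_tree.root)
        return tree


def _nj_label(node, labels) -> str:
    return labels[node]


def nj_tree(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining; deterministic given the matrix.

    Ties in the Q-criterion are broken by the lexicographically smallest
    (min leaf label, max leaf label) pair.  Negative branch lengths are
    clamped to zero with the deficit moved to the sister branch.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    tree = Tree()
    active = list(range(n))
    labels = {i: dm.ids[i] for i in range(n)}  # tie-break label: min leaf below
    nodes = {i: tree.add_node(dm.ids[i]) for i in range(n)}
    d = {i: {j: float(dm.d[i, j]) for j in range(n) if j != i} for i in range(n)}
    next_key = n

    while len(active) > 3:
        r = len(active)
        R = {i: sum(d[i][j] for j in active if j != i) for i in active}
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                q = (r - 2) * d[i][j] - R[i] - R[j]
                li, lj = sorted((labels[i], labels[j]))
                cand = (q, li, lj, i, j)
                if best is None or cand[:3] < best[:3]:
                    best = cand
        _, _, _, i, j = best
        dij = d[i][j]
        li = 0.5 * dij + (R[i] - R[j]) / (2 * (r - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        u = tree.add_node()
        tree.add_edge(nodes[i], u, li)
        tree.add_edge(nodes[j], u, lj)
        d[next_key] = {}
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (d[i][k] + d[j][k] - dij)
            d[next_key][k] = duk
            d[k][next_key] = duk
        nodes[next_key] = u
        labels[next_key] = min(labels[i], labels[j])
        active = [k for k in active if k not in (i, j)] + [next_key]
        next_key += 1

    a, b, c = active
    center = tree.add_node()
    la = 0.5 * (d[a][b] + d[a][c] - d[b][c])
    lb = 0.5 * (d[a][b] + d[b][c] - d[a][c])
    lc = 0.5 * (d[a][c] + d[b][c] - d[a][b])
    for node_key, length in ((a, la), (b, lb), (c, lc)):
        tree.add_edge(nodes[node_key], center, max(length, 0.0))
    return tree


def bootstrap_supports(
    aln: ProteinAlignment,
    replicates: int = 1000,
    seed: int = 0,
) -> Tree:
    """NJ tree with bootstrap supports (percent of replicate trees).

    Columns are resampled with replacement to the original alignment
    length; each replicate uses a seed derived from the root seed so
    earlier replicates are unchanged when the replicate count grows.
    """
    if replicates < 1:
        raise ValueError("need at least one bootstrap replicate")
    tree = nj_tree(p_distance_matrix(aln))
    counts: dict[frozenset, int] = {bip: 0 for bip in tree.bipartitions()}
    n_cols = aln.n_cols
    for rep in range(replicates):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(rep,)))
        cols = rng.integers(0, n_cols, size=n_cols)
        rep_aln = aln.subset_columns(cols.tolist())
        try:
            rep_tree = nj_tree(p_distance_matrix(rep_aln))
        except ValueError:  # all-gap resample
            continue
        for bip in rep_tree.bipartitions():
            if bip in counts:
                counts[bip] += 1
    tree.supports = {bip: 100.0 * c / replicates for bip, c in counts.items()}
    return tree


def assign_subgroups(tree: Tree, anchors: Mapping[str, str]) -> dict[str, str]:
    """Label every leaf from anchor taxa via smallest enclosing clades.

    Each unlabeled leaf takes the label of the smallest bipartition side
    containing it and at least one anchor, provided that side's anchors
    are unanimous; otherwise it is 'unclassified'.
    """
    if not anchors:
        raise ValueError("anchor map is empty")
    leaves = set(tree.leaves)
    missing = set(anchors) - leaves
    if missing:
        raise ValueError(f"anchor ids not in tree: {sorted(missing)}")

    sides = []
    seen_edges = set()
    for a in tree.adj:
        for b in tree.adj[a]:
            key = (a, b) if str(a) <= str(b) else (b, a)
            if key in seen_edges:
                continue
            seen_edges.add(key)
            s = tree._side(a, b)
            sides.append(s)
            sides.append(frozenset(leaves - s))

    out: dict[str, str] = {}
    for leaf in sorted(leaves):
        if leaf in anchors:
            out[leaf] = anchors[leaf]
            continue
        candidates = sorted(
            (s for s in sides if leaf in s and any(a in s for a in anchors)),
            key=lambda s: (len(s), tuple(sorted(s))),
        )
        if not candidates:
            out[leaf] = "unclassified"
            continue
        smallest = candidates[0]
        anchor_labels = {anchors[a] for a in anchors if a in smallest}
        out[leaf] = anchor_labels.pop() if len(anchor_labels) == 1 else "unclassified"
    return out
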