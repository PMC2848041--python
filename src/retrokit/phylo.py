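"""Uncorrected distance matrices, neighbor-joining trees and bootstrap.

Subfamily structure only needs coarse clustering, so trees are built by
the Saitou-Nei neighbor-joining algorithm on uncorrected p-distances
(the fraction of differing aligned sites, no multiple-hit correction).
Bootstrap support for the point-estimate tree is the percentage of
column-resampled replicates whose NJ tree contains each bipartition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO
from typing import Sequence

import numpy as np
from skbio import TreeNode

Alignment = Sequence[tuple[str, str]]  # (label, aligned row)

GAP_CHARS = {"-", "."}


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(d), 0):
            raise ValueError("distance matrix diagonal is not zero")
        object.__setattr__(self, "d", d)


@dataclass
class Phylogeny:
    """An unrooted tree (stored with a trifurcating root) plus metadata."""

    tree: TreeNode
    negative_branches_clamped: int = 0
    supports: dict[frozenset, float] = field(default_factory=dict)

    def newick(self) -> str:
        buf = StringIO()
        self.tree.write(buf, format="newick")
        return buf.getvalue().strip()


def distance_matrix(aligned: Alignment) -> DistanceMatrix:
    """Pairwise p-distance over an alignment, ignoring gap columns per pair."""
    if len(aligned) < 2:
        raise ValueError("need at least two aligned sequences")
    labels = tuple(name for name, _ in aligned)
    rows = [row.upper() for _, row in aligned]
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError("ragged alignment: rows differ in length")
    arr = np.array([list(r) for r in rows])
    is_gap = np.isin(arr, list(GAP_CHARS))
    n = len(rows)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            usable = ~(is_gap[i] | is_gap[j])
            total = int(usable.sum())
            if total == 0:
                raise ValueError(
                    f"no comparable columns between {labels[i]!r} and {labels[j]!r}")
            diffs = int((arr[i, usable] != arr[j, usable]).sum())
            d[i, j] = d[j, i] = diffs / total
    return DistanceMatrix(labels, d)


def neighbor_joining(dm: DistanceMatrix) -> Phylogeny:
    """Saitou-Nei agglomeration; deterministic (ties -> smallest (i,j) pair).

    Negative branch length estimates are clamped to zero and counted.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=label) for label in dm.labels]
    d = dm.d.copy()
    active = list(range(n))  # indices into d; order encodes tie-breaking
    clamped = 0

    def blen(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += 1
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                q = (m - 2) * sub[a, b] - r[a] - r[b]
                if best is None or q < best[0] - 1e-12:
                    best = (q, a, b)
        _, a, b = best
        i, j = active[a], active[b]
        li = 0.5 * sub[a, b] + (r[a] - r[b]) / (2 * (m - 2))
        lj = sub[a, b] - li
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = blen(li)
        child_j.length = blen(lj)
        parent = TreeNode(children=[child_i, child_j])
        # distances from the new node to every other active node
        new_row = np.zeros(d.shape[0] + 1)
        for c in range(m):
            k = active[c]
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row[:-1]
        d[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    for idx, length in ((i, li), (j, lj), (k, lk)):
        nodes[idx].length = blen(length)
    root = TreeNode(children=[nodes[i], nodes[j], nodes[k]])
    return Phylogeny(root, negative_branches_clamped=clamped)


def tree_splits(tree: TreeNode) -> set[frozenset]:
    """Non-trivial bipartitions of an unrooted tree, side-normalized.

    Each split is represented by the side *not* containing the
    alphabetically first leaf, so representation is rooting-invariant.
    """
    leaves = {t.name for t in tree.tips()}
    anchor = min(leaves)
    splits = set()
    for node in tree.non_tips(include_self=False):
        clade = frozenset(t.name for t in node.tips())
        side = clade if anchor not in clade else frozenset(leaves - clade)
        if 2 <= len(side) <= len(leaves) - 2:
            splits.add(side)
    return splits


def bootstrap_support(
    aligned: Alignment,
    n_reps: int = 100,
    seed: int | np.random.Generator = 0,
) -> Phylogeny:
    """NJ point tree with bipartition support from column resampling.

    Support values are attached as internal node names (percentages), the
    convention newick consumers expect.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    point = neighbor_joining(distance_matrix(aligned))
    counts = {split: 0 for split in tree_splits(point.tree)}
    labels = [name for name, _ in aligned]
    rows = [row for _, row in aligned]
    ncols = len(rows[0])
    for _ in range(n_reps):
        cols = rng.integers(0, ncols, size=ncols)
        resampled = ["".join(row[c] for c in cols) for row in rows]
        try:
            rep = neighbor_joining(distance_matrix(list(zip(labels, resampled))))
        except ValueError:
            continue  # replicate with no comparable columns for some pair
        rep_splits = tree_splits(rep.tree)
        for split in counts:
            if split in rep_splits:
                counts[split] += 1
    point.supports = {s: 100.0 * c / n_reps for s, c in counts.items()}
    leaves = {t.name for t in point.tree.tips()}
    anchor = min(leaves)
    for node in point.tree.non_tips(include_self=False):
        clade = frozenset(t.name for t in node.tips())
        side = clade if anchor not in clade else frozenset(leaves - clade)
        if side in point.supports:
            node.name = f"{point.supports[side]:g}"
    return point


def matrix_to_phylip(dm: DistanceMatrix) -> str:
    lines = [f" {len(dm.labels)}"]
    for label, row in zip(dm.labels, dm.d):
        lines.append(label + "  " + "  ".join(f"{x:.6f}" for x in row))
    return "\n".join(lines) + "\n"
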