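"""Distance-based phylogenetics at desk scale: pairwise nucleotide distances
(p-distance, JC69, TN93) with pairwise deletion, Saitou-Nei neighbor joining,
column-resampling bootstrap with support-based collapsing, and Newick I/O.

NJ is exact on additive distance matrices: it recovers the generating topology
and branch lengths.  Ties in the Q criterion are broken deterministically by the
lowest index pair, so runs are reproducible.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .seq import SequenceRecord

log = logging.getLogger("cansynth")

_UNAMBIG = frozenset("ACGT")


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray  # symmetric, zero diagonal
    sites_used: np.ndarray  # pairwise retained site counts

    def __post_init__(self) -> None:
        n = len(self.ids)
        assert self.d.shape == (n, n)
        assert np.allclose(self.d, self.d.T)
        assert np.all(np.diag(self.d) == 0)

    def to_frame(self) -> pd.DataFrame:
        """PHYLIP-style square matrix as a DataFrame (TSV-ready)."""
        return pd.DataFrame(self.d, index=self.ids, columns=self.ids)


@dataclass
class TreeNode:
    name: str | None = None
    branch_length: float = 0.0
    support: float | None = None  # percent, internal edges only
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class Tree:
    """Unrooted tree represented with a (usually trifurcating) root node."""

    root: TreeNode
    n_clamped: int = 0  # negative NJ branch estimates clamped to zero

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.root.leaves()]

    def total_branch_length(self) -> float:
        total = 0.0
        stack = list(self.root.children)
        while stack:
            node = stack.pop()
            total += node.branch_length
            stack.extend(node.children)
        return total


class DistanceError(ValueError):
    """A pair has no retained sites or a saturated (log argument <= 0) distance."""


# ---------------------------------------------------------------------------
# pairwise distances
# ---------------------------------------------------------------------------

def assert_colinear(alignment: Sequence[SequenceRecord]) -> int:
    """Check the gap-free stacking assumption; returns the common length."""
    lengths = {len(r.seq) for r in alignment}
    if len(lengths) != 1:
        raise ValueError(f"alignment has unequal lengths {sorted(lengths)}")
    return lengths.pop()


def _pair_distance(a: str, b: str, model: str, pair_label: str) -> tuple[float, int]:
    """Distance and retained-site count for one pair under pairwise deletion."""
    kept = [(x, y) for x, y in zip(a, b) if x in _UNAMBIG and y in _UNAMBIG]
    n = len(kept)
    if n == 0:
        raise DistanceError(f"pair {pair_label}: no sites retained after pairwise deletion")
    diffs = sum(x != y for x, y in kept)
    p = diffs / n
    if model == "p-distance":
        return p, n
    if model == "JC69":
        arg = 1.0 - 4.0 * p / 3.0
        if arg <= 0:
            raise DistanceError(f"pair {pair_label}: JC69 saturated (p = {p:.4f})")
        return -0.75 * math.log(arg), n
    if model == "TN93":
        counts = {base: 0 for base in "ACGT"}
        p1 = p2 = q = 0
        for x, y in kept:
            counts[x] += 1
            counts[y] += 1
            if x != y:
                pair = frozenset((x, y))
                if pair == frozenset("AG"):
                    p1 += 1
                elif pair == frozenset("CT"):
                    p2 += 1
                else:
                    q += 1
        total = 2 * n
        gA, gC, gG, gT = (counts[b] / total for b in "ACGT")
        gR, gY = gA + gG, gC + gT
        if gR == 0 or gY == 0:
            raise DistanceError(f"pair {pair_label}: degenerate base composition for TN93")
        P1, P2, Q = p1 / n, p2 / n, q / n
        k1 = 2.0 * gA * gG / gR
        k2 = 2.0 * gT * gC / gY
        k3 = 2.0 * (gR * gY - gA * gG * gY / gR - gT * gC * gR / gY)
        w1 = 1.0 - P1 / k1 - Q / (2.0 * gR) if k1 > 0 else 1.0
        w2 = 1.0 - P2 / k2 - Q / (2.0 * gY) if k2 > 0 else 1.0
        w3 = 1.0 - Q / (2.0 * gR * gY)
        if (k1 > 0 and w1 <= 0) or (k2 > 0 and w2 <= 0) or w3 <= 0:
            raise DistanceError(f"pair {pair_label}: TN93 saturated")
        d = 0.0
        if k1 > 0:
            d -= k1 * math.log(w1)
        if k2 > 0:
            d -= k2 * math.log(w2)
        d -= k3 * math.log(w3)
        return d, n
    raise ValueError(f"unknown model {model!r}; use p-distance, JC69 or TN93")


def pairwise_distance(
    alignment: Sequence[SequenceRecord], model: str = "TN93"
) -> DistanceMatrix:
    """Pairwise distances with pairwise deletion of gap/ambiguity columns.

    TN93 uses the empirical base frequencies of each pair's retained sites;
    identical sequences have distance zero under every model.
    """
    if len(alignment) < 3:
        raise ValueError("need at least 3 sequences")
    assert_colinear(alignment)
    n = len(alignment)
    d = np.zeros((n, n))
    used = np.zeros((n, n), dtype=int)
    for i in range(n):
        used[i, i] = len(alignment[i].seq)
        for j in range(i + 1, n):
            label = f"({alignment[i].id}, {alignment[j].id})"
            dist, kept = _pair_distance(alignment[i].seq, alignment[j].seq, model, label)
            d[i, j] = d[j, i] = dist
            used[i, j] = used[j, i] = kept
    return DistanceMatrix([r.id for r in alignment], d, used)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(D: DistanceMatrix) -> Tree:
    """Saitou-Nei NJ with the standard Q criterion.

    Deterministic: Q ties are broken by the lowest (i, j) index pair in the
    current node ordering (original input order, then join creation order).
    Negative branch estimates are clamped to zero and counted in
    ``Tree.n_clamped``.
    """
    n = len(D.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=i) for i in D.ids]
    dist = [list(row) for row in D.d.astype(float)]
    clamped = 0

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += 1
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = [sum(dist[i]) for i in range(m)]
        best = None
        best_q = math.inf
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * dist[i][j] - r[i] - r[j]
                if q < best_q - 1e-15:
                    best_q = q
                    best = (i, j)
        i, j = best
        li = dist[i][j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dist[i][j] - li
        child_i, child_j = nodes[i], nodes[j]
        child_i.branch_length = clamp(li)
        child_j.branch_length = clamp(lj)
        new = TreeNode(children=[child_i, child_j])
        new_row = [
            (dist[i][k] + dist[j][k] - dist[i][j]) / 2.0
            for k in range(m) if k not in (i, j)
        ]
        # remove j first (j > i) to keep indices valid
        for idx in (j, i):
            nodes.pop(idx)
            dist.pop(idx)
            for row in dist:
                row.pop(idx)
        nodes.append(new)
        for k in range(len(dist)):
            dist[k].append(new_row[k])
        dist.append(new_row + [0.0])

    # terminal three-node join at an unrooted center
    a, b, c = nodes
    dab, dac, dbc = dist[0][1], dist[0][2], dist[1][2]
    a.branch_length = clamp((dab + dac - dbc) / 2.0)
    b.branch_length = clamp((dab + dbc - dac) / 2.0)
    c.branch_length = clamp((dac + dbc - dab) / 2.0)
    root = TreeNode(children=[a, b, c])
    if clamped:
        log.debug("neighbor_joining: %d negative branch estimate(s) clamped to 0", clamped)
    return Tree(root, n_clamped=clamped)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def _bipartitions(tree: Tree, positive_only: bool = True) -> dict[frozenset, TreeNode]:
    """Map canonical leaf-set bipartition -> internal node (edge below the root).

    Trivial splits (single leaf / all-but-one) are skipped.  With
    ``positive_only`` zero-length internal edges are treated as unresolved and
    not reported — an edge of length zero carries no distance signal.
    """
    all_leaves = frozenset(tree.leaf_names())
    anchor = min(all_leaves)
    out: dict[frozenset, TreeNode] = {}

    def visit(node: TreeNode) -> frozenset:
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset().union(*(visit(c) for c in node.children))
        if node is not tree.root and len(below) >= 2 and len(all_leaves - below) >= 2:
            if not positive_only or node.branch_length > 1e-12:
                side = below if anchor not in below else all_leaves - below
                out[side] = node
        return below

    visit(tree.root)
    return out


def bootstrap_support(
    alignment: Sequence[SequenceRecord],
    n_reps: int = 1000,
    collapse_below: float = 50.0,
    seed: int | None = None,
    model: str = "TN93",
) -> Tree:
    """NJ tree with bootstrap supports; edges below ``collapse_below`` collapsed.

    Columns are resampled with replacement ``n_reps`` times, NJ is rebuilt per
    replicate and each original internal edge is scored by the fraction of
    replicates containing its bipartition.  Zero-length internal edges of the
    base tree are collapsed outright (they are unresolved by the data), which
    turns an alignment of identical sequences into a star tree.  Seeded and
    reproducible.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    length = assert_colinear(alignment)
    rng = np.random.default_rng(seed)
    base = neighbor_joining(pairwise_distance(alignment, model))
    base_bips = _bipartitions(base, positive_only=True)
    counts = {bip: 0 for bip in base_bips}
    seqs = [r.seq for r in alignment]
    for _ in range(n_reps):
        cols = rng.integers(0, length, size=length)
        resampled = [
            SequenceRecord(id=r.id, seq="".join(s[c] for c in cols), role=r.role)
            for r, s in zip(alignment, seqs)
        ]
        rep_tree = neighbor_joining(pairwise_distance(resampled, model))
        rep_bips = _bipartitions(rep_tree, positive_only=True)
        for bip in counts:
            if bip in rep_bips:
                counts[bip] += 1
    for bip, node in base_bips.items():
        node.support = 100.0 * counts[bip] / n_reps
    _collapse(base, collapse_below)
    return base


def _collapse(tree: Tree, collapse_below: float) -> None:
    """Collapse unresolved internal edges into polytomies (in place).

    An internal edge is removed when its length is (numerically) zero or its
    support is below ``collapse_below``.  Children of a removed node are
    spliced into its parent; their own branch lengths are kept.
    """

    def visit(node: TreeNode) -> None:
        new_children: list[TreeNode] = []
        for child in node.children:
            visit(child)
            internal = not child.is_leaf
            unsupported = child.support is not None and child.support < collapse_below
            unresolved = internal and (child.branch_length <= 1e-12 or unsupported)
            if unresolved:
                new_children.extend(child.children)
            else:
                new_children.append(child)
        node.children = new_children

    visit(tree.root)


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def write_newick(tree: Tree) -> str:
    """Newick string with branch lengths (6 significant digits) and supports as
    internal node labels.  Round-trips through :func:`parse_newick`."""

    def fmt(node: TreeNode, is_root: bool) -> str:
        if node.is_leaf:
            body = node.name or ""
        else:
            inner = ",".join(fmt(c, False) for c in node.children)
            label = "" if node.support is None else f"{node.support:.6g}"
            body = f"({inner}){label}"
        if is_root:
            return body + ";"
        return f"{body}:{node.branch_length:.6g}"

    return fmt(tree.root, True)


def parse_newick(s: str) -> Tree:
    """Parse the subset of Newick this package writes (labels, lengths, supports)."""
    s = s.strip()
    if not s.endswith(";"):
        raise ValueError("Newick string must end with ';'")
    text = s[:-1]
    pos = 0

    def parse_node() -> TreeNode:
        nonlocal pos
        node = TreeNode()
        if text[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_node())
                if text[pos] == ",":
                    pos += 1
                    continue
                if text[pos] == ")":
                    pos += 1
                    break
                raise ValueError(f"unexpected character {text[pos]!r} at {pos}")
        start = pos
        while pos < len(text) and text[pos] not in ",();":
            pos += 1
        token = text[start:pos]
        label, _, length = token.partition(":")
        if label:
            if node.children:
                node.support = float(label)
            else:
                node.name = label
        if length:
            node.branch_length = float(length)
        return node

    root = parse_node()
    if pos != len(text):
        raise ValueError(f"trailing characters in Newick string at {pos}")
    return Tree(root)
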