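"""Independent brute-force / closed-form oracles used across the test suite.

These deliberately avoid the package's own code paths: binding sites by an
all-offsets scan, additive matrices by random tree construction plus shortest
paths, tree distances by Dijkstra over the emitted topology.
"""
from __future__ import annotations

import heapq

import numpy as np

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def brute_force_sites(primer: str, template: str, max_mismatch: int, clamp: int):
    """All-offsets mismatch scan for primer sites on both strands."""
    out = []
    m, n = len(primer), len(template)
    rc = revcomp(primer)
    for off in range(n - m + 1):
        window = template[off : off + m]
        mm = sum(p != w for p, w in zip(primer, window))
        if mm <= max_mismatch and primer[m - clamp :] == window[m - clamp :]:
            out.append(("+", off + 1, off + m, mm))
        mm = sum(p != w for p, w in zip(rc, window))
        if mm <= max_mismatch and rc[:clamp] == window[:clamp]:
            out.append(("-", off + 1, off + m, mm))
    out.sort(key=lambda s: (s[1], s[0]))
    return out


def random_additive_matrix(n_leaves: int, rng: np.random.Generator) -> np.ndarray:
    """Distance matrix of path lengths on a random binary tree with random
    positive branch lengths (an additive matrix by construction)."""
    adj: dict[int, dict[int, float]] = {i: {} for i in range(n_leaves)}
    active = list(range(n_leaves))
    next_id = n_leaves
    while len(active) > 1:
        i, j = rng.choice(len(active), 2, replace=False)
        a, b = active[int(i)], active[int(j)]
        new = next_id
        next_id += 1
        adj[new] = {}
        for child in (a, b):
            w = float(rng.uniform(0.05, 1.0))
            adj[new][child] = w
            adj[child][new] = w
        active = [x for x in active if x not in (a, b)] + [new]
    D = np.zeros((n_leaves, n_leaves))
    for s in range(n_leaves):
        dist = _shortest_paths(adj, s)
        for t in range(n_leaves):
            D[s, t] = dist[t]
    return (D + D.T) / 2.0  # exact symmetry despite float path sums


def tree_path_distances(tree) -> dict[tuple[str, str], float]:
    """Leaf-to-leaf path lengths of a cansynth Tree, via Dijkstra."""
    adj: dict[int, dict[int, float]] = {}
    leaf_of: dict[str, int] = {}

    def walk(node, parent_key):
        key = id(node)
        adj.setdefault(key, {})
        if parent_key is not None:
            adj[key][parent_key] = node.branch_length
            adj.setdefault(parent_key, {})[key] = node.branch_length
        if node.is_leaf:
            leaf_of[node.name] = key
        for c in node.children:
            walk(c, key)

    walk(tree.root, None)
    names = sorted(leaf_of)
    out = {}
    for a in names:
        dist = _shortest_paths(adj, leaf_of[a])
        for b in names:
            out[(a, b)] = dist[leaf_of[b]]
    return out


def _shortest_paths(adj, source):
    dist = {source: 0.0}
    heap = [(0.0, source)]
    while heap:
        dv, v = heapq.heappop(heap)
        if dv > dist.get(v, float("inf")):
            continue
        for w, lw in adj[v].items():
            nd = dv + lw
            if w not in dist or nd < dist[w]:
                dist[w] = nd
                heapq.heappush(heap, (nd, w))
    return dist


def mutate_positions(seq: str, positions_alts: list[tuple[int, str]]) -> str:
    s = list(seq)
    for pos, alt in positions_alts:
        s[pos - 1] = alt
    return "".join(s)
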