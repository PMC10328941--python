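"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: trees are re-parsed
with dendropy, UniFrac is recomputed by per-branch enumeration,
Robinson-Foulds by naive double-loop bipartition comparison, and
Procrustes by grid search over rotation angle and scale.
"""

from __future__ import annotations

import itertools

import dendropy
import numpy as np


# ---------------------------------------------------------------------------
# tree parsing helpers (dendropy-based, independent of skbio)
# ---------------------------------------------------------------------------

def _parse(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick")


def _edges_with_tipsets(tree: dendropy.Tree):
    """Yield (branch_length, frozenset of descendant tip labels) for every
    edge below the seed node."""
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        tips = frozenset(lf.taxon.label for lf in node.leaf_iter())
        yield (node.edge.length or 0.0), tips


def brute_unweighted_unifrac(newick: str, present_a: set, present_b: set
                             ) -> float:
    unique = union = 0.0
    for length, tips in _edges_with_tipsets(_parse(newick)):
        in_a = bool(tips & present_a)
        in_b = bool(tips & present_b)
        if in_a or in_b:
            union += length
            if in_a != in_b:
                unique += length
    return unique / union if union > 0 else 0.0


def brute_weighted_unifrac(newick: str, abund_a: dict, abund_b: dict,
                           normalized: bool = False) -> float:
    ta, tb = sum(abund_a.values()), sum(abund_b.values())
    raw = denom = 0.0
    for length, tips in _edges_with_tipsets(_parse(newick)):
        pa = sum(abund_a.get(t, 0) for t in tips) / ta
        pb = sum(abund_b.get(t, 0) for t in tips) / tb
        raw += length * abs(pa - pb)
        denom += length * (pa + pb)
    if normalized:
        return raw / denom if denom > 0 else 0.0
    return raw


# ---------------------------------------------------------------------------
# Robinson-Foulds by naive double loop
# ---------------------------------------------------------------------------

def _splits(newick: str) -> list[frozenset]:
    tree = _parse(newick)
    all_tips = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    n = len(all_tips)
    out = []
    for _, tips in _edges_with_tipsets(tree):
        if 2 <= len(tips) <= n - 2:
            out.append(tips)
    return out, all_tips


def brute_rf(newick1: str, newick2: str) -> int:
    s1, tips = _splits(newick1)
    s2, _ = _splits(newick2)

    def same(a: frozenset, b: frozenset) -> bool:
        return a == b or a == tips - b

    def dedup(splits):
        out = []
        for s in splits:
            if not any(same(s, t) for t in out):
                out.append(s)
        return out

    s1, s2 = dedup(s1), dedup(s2)
    shared = 0
    for a in s1:
        for b in s2:
            if same(a, b):
                shared += 1
                break
    return (len(s1) - shared) + (len(s2) - shared)


# ---------------------------------------------------------------------------
# exhaustive unrooted binary topology enumeration
# ---------------------------------------------------------------------------

def all_topologies(labels: list[str]) -> list[str]:
    """Every unrooted binary topology on `labels` as a newick string,
    built by inserting each leaf into every edge of every partial tree."""
    labels = list(labels)
    assert len(labels) >= 4

    # tree = (edges list of (u,v), leaf map int->label); node 'c' = centre
    base_edges = [("c", 0), ("c", 1), ("c", 2)]
    trees = [(base_edges, 3)]
    for k in range(3, len(labels)):
        nxt = []
        for edges, n_internal in trees:
            for e in range(len(edges)):
                u, v = edges[e]
                w = f"i{k}"
                new = edges[:e] + edges[e + 1:] + [(u, w), (w, v), (w, k)]
                nxt.append((new, n_internal))
        trees = nxt

    out = []
    for edges, _ in trees:
        adj = {}
        for u, v in edges:
            adj.setdefault(u, []).append(v)
            adj.setdefault(v, []).append(u)

        def nwk(parent, node):
            if isinstance(node, int):
                return labels[node]
            parts = [nwk(node, c) for c in adj[node] if c != parent]
            return "(" + ",".join(parts) + ")"

        out.append(nwk(None, "c") + ";")
    return out


# ---------------------------------------------------------------------------
# Procrustes grid-search oracle
# ---------------------------------------------------------------------------

def grid_procrustes_m2(X: np.ndarray, Y: np.ndarray,
                       n_theta: int = 200_000) -> float:
    """min over rotation angle, reflection, and scale of
    ||X - c * Y R||^2 for centered unit-sum-of-squares planar configs."""
    assert X.shape[1] == 2 and Y.shape[1] == 2

    def norm(M):
        M = M - M.mean(axis=0)
        return M / np.sqrt((M ** 2).sum())

    X, Y = norm(X), norm(Y)
    thetas = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    best = np.inf
    for refl in (1.0, -1.0):
        c, s = np.cos(thetas), np.sin(thetas)
        # trace(R^T Y^T X) for R = [[c, -s], [s, c]] @ diag(1, refl)
        A = Y.T @ X
        t = c * (A[0, 0] + refl * A[1, 1]) + s * (A[1, 0] - refl * A[0, 1])
        # optimal scale for fixed rotation: residual = 1 - t^2 (t >= 0)
        tt = np.maximum(t, 0.0)
        best = min(best, float((1.0 - tt ** 2).min()))
    return best


# ---------------------------------------------------------------------------
# random ultrametric distance matrices (UPGMA reconstructs these exactly)
# ---------------------------------------------------------------------------

def random_ultrametric(labels: list[str], rng: np.random.Generator
                       ) -> np.ndarray:
    """Random merge process: distances are twice the height of each
    pair's lowest common merge, so the matrix is ultrametric."""
    n = len(labels)
    d = np.zeros((n, n))
    clusters = [[i] for i in range(n)]
    heights = [0.0] * n
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        h = max(heights[i], heights[j]) + float(rng.exponential(1.0)) + 1e-3
        for a in clusters[i]:
            for b in clusters[j]:
                d[a, b] = d[b, a] = 2 * h
        clusters[i] = clusters[i] + clusters[j]
        heights[i] = h
        del clusters[j], heights[j]
    return d
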