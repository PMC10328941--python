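"""UPGMA dendrograms, Robinson-Foulds congruence, and the random-topology
Monte-Carlo phylosymbiosis test.

Trees are ``skbio.TreeNode`` objects throughout; Robinson-Foulds treats
them as unrooted and ignores branch lengths.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from skbio import DistanceMatrix, TreeNode

__all__ = [
    "upgma",
    "bootstrap_support",
    "bipartitions",
    "robinson_foulds",
    "random_topology",
    "congruence_test",
    "CongruenceResult",
]


def upgma(dm: DistanceMatrix) -> TreeNode:
    """Average-linkage agglomeration of a labeled distance matrix.

    Merge height is half the between-cluster mean distance, so the output
    is ultrametric. Ties are broken by the lexicographically smallest
    pair of cluster-minimum labels, making the result independent of
    input label order.
    """
    labels = list(dm.ids)
    if len(labels) < 2:
        raise ValueError("UPGMA needs at least 2 labels")
    if np.isnan(dm.data).any():
        raise ValueError("distance matrix contains NaN")

    # cluster id -> (node, height, size, min_label)
    clusters: dict[int, tuple[TreeNode, float, int, str]] = {}
    for i, lab in enumerate(labels):
        clusters[i] = (TreeNode(name=lab), 0.0, 1, lab)
    dist: dict[tuple[int, int], float] = {}
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            dist[(i, j)] = float(dm[labels[i], labels[j]])
    next_id = len(labels)

    while len(clusters) > 1:
        best = None
        for (i, j), d in dist.items():
            key = (d, tuple(sorted((clusters[i][3], clusters[j][3]))))
            if best is None or key < best[0]:
                best = (key, i, j)
        (d, _), i, j = best
        ni, hi, si, mi = clusters.pop(i)
        nj, hj, sj, mj = clusters.pop(j)
        height = d / 2.0
        ni.length = height - hi
        nj.length = height - hj
        parent = TreeNode(children=[ni, nj])
        # UPGMA update: size-weighted average of member distances
        newd = {}
        for k in clusters:
            a, b = (min(i, k), max(i, k)), (min(j, k), max(j, k))
            newd[k] = (si * dist[a] + sj * dist[b]) / (si + sj)
        dist = {(a, b): v for (a, b), v in dist.items()
                if i not in (a, b) and j not in (a, b)}
        for k, v in newd.items():
            dist[(min(k, next_id), max(k, next_id))] = v
        clusters[next_id] = (parent, height, si + sj, min(mi, mj))
        next_id += 1

    (root, _, _, _), = clusters.values()
    root.length = None
    return root


def bipartitions(tree: TreeNode) -> frozenset[frozenset[str]]:
    """Non-trivial bipartitions of an (implicitly unrooted) tree.

    Each split is canonicalized as the side not containing the
    lexicographically smallest tip, so rooted and unrooted encodings of
    the same topology produce identical sets.
    """
    tips = frozenset(t.name for t in tree.tips())
    if len(tips) != sum(1 for _ in tree.tips()):
        raise ValueError("duplicate tip labels")
    anchor = min(tips)
    splits = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if anchor in side:
            side = tips - side
        if 2 <= len(side) <= len(tips) - 2:
            splits.add(side)
    return frozenset(splits)


def robinson_foulds(t1: TreeNode, t2: TreeNode) -> tuple[int, float]:
    """Symmetric-difference split distance and its [0, 1] normalization.

    nrf divides by the total split count of both trees (2(n-3) for a
    pair of binary trees); 0 means every bipartition is shared.
    """
    tips1 = frozenset(t.name for t in t1.tips())
    tips2 = frozenset(t.name for t in t2.tips())
    if tips1 != tips2:
        raise ValueError(
            "tip sets differ: only in first=%s only in second=%s"
            % (sorted(tips1 - tips2), sorted(tips2 - tips1))
        )
    if len(tips1) < 4:
        raise ValueError("Robinson-Foulds needs >= 4 tips")
    s1, s2 = bipartitions(t1), bipartitions(t2)
    rf = len(s1 ^ s2)
    denom = len(s1) + len(s2)
    nrf = rf / denom if denom else 0.0
    return rf, nrf


# ---------------------------------------------------------------------------
# uniform random unrooted binary topologies
# ---------------------------------------------------------------------------

def _random_tree_edges(labels: list[str], rng: np.random.Generator
                       ) -> tuple[list[tuple[int, int]], dict[int, str]]:
    """Sequential leaf insertion: leaf k joins one of the 2k-5 edges
    uniformly, which is uniform over unrooted binary labeled topologies.

    Nodes are ints; leaves carry labels via the returned map.
    """
    leaf = {i: lab for i, lab in enumerate(labels)}
    nxt = len(labels)
    centre = nxt
    nxt += 1
    edges = [(centre, 0), (centre, 1), (centre, 2)]
    for k in range(3, len(labels)):
        e = int(rng.integers(len(edges)))
        u, v = edges.pop(e)
        w = nxt
        nxt += 1
        edges.extend([(u, w), (w, v), (w, k)])
    return edges, leaf


def _edges_to_splits(edges, leaf, labels) -> frozenset[frozenset[str]]:
    adj: dict[int, list[int]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    tips = frozenset(labels)
    anchor = min(tips)
    n = len(labels)
    splits = set()
    # tip set below each directed edge, rooted at internal node `n`
    memo: dict[tuple[int, int], frozenset] = {}

    def below(parent: int, child: int) -> frozenset:
        got = memo.get((parent, child))
        if got is not None:
            return got
        if child in leaf:
            out = frozenset((leaf[child],))
        else:
            out = frozenset().union(
                *(below(child, g) for g in adj[child] if g != parent))
        memo[(parent, child)] = out
        return out

    for u, v in edges:
        if u in leaf or v in leaf:
            continue
        side = below(u, v)
        if anchor in side:
            side = tips - side
        if 2 <= len(side) <= n - 2:
            splits.add(side)
    return frozenset(splits)


def random_topology(labels, seed) -> TreeNode:
    """Uniform random unrooted binary topology over `labels`, unit branches."""
    labels = sorted(labels)
    if len(labels) < 4:
        raise ValueError("need >= 4 labels")
    rng = np.random.default_rng(seed)
    edges, leaf = _random_tree_edges(labels, rng)
    adj: dict[int, list[int]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    root = len(labels)  # first internal node: trifurcating unrooted anchor

    def build(parent: int | None, node: int) -> TreeNode:
        if node in leaf:
            return TreeNode(name=leaf[node], length=1.0)
        children = [build(node, c) for c in adj[node] if c != parent]
        return TreeNode(children=children,
                        length=None if parent is None else 1.0)

    return build(None, root)


# ---------------------------------------------------------------------------
# bootstrap support and the Monte-Carlo congruence test
# ---------------------------------------------------------------------------

def bootstrap_support(replicate_trees: list[TreeNode],
                      reference: TreeNode) -> TreeNode:
    """Annotate each internal node of `reference` with the fraction of
    replicates containing the node's bipartition (``.support`` attribute,
    also set as the node name on the returned copy)."""
    if not replicate_trees:
        raise ValueError("need at least one replicate tree")
    ref_tips = frozenset(t.name for t in reference.tips())
    for rep in replicate_trees:
        tips = frozenset(t.name for t in rep.tips())
        if tips != ref_tips:
            raise ValueError(
                "replicate tip set differs from reference: %s vs %s"
                % (sorted(tips ^ ref_tips), sorted(ref_tips)))
    rep_splits = [bipartitions(t) for t in replicate_trees]
    anchor = min(ref_tips)
    out = reference.copy()
    for node in out.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if anchor in side:
            side = ref_tips - side
        if not (2 <= len(side) <= len(ref_tips) - 2):
            node.support = 1.0  # trivial split: present in every tree
        else:
            node.support = sum(side in s for s in rep_splits) / len(rep_splits)
        node.name = f"{node.support:g}"
    return out


@dataclass
class CongruenceResult:
    rf: int
    nrf: float
    p_value: float
    n_random: int
    seed: int
    tail: str
    null_rf_distribution: dict[int, int] = field(default_factory=dict)


def congruence_test(host_tree: TreeNode, dendrogram: TreeNode,
                    n_random: int = 100_000, seed: int = 0,
                    tail: str = "congruent") -> CongruenceResult:
    """Monte-Carlo test of topological congruence against a uniform
    random-topology null.

    Observed = RF(host, dendrogram); null_i = RF(host, random topology on
    the same tips). With ``tail='congruent'`` (default),
    p = (1 + #{null_i <= observed}) / (1 + n_random): small p means the
    dendrogram matches the host tree better than random trees do. The
    ``'paper-literal'`` tail counts null_i >= observed instead.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    if tail not in ("congruent", "paper-literal"):
        raise ValueError("tail must be 'congruent' or 'paper-literal'")
    rf, nrf = robinson_foulds(host_tree, dendrogram)
    labels = sorted(t.name for t in host_tree.tips())
    host_splits = bipartitions(host_tree)
    rng = np.random.default_rng(seed)
    null = Counter()
    hits = 0
    for _ in range(n_random):
        edges, leaf = _random_tree_edges(labels, rng)
        splits = _edges_to_splits(edges, leaf, labels)
        r = len(host_splits ^ splits)
        null[r] += 1
        if (tail == "congruent" and r <= rf) or \
           (tail == "paper-literal" and r >= rf):
            hits += 1
    p = (1 + hits) / (1 + n_random)
    return CongruenceResult(rf=rf, nrf=nrf, p_value=p, n_random=n_random,
                            seed=seed, tail=tail,
                            null_rf_distribution=dict(sorted(null.items())))


def read_newick(path_or_str) -> TreeNode:
    s = str(path_or_str)
    if s.strip().endswith(";") and "(" in s:
        return TreeNode.read(io.StringIO(s))
    return TreeNode.read(s)


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path))
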