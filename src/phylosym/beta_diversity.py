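"""Bray-Curtis and UniFrac distances plus the rarefaction-replicated
distance procedure that feeds dendrogram construction.

All operations return ``skbio.DistanceMatrix`` objects labeled by sample
id. UniFrac variants are computed over an explicit branch incidence
table (each branch paired with its descendant tip set), so semantics are
exactly: a branch contributes only when at least one of its descendant
tips is present in the pair being compared.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .feature_tables import FeatureTable, rarefy

__all__ = [
    "bray_curtis",
    "unweighted_unifrac",
    "weighted_unifrac",
    "beta_rarefaction",
    "write_dm_tsv",
    "read_dm_tsv",
]


def bray_curtis(table: FeatureTable) -> DistanceMatrix:
    """d(x, y) = sum|x_i - y_i| / sum(x_i + y_i); 0 for two empty samples."""
    if len(table.sample_ids) < 2:
        raise ValueError("need >= 2 samples")
    x = table.counts.to_numpy(dtype=float)
    n = x.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(x[i] - x[i + 1:]).sum(axis=1)
        tot = (x[i] + x[i + 1:]).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(tot > 0, diff / np.where(tot > 0, tot, 1.0), 0.0)
        if (tot == 0).any():
            warnings.warn("all-zero sample pair: Bray-Curtis defined as 0")
        out[i, i + 1:] = d
        out[i + 1:, i] = d
    return DistanceMatrix(out, ids=table.sample_ids)


def _branch_table(table: FeatureTable, tree: TreeNode
                  ) -> tuple[np.ndarray, np.ndarray]:
    """(branch x feature) 0/1 incidence and branch lengths.

    One row per tree branch (every non-root node's edge to its parent).
    Trees whose root has more than two children are midpoint-rooted first.
    """
    nonzero = [f for f in table.feature_ids
               if table.counts[f].to_numpy().sum() > 0]
    tip_names = {t.name for t in tree.tips()}
    missing = [f for f in nonzero if f not in tip_names]
    if missing:
        raise ValueError(f"features absent from tree: {missing}")
    if len(tree.children) > 2:
        tree = tree.root_at_midpoint()
    feat_idx = {f: j for j, f in enumerate(table.feature_ids)}
    rows, lengths = [], []
    for node in tree.postorder(include_self=False):
        row = np.zeros(len(feat_idx), dtype=bool)
        for t in node.tips(include_self=True):
            j = feat_idx.get(t.name)
            if j is not None:
                row[j] = True
        rows.append(row)
        lengths.append(node.length or 0.0)
    return np.asarray(rows), np.asarray(lengths, dtype=float)


def unweighted_unifrac(table: FeatureTable, tree: TreeNode) -> DistanceMatrix:
    """Fraction of branch length leading only to tips present in exactly
    one of the two samples, over branch length leading to tips present in
    either. Presence means count > 0."""
    B, lens = _branch_table(table, tree)
    present = table.counts.to_numpy() > 0            # samples x features
    on = present @ B.T > 0                           # samples x branches
    n = len(table.sample_ids)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            either = on[i] | on[j]
            union = lens[either].sum()
            unique = lens[on[i] ^ on[j]].sum()
            out[i, j] = out[j, i] = unique / union if union > 0 else 0.0
    return DistanceMatrix(out, ids=table.sample_ids)


def weighted_unifrac(table: FeatureTable, tree: TreeNode,
                     normalized: bool = False) -> DistanceMatrix:
    """sum_b l_b |p_A(b) - p_B(b)| with p the fraction of a sample's reads
    descending through branch b; optionally normalized by
    sum_b l_b (p_A(b) + p_B(b))."""
    totals = table.sample_totals.to_numpy(dtype=float)
    if (totals == 0).any():
        bad = [s for s, t in zip(table.sample_ids, totals) if t == 0]
        raise ValueError(f"zero-total samples: {bad}")
    B, lens = _branch_table(table, tree)
    props = table.counts.to_numpy() / totals[:, None]
    flow = props @ B.T                               # samples x branches
    n = len(table.sample_ids)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            raw = (lens * np.abs(flow[i] - flow[j])).sum()
            if normalized:
                denom = (lens * (flow[i] + flow[j])).sum()
                raw = raw / denom if denom > 0 else 0.0
            out[i, j] = out[j, i] = raw
    return DistanceMatrix(out, ids=table.sample_ids)


_METRICS = {"braycurtis", "uu", "wu", "wun"}


def _one_metric(table: FeatureTable, metric: str,
                tree: TreeNode | None) -> DistanceMatrix:
    if metric == "braycurtis":
        return bray_curtis(table)
    if tree is None:
        raise ValueError(f"metric {metric!r} needs a tree")
    if metric == "uu":
        return unweighted_unifrac(table, tree)
    if metric == "wu":
        return weighted_unifrac(table, tree, normalized=False)
    if metric == "wun":
        return weighted_unifrac(table, tree, normalized=True)
    raise ValueError(f"unknown metric {metric!r}; choose from {_METRICS}")


def beta_rarefaction(table: FeatureTable, metric: str,
                     tree: TreeNode | None = None, depth: int = 1000,
                     iterations: int = 10, seed: int = 0
                     ) -> tuple[DistanceMatrix, list[DistanceMatrix]]:
    """Rarefy-then-measure `iterations` times (seeds seed, seed+1, ...);
    return the element-wise mean matrix and the per-iteration matrices."""
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    mats = []
    for i in range(iterations):
        sub = rarefy(table, depth, seed + i)
        mats.append(_one_metric(sub, metric, tree))
    ids = mats[0].ids
    mean = np.mean([m.data for m in mats], axis=0)
    return DistanceMatrix(mean, ids=ids), mats


def write_dm_tsv(dm: DistanceMatrix, path) -> None:
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(path, sep="\t")


def read_dm_tsv(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.to_numpy(), ids=list(df.index))
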