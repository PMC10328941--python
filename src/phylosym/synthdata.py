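"""Synthetic inputs for the whole pipeline: host trees, host-tracking
communities with a tunable phylosymbiosis dial, two marker-resolution
views of the same communities, and reference sequences/reads for the
classifier.

The latent model: per feature, the per-host value is
``z = sqrt(s) * BM(host_tree) + sqrt(1 - s) * iid`` with both terms
standardized to unit variance across hosts, so ``signal_s`` is the share
of latent variance explained by Brownian motion on the host phylogeny.
Sample compositions are softmax-linked; read counts are multinomial at a
lognormal depth (defaults put roughly a fifth of samples under 1000
reads, exercising the depth filter downstream).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np
from skbio import TreeNode

from .feature_tables import (
    RANKS,
    FeatureTable,
    TaxonomyMap,
    collapse_taxonomy,
    format_lineage,
    write_table_tsv,
    write_taxonomy_tsv,
)
from .refdb import RefDB, RefRecord

__all__ = [
    "SimConfig",
    "SimOutput",
    "simulate_host_tree",
    "simulate_communities",
    "simulate_references",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    n_hosts: int = 9
    samples_per_host: int = 3
    n_genera: int = 30
    asvs_per_genus: int = 4
    signal_s: float = 0.5
    depth_log_mean: float = 7.75   # ~20% of lognormal depths under 1000
    depth_log_sd: float = 1.0
    seed: int = 0
    # softmax link and replicate-level noise (not dialed by the spec)
    comp_scale: float = 2.0
    sample_noise_sd: float = 0.3

    def __post_init__(self) -> None:
        for name in ("n_hosts", "samples_per_host", "n_genera",
                     "asvs_per_genus"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0.0 <= self.signal_s <= 1.0):
            raise ValueError("signal_s must be in [0, 1]")


@dataclass
class SimOutput:
    host_tree: TreeNode
    table_hires: FeatureTable
    table_lores: FeatureTable
    tree_hires: TreeNode
    tree_lores: TreeNode
    taxonomy: TaxonomyMap
    truth: dict

    def write(self, outdir) -> None:
        import os
        os.makedirs(outdir, exist_ok=True)
        j = os.path.join
        self.host_tree.write(j(outdir, "host_tree.nwk"))
        self.tree_hires.write(j(outdir, "tree_hires.nwk"))
        self.tree_lores.write(j(outdir, "tree_lores.nwk"))
        write_table_tsv(self.table_hires, j(outdir, "table_hires.tsv"))
        write_table_tsv(self.table_lores, j(outdir, "table_lores.tsv"))
        write_taxonomy_tsv(self.taxonomy, j(outdir, "taxonomy.tsv"))
        truth = dict(self.truth)
        truth["latent"] = np.asarray(truth["latent"]).tolist()
        with open(j(outdir, "truth.json"), "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)


def _yule(labels: list[str], rng: np.random.Generator,
          rate: float = 1.0) -> TreeNode:
    """Seeded pure-birth tree with a strict clock: ultrametric, binary,
    strictly positive branch lengths."""
    n = len(labels)
    t = 0.0
    active: list[tuple[TreeNode, float]] = []
    root = TreeNode()
    for _ in range(2):
        child = TreeNode()
        root.append(child)
        active.append((child, 0.0))
    while len(active) < n:
        t += rng.exponential(1.0 / (rate * len(active)))
        i = int(rng.integers(len(active)))
        node, birth = active.pop(i)
        node.length = t - birth
        for _ in range(2):
            child = TreeNode()
            node.append(child)
            active.append((child, t))
    t_end = t + rng.exponential(1.0 / (rate * n))
    order = rng.permutation(n)
    for (node, birth), k in zip(active, order):
        node.name = labels[int(k)]
        node.length = t_end - birth
    return root


def simulate_host_tree(n_hosts: int, seed: int) -> TreeNode:
    """Rooted binary ultrametric pure-birth tree with tips host01..hostNN."""
    if n_hosts < 3:
        raise ValueError("n_hosts must be >= 3")
    labels = [f"host{i + 1:02d}" for i in range(n_hosts)]
    return _yule(labels, np.random.default_rng(seed))


def _brownian_tips(tree: TreeNode, n_features: int, hosts: list[str],
                   rng: np.random.Generator) -> np.ndarray:
    """(features x hosts) Brownian-motion tip values, root at zero."""
    vals: dict[int, np.ndarray] = {id(tree): np.zeros(n_features)}
    out = np.zeros((n_features, len(hosts)))
    pos = {h: i for i, h in enumerate(hosts)}
    for node in tree.preorder(include_self=False):
        step = rng.normal(size=n_features) * math.sqrt(node.length or 0.0)
        v = vals[id(node.parent)] + step
        if node.is_tip():
            out[:, pos[node.name]] = v
        else:
            vals[id(node)] = v
    return out


def _standardize(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def simulate_communities(host_tree: TreeNode, cfg: SimConfig,
                         hosts: list[str] | None = None) -> SimOutput:
    """Simulate replicate samples per host whose composition tracks the
    host phylogeny with strength ``cfg.signal_s``, in an ASV-resolved
    (hires) view and an exactly genus-merged (lores) view."""
    tip_names = sorted(t.name for t in host_tree.tips())
    if hosts is not None and sorted(hosts) != tip_names:
        raise ValueError(
            "host labels do not match tree tips: tree=%s given=%s"
            % (tip_names, sorted(hosts)))
    hosts = tip_names
    if len(hosts) < 3:
        raise ValueError("host tree must have >= 3 tips")

    rng = np.random.default_rng(cfg.seed)
    G, A = cfg.n_genera, cfg.asvs_per_genus
    genera = [f"g{i + 1:02d}" for i in range(G)]
    feature_ids = [f"{g}_a{j + 1}" for g in genera for j in range(A)]
    n_feat = G * A

    # genus backbone tree; hires expands each genus tip into its ASVs
    tree_lores = _yule(genera, rng)
    tree_hires = tree_lores.copy()
    for tip in list(tree_hires.tips()):
        g = tip.name
        tip.name = None
        for j in range(A):
            tip.append(TreeNode(name=f"{g}_a{j + 1}", length=0.05))

    lineages = {}
    for gi, g in enumerate(genera):
        fam = "fam1" if gi < (G + 1) // 2 else "fam2"
        for j in range(A):
            lineages[f"{g}_a{j + 1}"] = (
                "Bacteria", "SimPhylum", "SimClass", "SimOrder",
                fam, g, f"{g}_a{j + 1}")
    taxonomy = TaxonomyMap(lineages)

    s = cfg.signal_s
    bm = _standardize(_brownian_tips(host_tree, n_feat, hosts, rng))
    iid = _standardize(rng.normal(size=(n_feat, len(hosts))))
    z = math.sqrt(s) * bm + math.sqrt(1.0 - s) * iid

    sample_ids, counts, meta = [], [], {}
    for hi, h in enumerate(hosts):
        for r in range(cfg.samples_per_host):
            sid = f"{h}.r{r + 1}"
            logits = cfg.comp_scale * z[:, hi]
            if cfg.sample_noise_sd > 0:
                logits = logits + rng.normal(0, cfg.sample_noise_sd, n_feat)
            p = np.exp(logits - logits.max())
            p /= p.sum()
            depth = max(1, int(round(
                rng.lognormal(cfg.depth_log_mean, cfg.depth_log_sd))))
            counts.append(rng.multinomial(depth, p))
            sample_ids.append(sid)
            meta[sid] = h

    import pandas as pd
    table_hires = FeatureTable(
        pd.DataFrame(np.asarray(counts, dtype=np.int64),
                     index=sample_ids, columns=feature_ids),
        meta, [{"op": "simulate_communities", "config": asdict(cfg)}])

    # exact genus merge, then short genus names matching the lores tree tips
    merged = collapse_taxonomy(table_hires, taxonomy, "genus")
    prefix_to_genus = {
        format_lineage(lineages[f"{g}_a1"], 6): g for g in genera}
    lores_counts = merged.counts.rename(columns=prefix_to_genus)
    table_lores = FeatureTable(lores_counts, meta, merged.provenance)

    for g in genera:
        lineages_g = lineages[f"{g}_a1"]
        taxonomy.lineages[g] = lineages_g[:6] + ("",)

    truth = {
        "signal_s": s,
        "hosts": hosts,
        "feature_ids": feature_ids,
        "latent": z,
    }
    return SimOutput(host_tree=host_tree, table_hires=table_hires,
                     table_lores=table_lores, tree_hires=tree_hires,
                     tree_lores=tree_lores, taxonomy=taxonomy, truth=truth)


# ---------------------------------------------------------------------------
# reference sequences and labeled reads for the classifier
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RefLevel:
    rank: str          # one of the 7 canonical ranks
    n_children: int
    n_substitutions: int


DEFAULT_LEVELS = (
    RefLevel("phylum", 2, 80),
    RefLevel("family", 2, 40),
    RefLevel("genus", 3, 20),
    RefLevel("species", 3, 6),
)


def _mutate(seq: np.ndarray, n_subs: int, rng: np.random.Generator
            ) -> np.ndarray:
    out = seq.copy()
    if n_subs == 0:
        return out
    pos = rng.choice(len(seq), size=min(n_subs, len(seq)), replace=False)
    for p in pos:
        choices = [b for b in "ACGT" if b != out[p]]
        out[p] = choices[int(rng.integers(3))]
    return out


def simulate_references(levels=DEFAULT_LEVELS, seq_len: int = 600,
                        read_len: int = 200, reads_per_leaf: int = 10,
                        error_rate: float = 0.01, seed: int = 0
                        ) -> tuple[RefDB, list[tuple[str, str, tuple]]]:
    """Evolve a root sequence down a ranked taxonomy tree with per-level
    substitution budgets; emit leaf reference sequences and read windows
    with iid substitution errors, each read tagged with its true lineage.
    """
    if not (0.0 <= error_rate < 0.25):
        raise ValueError("error_rate must be in [0, 0.25)")
    if read_len > seq_len:
        raise ValueError("read_len exceeds reference length")
    levels = [lv if isinstance(lv, RefLevel) else RefLevel(*lv)
              for lv in levels]
    rank_pos = {lv.rank: RANKS.index(lv.rank) for lv in levels}
    if sorted(rank_pos.values()) != [rank_pos[lv.rank] for lv in levels]:
        raise ValueError("levels must be ordered shallow to deep")

    rng = np.random.default_rng(seed)
    root_seq = _BASES[rng.integers(4, size=seq_len)]

    records: list[RefRecord] = []

    def descend(depth: int, seq: np.ndarray, names: list[str]) -> None:
        if depth == len(levels):
            lineage = ["Bacteria"] + [""] * (len(RANKS) - 1)
            last = "Bacteria"
            li = 0
            for lv, nm in zip(levels, names):
                pos = rank_pos[lv.rank]
                for fill in range(li + 1, pos):
                    lineage[fill] = last
                lineage[pos] = nm
                last, li = nm, pos
            rid = names[-1]
            records.append(RefRecord(rid, "".join(seq), tuple(lineage)))
            return
        lv = levels[depth]
        for c in range(lv.n_children):
            child_seq = _mutate(seq, lv.n_substitutions, rng)
            nm = (names[-1] if names else lv.rank[0]) + f".{c + 1}" \
                if names else f"{lv.rank[0]}{c + 1}"
            descend(depth + 1, child_seq, names + [nm])

    descend(0, root_seq, [])
    db = RefDB(records, {"collected": len(records), "removed_duplicate": 0,
                         "removed_short": 0, "removed": 0,
                         "remaining": len(records), "merged_in": 0,
                         "final": len(records)})

    reads = []
    for rec in records:
        seq = np.array(list(rec.seq))
        for j in range(reads_per_leaf):
            start = int(rng.integers(0, seq_len - read_len + 1))
            window = seq[start:start + read_len].copy()
            if error_rate > 0:
                errs = np.nonzero(rng.random(read_len) < error_rate)[0]
                for p in errs:
                    choices = [b for b in "ACGT" if b != window[p]]
                    window[p] = choices[int(rng.integers(3))]
            reads.append((f"{rec.id}_read{j + 1}", "".join(window),
                          rec.lineage))
    return db, reads
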