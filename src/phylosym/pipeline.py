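"""End-to-end phylosymbiosis workflow: filter, host-collapse,
rarefaction-replicated beta diversity, UPGMA with bootstrap support,
random-topology congruence tests, and cross-marker PCoA/PROTEST."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

import pandas as pd

from . import beta_diversity as bd
from . import ordination as ordn
from . import tree_congruence as tc
from .feature_tables import (
    FeatureTable,
    collapse_by_group,
    filter_samples_min_depth,
    rarefy,
    read_table_tsv,
    write_table_tsv,
)
from .synthdata import SimConfig, simulate_communities, simulate_host_tree

METRICS = ("braycurtis", "uu", "wu")

__all__ = ["PipelineConfig", "run_phylosymbiosis", "demo_config"]


@dataclass
class PipelineConfig:
    """Paths plus parameters; every parameter defaults to the value the
    workflow is normally run with (1000-read filter and depth, 1000
    rarefaction/bootstrap replicates, 100,000 random trees and
    permutations)."""

    # either simulate=... or the four paths below
    simulate: dict | None = None
    table_hires: str | None = None
    table_lores: str | None = None
    tree_hires: str | None = None
    tree_lores: str | None = None
    host_tree: str | None = None
    sample_hosts: dict[str, str] = field(default_factory=dict)

    min_reads: int = 1000
    depth: int = 1000
    iterations: int = 1000
    n_random: int = 100_000
    n_permutations: int = 100_000
    abundance_thresholds: tuple[float, float] = (0.03, 0.05)
    tail: str = "congruent"
    seed: int = 0

    def resolved(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.resolved(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = json.load(fh)
        names = {f.name for f in dataclasses.fields(cls)}
        d = {k: v for k, v in d.items() if k in names}
        if "abundance_thresholds" in d:
            d["abundance_thresholds"] = tuple(d["abundance_thresholds"])
        return cls(**d)


def demo_config(signal_s: float = 1.0, seed: int = 0) -> PipelineConfig:
    """Desk-scale synthetic profile: full paper defaults would spend
    minutes on Monte-Carlo loops, so the demo scales the replicate
    counts down while keeping the filter/depth semantics."""
    return PipelineConfig(
        simulate={"n_hosts": 9, "samples_per_host": 3, "n_genera": 30,
                  "asvs_per_genus": 4, "signal_s": signal_s,
                  "depth_log_mean": 9.2, "depth_log_sd": 0.4, "seed": seed,
                  "comp_scale": 4.0},
        depth=5000, iterations=20, n_random=1000, n_permutations=999,
        seed=seed,
    )


def _load_inputs(cfg: PipelineConfig):
    if cfg.simulate is not None:
        sim_cfg = SimConfig(**cfg.simulate)
        host_tree = simulate_host_tree(sim_cfg.n_hosts, sim_cfg.seed)
        sim = simulate_communities(host_tree, sim_cfg)
        views = {"hires": (sim.table_hires, sim.tree_hires),
                 "lores": (sim.table_lores, sim.tree_lores)}
        return host_tree, views
    host_tree = tc.read_newick(cfg.host_tree)
    views = {}
    for name, tpath, wpath in (("hires", cfg.table_hires, cfg.tree_hires),
                               ("lores", cfg.table_lores, cfg.tree_lores)):
        if tpath is None:
            continue
        table = read_table_tsv(tpath, sample_meta=cfg.sample_hosts)
        tree = tc.read_newick(wpath) if wpath else None
        views[name] = (table, tree)
    if not views:
        raise ValueError("no input tables: set simulate= or table paths")
    return host_tree, views


def run_phylosymbiosis(cfg: PipelineConfig, outdir) -> dict:
    """Execute the full workflow and write a JSON + TSV report plus all
    intermediate artifacts (filtered tables, distance matrices,
    dendrograms with support) under `outdir`."""
    os.makedirs(outdir, exist_ok=True)
    host_tree, views = _load_inputs(cfg)
    chash = cfg.config_hash()
    report: dict = {"config_hash": chash, "config": cfg.resolved(),
                    "views": {}}

    filtered = {}
    for name, (table, tree) in views.items():
        try:
            ft = filter_samples_min_depth(table, cfg.min_reads)
        except Exception as exc:  # pragma: no cover - stage labeling
            raise RuntimeError(f"stage filter[{name}]: {exc}") from exc
        filtered[name] = (ft, tree)
        write_table_tsv(ft, os.path.join(outdir, f"{name}.filtered.tsv"))

    rows = []
    for name, (ft, tree) in filtered.items():
        collapsed = collapse_by_group(ft)
        view_rep = {}
        for metric in METRICS:
            mtree = tree if metric != "braycurtis" else None
            mean_dm, reps = bd.beta_rarefaction(
                collapsed, metric, tree=mtree, depth=cfg.depth,
                iterations=cfg.iterations, seed=cfg.seed)
            dendro = tc.upgma(mean_dm)
            supported = tc.bootstrap_support(
                [tc.upgma(m) for m in reps], dendro)
            res = tc.congruence_test(host_tree, dendro,
                                     n_random=cfg.n_random, seed=cfg.seed,
                                     tail=cfg.tail)
            bd.write_dm_tsv(mean_dm, os.path.join(
                outdir, f"{name}.{metric}.dm.tsv"))
            supported.write(os.path.join(
                outdir, f"{name}.{metric}.dendrogram.nwk"))
            view_rep[metric] = {"rf": res.rf, "nrf": res.nrf,
                                "p_value": res.p_value,
                                "n_random": res.n_random}
            rows.append({"view": name, "metric": metric, "rf": res.rf,
                         "nrf": res.nrf, "p_value": res.p_value})
        report["views"][name] = view_rep

    # cross-marker concordance on sample-level ordinations
    if len(filtered) == 2:
        report["procrustes"] = {}
        (n1, (t1, w1)), (n2, (t2, w2)) = filtered.items()
        shared = sorted(set(t1.sample_ids) & set(t2.sample_ids))
        for metric in METRICS:
            r1 = rarefy(t1, cfg.depth, cfg.seed)
            r2 = rarefy(t2, cfg.depth, cfg.seed)
            keep = sorted(set(r1.sample_ids) & set(r2.sample_ids)
                          & set(shared))
            r1 = FeatureTable(r1.counts.loc[keep], r1.sample_meta)
            r2 = FeatureTable(r2.counts.loc[keep], r2.sample_meta)
            d1 = bd._one_metric(r1, metric, w1 if metric != "braycurtis"
                                else None)
            d2 = bd._one_metric(r2, metric, w2 if metric != "braycurtis"
                                else None)
            try:
                res = ordn.protest(ordn.pcoa(d1), ordn.pcoa(d2),
                                   n_permutations=cfg.n_permutations,
                                   seed=cfg.seed)
            except ValueError as exc:
                # e.g. a saturated presence/absence metric yields an
                # all-zero matrix with no ordination: report, don't abort
                report["procrustes"][metric] = {"error": str(exc)}
                rows.append({"view": f"{n1}-vs-{n2}", "metric": metric,
                             "r": float("nan"), "p_value": float("nan")})
                continue
            report["procrustes"][metric] = {
                "m2": res.m2, "r": res.r, "p_value": res.p_value,
                "n_permutations": res.n_permutations}
            rows.append({"view": f"{n1}-vs-{n2}", "metric": metric,
                         "r": res.r, "p_value": res.p_value})

    with open(os.path.join(outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    pd.DataFrame(rows).to_csv(os.path.join(outdir, "report.tsv"),
                              sep="\t", index=False)
    with open(os.path.join(outdir, "config.resolved.json"), "w") as fh:
        json.dump({"hash": chash, **cfg.resolved()}, fh, indent=1,
                  sort_keys=True, default=str)
    return report
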