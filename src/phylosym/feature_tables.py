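"""Feature-table transformations between ASV inference and diversity analysis.

A :class:`FeatureTable` is a samples x features matrix of non-negative
integer read counts plus per-sample metadata (host label) and an audit
trail of every transformation applied to it.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")
LINEAGE_SEP = "; "

__all__ = [
    "RANKS",
    "FeatureTable",
    "TaxonomyMap",
    "parse_lineage",
    "format_lineage",
    "filter_samples_min_depth",
    "collapse_by_group",
    "rarefy",
    "collapse_taxonomy",
    "relative_abundance_filter",
    "subset_by_taxon",
    "read_table_tsv",
    "write_table_tsv",
    "read_taxonomy_tsv",
    "write_taxonomy_tsv",
]


def parse_lineage(s: str) -> tuple[str, ...]:
    """Parse a 'k__X; p__Y; ...' string into a 7-tuple of rank names.

    Missing trailing ranks and empty prefixed fields become ''.
    """
    parts = [p.strip() for p in s.split(";")] if s else []
    out = []
    for i in range(len(RANKS)):
        name = ""
        if i < len(parts):
            tok = parts[i]
            if tok.startswith(RANK_PREFIXES[i]):
                tok = tok[len(RANK_PREFIXES[i]):]
            name = tok
        out.append(name)
    return tuple(out)


def format_lineage(lineage: Iterable[str], depth: int = 7) -> str:
    names = list(lineage)
    return LINEAGE_SEP.join(
        RANK_PREFIXES[i] + names[i] for i in range(depth)
    )


@dataclass
class TaxonomyMap:
    """feature_id -> ranked 7-level lineage; '' marks an unresolved rank."""

    lineages: dict[str, tuple[str, ...]]
    #: feature ids where a resolved rank sits below an unresolved one
    gapped: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        fixed = {}
        gapped = []
        for fid, lin in self.lineages.items():
            lin = tuple(lin)
            if len(lin) != len(RANKS):
                raise ValueError(
                    f"lineage for {fid!r} has {len(lin)} ranks, expected {len(RANKS)}"
                )
            seen_gap = False
            for name in lin:
                if name == "":
                    seen_gap = True
                elif seen_gap:
                    gapped.append(fid)
                    break
            fixed[fid] = lin
        self.lineages = fixed
        self.gapped = gapped

    def __getitem__(self, fid: str) -> tuple[str, ...]:
        return self.lineages[fid]

    def __contains__(self, fid: str) -> bool:
        return fid in self.lineages

    def prefix(self, fid: str, rank: str) -> str:
        """Lineage-prefix string through `rank` (positional, verbatim names)."""
        depth = RANKS.index(rank) + 1
        return format_lineage(self.lineages[fid], depth)


@dataclass
class FeatureTable:
    """Samples x features integer count matrix with host metadata.

    ``counts`` is a pandas DataFrame indexed by sample id with feature-id
    columns. Every transformation appends a provenance record.
    """

    counts: pd.DataFrame
    sample_meta: dict[str, str] = field(default_factory=dict)
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        if df.columns.has_duplicates:
            raise ValueError("duplicate feature ids")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integers")
            df = df.astype(np.int64)
        if (df.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = df.astype(np.int64)

    # -- convenience accessors -------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def _derive(self, counts: pd.DataFrame, record: dict,
                sample_meta: Mapping[str, str] | None = None) -> "FeatureTable":
        meta = dict(self.sample_meta if sample_meta is None else sample_meta)
        meta = {s: meta[s] for s in counts.index if s in meta}
        return FeatureTable(counts, meta, self.provenance + [record])


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def filter_samples_min_depth(table: FeatureTable, min_reads: int = 1000,
                             drop_empty: bool = False) -> FeatureTable:
    """Remove samples with fewer than `min_reads` total reads.

    A sample with exactly `min_reads` reads is kept. All-zero feature
    columns are retained unless ``drop_empty``.
    """
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    totals = table.sample_totals
    keep = totals >= min_reads
    out = table.counts.loc[keep]
    if drop_empty:
        out = out.loc[:, out.sum(axis=0) > 0]
    grand = int(totals.sum())
    retained = int(totals[keep].sum())
    pct = round_half_up(100.0 * retained / grand, 1) if grand else 0.0
    record = {
        "op": "filter_samples_min_depth",
        "min_reads": int(min_reads),
        "drop_empty": bool(drop_empty),
        "samples_in": int(len(totals)),
        "samples_kept": int(keep.sum()),
        "total_reads": grand,
        "retained_reads": retained,
        "retained_percent": pct,
    }
    if keep.sum() == 0:
        warnings.warn("filter_samples_min_depth removed every sample")
    return table._derive(out, record)


def collapse_by_group(table: FeatureTable,
                      group: Mapping[str, str] | None = None) -> FeatureTable:
    """Sum counts of all samples sharing a group label (e.g. one host).

    ``group`` defaults to the table's sample metadata. Output has one
    sample per label; the grand total is conserved.
    """
    if group is None:
        group = table.sample_meta
    missing = [s for s in table.sample_ids if s not in group]
    if missing:
        raise ValueError(f"samples without a group label: {missing}")
    labels = pd.Series({s: group[s] for s in table.sample_ids})
    out = table.counts.groupby(labels).sum()
    out = out.loc[sorted(out.index)]
    out.index.name = None
    record = {"op": "collapse_by_group", "groups": int(len(out))}
    meta = {g: g for g in out.index}
    return table._derive(out, record, sample_meta=meta)


def rarefy(table: FeatureTable, depth: int, seed: int) -> FeatureTable:
    """Subsample each sample to exactly `depth` reads without replacement.

    Samples with fewer than `depth` total reads are dropped (warned if
    that empties the table). Seeded and reproducible.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = table.sample_totals
    keep = totals >= depth
    kept = table.counts.loc[keep]
    rows = []
    for _, row in kept.iterrows():
        counts = row.to_numpy()
        if counts.sum() == depth:
            rows.append(counts)
        else:
            rows.append(rng.multivariate_hypergeometric(counts, depth))
    out = pd.DataFrame(
        np.asarray(rows, dtype=np.int64).reshape(len(rows), kept.shape[1]),
        index=kept.index, columns=kept.columns,
    )
    if not len(out):
        warnings.warn("rarefy dropped every sample")
    record = {
        "op": "rarefy", "depth": int(depth), "seed": int(seed),
        "samples_dropped": int((~keep).sum()),
    }
    return table._derive(out, record)


def collapse_taxonomy(table: FeatureTable, taxonomy: TaxonomyMap,
                      rank: str) -> FeatureTable:
    """Sum features sharing an identical lineage-prefix through `rank`.

    Prefix strings are compared verbatim: lineages differing by any
    character (a trailing digit, say) stay distinct. Features missing
    from the taxonomy fall into an 'Unassigned' bucket.
    """
    if rank not in RANKS:
        raise ValueError(f"rank must be one of {RANKS}")
    unassigned = []
    groups: dict[str, list[str]] = {}
    for fid in table.feature_ids:
        if fid in taxonomy:
            key = taxonomy.prefix(fid, rank)
        else:
            key = "Unassigned"
            unassigned.append(fid)
        groups.setdefault(key, []).append(fid)
    data = {key: table.counts[fids].sum(axis=1) for key, fids in groups.items()}
    out = pd.DataFrame(data, index=table.counts.index)
    record = {
        "op": "collapse_taxonomy", "rank": rank,
        "features_in": len(table.feature_ids), "features_out": out.shape[1],
        "unassigned_features": unassigned,
    }
    return table._derive(out, record)


def relative_abundance_filter(table: FeatureTable, threshold: float
                              ) -> tuple[FeatureTable, pd.DataFrame]:
    """Per-sample display mask of features with relative abundance > threshold.

    The inequality is strict; counts are preserved, only the boolean
    mask marks what passes.
    """
    if not (0 <= threshold < 1):
        raise ValueError("threshold must be in [0, 1)")
    totals = table.sample_totals.to_numpy()[:, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(totals > 0, table.counts.to_numpy() / totals, 0.0)
    mask = pd.DataFrame(rel > threshold, index=table.counts.index,
                        columns=table.counts.columns)
    record = {"op": "relative_abundance_filter", "threshold": float(threshold),
              "cells_passing": int(mask.to_numpy().sum())}
    return table._derive(table.counts, record), mask


def subset_by_taxon(table: FeatureTable, taxonomy: TaxonomyMap,
                    taxon: str) -> tuple[FeatureTable, pd.DataFrame]:
    """Subset to features under a lineage prefix; within-subset abundances.

    Returns the subset table (samples with zero subset reads dropped and
    logged) and a DataFrame of within-subset relative abundances whose
    denominator is the SUBSET total per sample. The provenance record
    additionally reports each sample's subset-total / sample-total
    proportion as a percentage rounded to one decimal.
    """
    hits = []
    for fid in table.feature_ids:
        if fid not in taxonomy:
            continue
        full = format_lineage(taxonomy[fid])
        if full.startswith(taxon):
            hits.append(fid)
    if not hits:
        raise ValueError(f"no feature matches lineage prefix {taxon!r}")
    sub = table.counts[hits]
    sub_totals = sub.sum(axis=1)
    sample_totals = table.sample_totals
    proportions = {
        s: round_half_up(100.0 * sub_totals[s] / sample_totals[s], 1)
        if sample_totals[s] else 0.0
        for s in table.sample_ids
    }
    keep = sub_totals > 0
    dropped = list(sub.index[~keep])
    sub = sub.loc[keep]
    rel = sub.div(sub.sum(axis=1), axis=0)
    record = {
        "op": "subset_by_taxon", "taxon": taxon, "features": hits,
        "subset_percent_of_sample": proportions,
        "samples_dropped_zero_subset": dropped,
    }
    return table._derive(sub, record), rel


def round_half_up(x: float, ndigits: int) -> float:
    """Round with ties away from zero, as printed summaries conventionally do."""
    scale = 10 ** ndigits
    return math.floor(abs(x) * scale + 0.5) / scale * (1 if x >= 0 else -1)


# ---------------------------------------------------------------------------
# TSV / sidecar IO (features as rows, samples as columns)
# ---------------------------------------------------------------------------

def write_table_tsv(table: FeatureTable, path, provenance_sidecar: bool = True
                    ) -> None:
    df = table.counts.T
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t")
    if provenance_sidecar:
        side = str(path) + ".provenance.json"
        with open(side, "w") as fh:
            json.dump({"provenance": table.provenance,
                       "sample_meta": table.sample_meta}, fh, indent=1)


def read_table_tsv(path, sample_meta: Mapping[str, str] | None = None
                   ) -> FeatureTable:
    df = pd.read_csv(path, sep="\t", index_col=0).T
    df.index.name = None
    df.columns.name = None
    return FeatureTable(df, dict(sample_meta or {}))


def write_taxonomy_tsv(taxonomy: TaxonomyMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("feature_id\tlineage\n")
        for fid, lin in taxonomy.lineages.items():
            fh.write(f"{fid}\t{format_lineage(lin)}\n")


def read_taxonomy_tsv(path) -> TaxonomyMap:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return TaxonomyMap({row.iloc[0]: parse_lineage(row.iloc[1])
                        for _, row in df.iterrows()})
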