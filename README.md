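# phylosym

A tested, reusable pipeline for comparing marker-gene microbiome profiles
and detecting phylosymbiosis — the pattern in which microbial community
dissimilarity among hosts mirrors host phylogenetic relatedness.

The package covers the full computational workflow downstream of ASV
inference:

- **`phylosym.synthdata`** — synthetic inputs for every stage: seeded
  pure-birth host trees; per-host replicate communities whose latent
  composition tracks the host phylogeny with a tunable strength dial
  (`signal_s`, the share of latent variance explained by Brownian motion
  on the host tree); two marker "views" of the same communities
  (ASV-resolved vs exactly genus-merged); and reference sequences plus
  error-bearing reads with known lineages for the classifier.
- **`phylosym.feature_tables`** — minimum-depth sample filtering
  (boundary kept at equality), host-collapsing with summed counts,
  seeded rarefaction without replacement, taxonomy collapsing with
  verbatim lineage-prefix matching, strict relative-abundance display
  masks, and lineage-subset profiling. Every transformation appends to a
  provenance audit trail.
- **`phylosym.beta_diversity`** — Bray-Curtis, unweighted UniFrac, and
  weighted UniFrac (raw by default, normalized behind a flag), plus the
  rarefaction-replicated distance procedure whose per-iteration matrices
  feed dendrogram bootstrap support.
- **`phylosym.tree_congruence`** — UPGMA with deterministic
  tie-breaking, bipartition-based bootstrap support, unrooted
  Robinson-Foulds distance with its [0, 1] normalization, uniform random
  unrooted binary topologies, and the Monte-Carlo congruence test with
  add-one p-values (small p: the community dendrogram matches the host
  tree better than random topologies do).
- **`phylosym.ordination`** — PCoA (Gower double-centering; negative
  eigenvalues dropped and logged), symmetric Procrustes with reflections
  allowed, and PROTEST row-permutation significance.
- **`phylosym.refdb`** — reference-set curation (exact-duplicate and
  length filtering with provenance arithmetic, merge without cross-set
  deduplication), lineage harmonization (digit-strip and explicit
  synonym tables), and an RDP-style naive-Bayes k-mer classifier with
  bootstrap confidence and rank-truncated output lineages.
- **`phylosym.pipeline` / `phylosym.cli`** — orchestration of the whole
  workflow with a resolved-config snapshot and hash on every run.

## CLI

All stochastic subcommands require `--seed`. A one-command synthetic
end-to-end demo:

```sh
phylosym run-all --seed 1 --signal 1.0 --out out/demo
```

writes filtered tables, distance matrices, support-annotated
dendrograms, and a JSON + TSV report (normalized Robinson-Foulds score
and congruence p per metric and marker view; Procrustes r and p between
views). Individual stages:

```sh
phylosym simulate  --seed 1 --out out/sim
phylosym tables    --table out/sim/table_hires.tsv --min-reads 1000 --out out/filtered.tsv
phylosym beta      --table out/filtered.tsv --metric uu --tree out/sim/tree_hires.nwk \
                   --depth 1000 --iterations 10 --seed 1 --out out/uu.tsv
phylosym dendro    --dm out/uu.tsv --out out/uu.nwk
phylosym phylosym  --host out/sim/host_tree.nwk --dendro out/uu.nwk --n-random 100000 --seed 1
phylosym curate-db --fasta refs.fasta --taxonomy tax.tsv --out curated.fasta
phylosym train     --fasta curated.fasta --taxonomy tax.tsv --out model.json
phylosym classify  --model model.json --reads reads.fasta --seed 1 --out assignments.tsv
phylosym procrustes --ord1 a.tsv --ord2 b.tsv --n-perm 100000 --seed 1
```

Feature tables are TSV (features as rows, samples as columns), taxonomy
is a 2-column TSV of 7-rank prefixed lineages
(`k__...; p__...; ...; s__...`), trees are Newick, distance matrices are
labeled square TSV, and references are FASTA.

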