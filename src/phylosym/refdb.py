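"""Reference-database curation and an RDP-style naive-Bayes k-mer
taxonomy classifier with bootstrap confidence.

Curation operates on local FASTA + lineage inputs: exact-duplicate
removal, a minimum-length filter, and provenance accounting for an
optional merge with a second reference set.
"""

from __future__ import annotations

import json
import math
import re
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .feature_tables import RANKS, TaxonomyMap, format_lineage, parse_lineage

__all__ = [
    "RefRecord",
    "RefDB",
    "curate_refdb",
    "HarmonizeRules",
    "harmonize_lineages",
    "ClassifierModel",
    "train_classifier",
    "classify",
    "Assignment",
    "read_fasta",
    "write_fasta",
]


@dataclass
class RefRecord:
    id: str
    seq: str
    lineage: tuple[str, ...]


@dataclass
class RefDB:
    records: list[RefRecord]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)


_GAP = re.compile(r"[-. ]")


def curate_refdb(seqs: Iterable[tuple[str, str]],
                 lineages: Mapping[str, str | Sequence[str]],
                 min_length: int = 180,
                 merge_with: RefDB | None = None) -> RefDB:
    """Drop sequences below `min_length` (length exactly `min_length` is
    kept) and exact-sequence duplicates (uppercased, gap-stripped; first
    occurrence wins), then concatenate `merge_with` without cross-set
    deduplication. Provenance records every count.
    """
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    seqs = list(seqs)
    missing = [sid for sid, _ in seqs if sid not in lineages]
    if missing:
        raise ValueError(f"sequences without a lineage: {missing}")

    collected = len(seqs)
    removed_short = removed_dup = 0
    seen: set[str] = set()
    records: list[RefRecord] = []
    for sid, raw in seqs:
        seq = _GAP.sub("", raw.upper())
        if len(seq) < min_length:
            removed_short += 1
            continue
        if seq in seen:
            removed_dup += 1
            continue
        seen.add(seq)
        lin = lineages[sid]
        if isinstance(lin, str):
            lin = parse_lineage(lin)
        records.append(RefRecord(sid, seq, tuple(lin)))

    remaining = len(records)
    assert remaining == collected - removed_dup - removed_short
    merged_in = 0
    if merge_with is not None:
        merged_in = len(merge_with.records)
        records = records + [RefRecord(r.id, r.seq, r.lineage)
                             for r in merge_with.records]
    provenance = {
        "collected": collected,
        "removed_duplicate": removed_dup,
        "removed_short": removed_short,
        "removed": removed_dup + removed_short,
        "remaining": remaining,
        "merged_in": merged_in,
        "final": remaining + merged_in,
        "min_length": min_length,
    }
    return RefDB(records, provenance)


# ---------------------------------------------------------------------------
# lineage harmonization
# ---------------------------------------------------------------------------

@dataclass
class HarmonizeRules:
    """Canonicalization passes applied to every rank name.

    ``strip_trailing_digits`` removes digit disambiguators appended to a
    name; ``synonyms`` maps names to their canonical form and is never
    inferred automatically (class-level reclassification conflicts can
    only be resolved via this table).
    """
    strip_trailing_digits: bool = False
    synonyms: dict[str, str] = field(default_factory=dict)


def harmonize_lineages(taxonomy: TaxonomyMap, rules: HarmonizeRules
                       ) -> tuple[TaxonomyMap, list[tuple]]:
    # reject cyclic synonym chains up front
    for start in rules.synonyms:
        cur, hops = start, 0
        while cur in rules.synonyms:
            cur = rules.synonyms[cur]
            hops += 1
            if cur == start or hops > len(rules.synonyms):
                raise ValueError(f"cyclic synonym rules involving {start!r}")

    changes: list[tuple] = []
    out: dict[str, tuple[str, ...]] = {}
    for fid, lineage in taxonomy.lineages.items():
        fixed = []
        for rank, name in zip(RANKS, lineage):
            new = name
            if rules.strip_trailing_digits:
                stripped = re.sub(r"\d+$", "", new)
                if stripped != new:
                    changes.append((fid, rank, new, stripped, "digit-strip"))
                    new = stripped
            while new in rules.synonyms:
                nxt = rules.synonyms[new]
                changes.append((fid, rank, new, nxt, "synonym"))
                new = nxt
            fixed.append(new)
        out[fid] = tuple(fixed)
    return TaxonomyMap(out), changes


# ---------------------------------------------------------------------------
# naive-Bayes k-mer classifier
# ---------------------------------------------------------------------------

_VALID_WORD = re.compile(r"^[ACGT]+$")


def _words(seq: str, k: int) -> list[str]:
    seq = seq.upper()
    out = {seq[i:i + k] for i in range(len(seq) - k + 1)}
    return sorted(w for w in out if _VALID_WORD.match(w))


@dataclass
class ClassifierModel:
    """Word-presence model: for taxon t and word w,
    P(w|t) = (m(w,t) + Pw) / (M_t + 1) with word prior
    Pw = (n_w + 0.5) / (N + 1), where m counts taxon-t training sequences
    containing w, M_t the taxon's sequence count, n_w the word's overall
    document frequency, and N the total sequence count."""

    k: int
    taxa: list[tuple[str, ...]]       # leaf lineages, sorted
    vocab: dict[str, int]
    m: np.ndarray                     # taxa x words presence counts
    M: np.ndarray                     # sequences per taxon
    n_w: np.ndarray                   # overall document frequency per word
    N: int

    def log_scores(self, words: list[str]) -> np.ndarray:
        """(words x taxa) matrix of log P(w|t); words unseen in training
        fall back to the bare prior numerator."""
        T = len(self.taxa)
        out = np.empty((len(words), T))
        prior_unseen = 0.5 / (self.N + 1)
        log_denom = np.log(self.M + 1.0)
        for i, w in enumerate(words):
            j = self.vocab.get(w)
            if j is None:
                out[i] = math.log(prior_unseen) - log_denom
            else:
                pw = (self.n_w[j] + 0.5) / (self.N + 1)
                out[i] = np.log(self.m[:, j] + pw) - log_denom
        return out

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        return json.dumps({
            "k": self.k,
            "taxa": [list(t) for t in self.taxa],
            "vocab": self.vocab,
            "m": self.m.tolist(),
            "M": self.M.tolist(),
            "n_w": self.n_w.tolist(),
            "N": self.N,
        }, sort_keys=True, separators=(",", ":"))

    @classmethod
    def from_json(cls, s: str) -> "ClassifierModel":
        d = json.loads(s)
        return cls(
            k=d["k"],
            taxa=[tuple(t) for t in d["taxa"]],
            vocab={k: int(v) for k, v in d["vocab"].items()},
            m=np.asarray(d["m"], dtype=np.int64),
            M=np.asarray(d["M"], dtype=np.int64),
            n_w=np.asarray(d["n_w"], dtype=np.int64),
            N=int(d["N"]),
        )


def train_classifier(db: RefDB, k: int = 8) -> ClassifierModel:
    if not (4 <= k <= 16):
        raise ValueError("k must be in [4, 16]")
    short = [r.id for r in db.records if len(r.seq) < k]
    if short:
        raise ValueError(f"sequences shorter than k: {short}")
    taxa = sorted({r.lineage for r in db.records})
    if len(taxa) < 2:
        raise ValueError("need >= 2 distinct taxa to train")
    tax_idx = {t: i for i, t in enumerate(taxa)}
    vocab: dict[str, int] = {}
    per_seq_words = []
    for r in db.records:
        ws = _words(r.seq, k)
        per_seq_words.append(ws)
        for w in ws:
            if w not in vocab:
                vocab[w] = len(vocab)
    m = np.zeros((len(taxa), len(vocab)), dtype=np.int64)
    M = np.zeros(len(taxa), dtype=np.int64)
    for r, ws in zip(db.records, per_seq_words):
        t = tax_idx[r.lineage]
        M[t] += 1
        for w in ws:
            m[t, vocab[w]] += 1
    n_w = m.sum(axis=0)
    return ClassifierModel(k=k, taxa=taxa, vocab=vocab, m=m, M=M,
                           n_w=n_w, N=int(M.sum()))


@dataclass
class Assignment:
    read_id: str
    lineage: tuple[str, ...]          # truncated at the confidence cutoff
    confidences: tuple[float, ...]    # per rank, vs the full-read call
    full_lineage: tuple[str, ...]
    classified: bool = True

    def lineage_str(self) -> str:
        return format_lineage(self.lineage)


def classify(model: ClassifierModel, reads: Iterable[tuple[str, str]],
             n_bootstrap: int = 100, confidence_threshold: float = 0.8,
             seed: int = 0) -> list[Assignment]:
    """Classify reads with bootstrap confidence.

    Per read: ceil(W/8)-word draws (with replacement) from the read's W
    distinct valid words, each assigned to its max-scoring leaf taxon;
    per-rank confidence is the fraction of draws agreeing with the
    full-read call's lineage at that rank. The reported lineage stops at
    the deepest rank whose confidence reaches the threshold. Per-read
    randomness is keyed on (seed, read id), so read order is irrelevant.
    """
    if n_bootstrap < 1:
        raise ValueError("n_bootstrap must be >= 1")
    blank = ("",) * len(RANKS)
    out = []
    for rid, seq in reads:
        words = _words(seq, model.k) if len(seq) >= model.k else []
        if not words:
            out.append(Assignment(rid, blank, (0.0,) * len(RANKS), blank,
                                  classified=False))
            continue
        S = model.log_scores(words)                     # W x T
        full_t = int(S.sum(axis=0).argmax())
        full = model.taxa[full_t]
        W = len(words)
        n_draw = -(-W // 8)                             # ceil(W/8)
        rng = np.random.default_rng(
            np.random.SeedSequence([seed, zlib.crc32(rid.encode())]))
        idx = rng.integers(0, W, size=(n_bootstrap, n_draw))
        agree = np.zeros(len(RANKS))
        for b in range(n_bootstrap):
            t = int(S[idx[b]].sum(axis=0).argmax())
            lin = model.taxa[t]
            for r in range(len(RANKS)):
                if lin[:r + 1] == full[:r + 1]:
                    agree[r] += 1
                else:
                    break
        conf = tuple(agree / n_bootstrap)
        depth = 0
        for r in range(len(RANKS)):
            if conf[r] >= confidence_threshold:
                depth = r + 1
            else:
                break
        lineage = full[:depth] + ("",) * (len(RANKS) - depth)
        out.append(Assignment(rid, lineage, conf, full,
                              classified=depth > 0))
    return out


# ---------------------------------------------------------------------------
# FASTA IO (plain text)
# ---------------------------------------------------------------------------

def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    SeqIO.write((SeqRecord(Seq(s), id=i, description="") for i, s in records),
                str(path), "fasta")


def read_fasta(path) -> list[tuple[str, str]]:
    from Bio import SeqIO
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
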