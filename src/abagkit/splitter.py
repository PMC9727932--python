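"""Abstract grouping, train/dev/test splitting, corpus statistics.

Abstracts fall into 4 groups by which entity types they mention: both,
antibody-only, antigen-only, or none.  Because the groups are very unequal
in practice, splits can randomize either over the whole corpus or within
each group (stratified), so every group lands in train/dev/test in the
configured proportion.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .corpus_io import Document, TokenizerConfig, tokenize

GROUPS = ("both", "antibody_only", "antigen_only", "none")
SPLITS = ("train", "dev", "test")


@dataclass
class SplitConfig:
    """Ratios are train:dev:test fractions, e.g. (0.6, 0.2, 0.2)."""

    ratios: Tuple[float, float, float] = (0.6, 0.2, 0.2)
    method: str = "group_wise"  # whole | group_wise
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.ratios) != 3 or any(r <= 0 for r in self.ratios):
            raise ValueError("ratios must be three positive fractions")
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError(f"ratios must sum to 1: {self.ratios}")
        if self.method not in ("whole", "group_wise"):
            raise ValueError(f"unknown split method: {self.method!r}")


def classify_abstract(doc: Document, set_name: str = "gold") -> str:
    """Group an abstract by presence/absence of each entity type."""
    anns = doc.get_set(set_name)
    has_ab = any(a.entity_type == "Antibody" for a in anns)
    has_ag = any(a.entity_type == "Antigen" for a in anns)
    if has_ab and has_ag:
        return "both"
    if has_ab:
        return "antibody_only"
    if has_ag:
        return "antigen_only"
    return "none"


def largest_remainder(n: int, ratios: Sequence[float]) -> List[int]:
    """Integer allocation of ``n`` items by the largest-remainder method.

    Remainder ties are broken toward earlier positions (the training set
    comes first), making the allocation deterministic.
    """
    quotas = [n * r for r in ratios]
    alloc = [int(q) for q in quotas]
    short = n - sum(alloc)
    order = sorted(
        range(len(ratios)), key=lambda i: (-(quotas[i] - alloc[i]), i)
    )
    for i in order[:short]:
        alloc[i] += 1
    return alloc


def split_corpus(
    docs: Sequence[Document],
    cfg: Optional[SplitConfig] = None,
    set_name: str = "gold",
) -> Dict[str, List[str]]:
    """Partition document ids into train/dev/test.

    ``whole`` shuffles the full corpus once; ``group_wise`` shuffles and
    allocates within each presence group so per-group composition tracks
    the ratios to within one document.  Reproducible from ``cfg.seed``.
    """
    cfg = cfg or SplitConfig()
    if len(docs) < 3:
        raise ValueError("need at least 3 documents to split")
    rng = random.Random(cfg.seed)

    def allocate(ids: List[str]) -> Dict[str, List[str]]:
        ids = sorted(ids)
        rng.shuffle(ids)
        sizes = largest_remainder(len(ids), cfg.ratios)
        out, pos = {}, 0
        for name, k in zip(SPLITS, sizes):
            out[name] = ids[pos:pos + k]
            pos += k
        return out

    if cfg.method == "whole":
        return allocate([d.doc_id for d in docs])

    by_group: Dict[str, List[str]] = {g: [] for g in GROUPS}
    for d in docs:
        by_group[classify_abstract(d, set_name)].append(d.doc_id)
    result: Dict[str, List[str]] = {s: [] for s in SPLITS}
    for g in GROUPS:
        ids = by_group[g]
        if not ids:
            continue
        if len(ids) < 3:
            warnings.warn(
                f"group {g!r} has only {len(ids)} documents; "
                "some splits may be empty for it"
            )
        part = allocate(ids)
        for s in SPLITS:
            result[s].extend(part[s])
    return result


@dataclass
class CorpusStats:
    """Per-split and total corpus statistics.

    ``per_split`` maps split name (plus "total") to a dict with keys:
    n_docs, ab_mentions, ag_mentions, unique_ab, unique_ag, n_sentences,
    n_words.  Averages are computed (not stored) so they stay exact;
    rounding happens only at presentation time.
    """

    per_split: Dict[str, Dict[str, float]] = field(default_factory=dict)
    empty: bool = False

    @staticmethod
    def avg_mentions_per_abstract(ab: int, ag: int, n_docs: int) -> float:
        return (ab + ag) / n_docs if n_docs else 0.0

    def average(self, split: str, what: str) -> float:
        row = self.per_split[split]
        if row["n_docs"] == 0:
            return 0.0
        if what == "mentions":
            return (row["ab_mentions"] + row["ag_mentions"]) / row["n_docs"]
        return row[what] / row["n_docs"]

    def table(self) -> str:
        """Aligned human-readable table, averages at 1 decimal."""
        cols = [s for s in (*SPLITS, "total") if s in self.per_split]
        rows = [
            ("No. of abstracts", "n_docs", 0),
            ("No. of antibody mentions", "ab_mentions", 0),
            ("No. of unique antibody mentions", "unique_ab", 0),
            ("No. of antigen mentions", "ag_mentions", 0),
            ("No. of unique antigen mentions", "unique_ag", 0),
            ("Avg. sentences per abstract", "n_sentences", 1),
            ("Avg. words per abstract", "n_words", 1),
            ("Avg. mentions per abstract", "mentions", 1),
        ]
        lines = ["%-34s" % "Characteristics" + "".join(f"{c:>12}" for c in cols)]
        for label, key, dp in rows:
            cells = []
            for c in cols:
                v = self.per_split[c][key] if dp == 0 else self.average(c, key)
                cells.append(f"{v:>12.{dp}f}" if dp else f"{int(v):>12d}")
            lines.append("%-34s" % label + "".join(cells))
        return "\n".join(lines)


def corpus_stats(
    docs: Sequence[Document],
    splits: Optional[Dict[str, List[str]]] = None,
    set_name: str = "gold",
    tok_cfg: Optional[TokenizerConfig] = None,
) -> CorpusStats:
    """Count documents, mentions, unique mentions, sentences and words.

    "Words" are tokens from the corpus tokenizer; unique mentions are
    distinct covered-text strings per entity type, case sensitive.  Counts
    are additive across splits; unique-mention counts are recomputed per
    split (and on the whole corpus for "total").
    """
    tok_cfg = tok_cfg or TokenizerConfig()
    by_id = {d.doc_id: d for d in docs}
    groups: Dict[str, List[Document]] = {}
    if splits:
        for name, ids in splits.items():
            groups[name] = [by_id[i] for i in ids]
    groups["total"] = list(docs)

    stats = CorpusStats(empty=not docs)
    for name, members in groups.items():
        ab = ag = sents = words = 0
        uniq: Dict[str, set] = {"Antibody": set(), "Antigen": set()}
        for d in members:
            anns = d.get_set(set_name)
            for a in anns:
                if a.entity_type == "Antibody":
                    ab += 1
                else:
                    ag += 1
                uniq[a.entity_type].add(a.text)
            sents += len(d.sentences) if d.sentences else (1 if d.text.strip() else 0)
            words += len(tokenize(d, tok_cfg).tokens)
        stats.per_split[name] = {
            "n_docs": len(members),
            "ab_mentions": ab,
            "ag_mentions": ag,
            "unique_ab": len(uniq["Antibody"]),
            "unique_ag": len(uniq["Antigen"]),
            "n_sentences": sents,
            "n_words": words,
        }
    return stats
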