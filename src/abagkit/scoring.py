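"""Entity-level NER scoring (exact and relax match) and inter-annotator
agreement.

Matching between two annotation sets is always one-to-one and optimal
(maximum bipartite matching), never greedy, which guarantees that relaxing
the match criterion can only raise F1.  Four match modes are supported:

* ``strict``      — same span and same entity type;
* ``type_relax``  — same span, entity type ignored;
* ``span_relax``  — same entity type, spans need only overlap;
* ``both_relax``  — overlapping span, entity type ignored.

Overlap means at least one shared character.  Precision, recall and F1 use
the standard definitions P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R),
with 0 when a denominator is 0; micro scores pool counts over entity types
and documents.

Agreement between two annotators decomposes matched pairs into full
agreement (FA: same span and type), concept agreement (CA: same span,
different type), partial agreement (PA: overlap, same type) and
disagreement (DA: overlap, different type); annotations tagged by only one
annotator are singles (SN).  With the five categories as percentages of all
agreement units::

    strict F1 = FA / (100 - SN/2) * 100
    relax  F1 = (FA + CA + PA + DA) / (100 - SN/2) * 100

SN plays the role of FP+FN, hence the half-SN correction in the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.optimize import linear_sum_assignment

from .corpus_io import Annotation

MATCH_MODES = ("strict", "type_relax", "span_relax", "both_relax")

# agreement categories, best first; order fixes matching preference
CATEGORIES = ("FA", "CA", "PA", "DA")


def _require_one_doc(*sets: Iterable[Annotation]) -> None:
    ids = {a.doc_id for anns in sets for a in anns}
    if len(ids) > 1:
        raise ValueError(f"annotations span multiple documents: {sorted(ids)}")


def _admissible(g: Annotation, p: Annotation, mode: str) -> bool:
    if mode == "strict":
        return g.same_span(p) and g.entity_type == p.entity_type
    if mode == "type_relax":
        return g.same_span(p)
    if mode == "span_relax":
        return g.overlaps(p) and g.entity_type == p.entity_type
    if mode == "both_relax":
        return g.overlaps(p)
    raise ValueError(f"unknown match mode: {mode!r}")


def _category(a: Annotation, b: Annotation) -> Optional[str]:
    if not a.overlaps(b):
        return None
    if a.same_span(b):
        return "FA" if a.entity_type == b.entity_type else "CA"
    return "PA" if a.entity_type == b.entity_type else "DA"


def _optimal_pairs(
    left: Sequence[Annotation],
    right: Sequence[Annotation],
    weight_of: "callable",
) -> List[Tuple[int, int]]:
    """Maximum-weight one-to-one pairing; zero-weight pairs are discarded.

    ``weight_of(a, b)`` must be 0 for inadmissible pairs and positive
    otherwise.  Inputs are pre-sorted by position so the assignment is
    deterministic (earliest-start preference on ties).
    """
    if not left or not right:
        return []
    w = np.zeros((len(left), len(right)))
    for i, a in enumerate(left):
        for j, b in enumerate(right):
            w[i, j] = weight_of(a, b)
    rows, cols = linear_sum_assignment(w, maximize=True)
    return [(i, j) for i, j in zip(rows, cols) if w[i, j] > 0]


def match_annotations(
    gold: Iterable[Annotation],
    pred: Iterable[Annotation],
    mode: str = "strict",
) -> Tuple[int, int, int, List[Tuple[Annotation, Annotation]]]:
    """Match one document's gold and predicted annotations.

    Returns (TP, FP, FN, matched pairs): TP pairs found by maximum
    matching over admissible pairs, FP the unmatched predictions, FN the
    unmatched gold annotations.
    """
    _require_one_doc(gold, pred)
    g = sorted(gold)
    p = sorted(pred)
    pairs_idx = _optimal_pairs(
        g, p, lambda a, b: 1.0 if _admissible(a, b, mode) else 0.0
    )
    pairs = [(g[i], p[j]) for i, j in sorted(pairs_idx)]
    tp = len(pairs)
    return tp, len(p) - tp, len(g) - tp, pairs


def prf(tp: int, fp: int, fn: int) -> Tuple[float, float, float]:
    """Precision, recall, F1 as percentages; 0 where undefined."""
    p = 100.0 * tp / (tp + fp) if tp + fp else 0.0
    r = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    return p, r, f1_score(p, r)


def f1_score(p: float, r: float) -> float:
    """Harmonic mean of precision and recall (same scale as its inputs)."""
    return 2.0 * p * r / (p + r) if p + r else 0.0


@dataclass
class TypeScores:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def support(self) -> int:
        return self.tp + self.fn

    @property
    def precision(self) -> float:
        return prf(self.tp, self.fp, self.fn)[0]

    @property
    def recall(self) -> float:
        return prf(self.tp, self.fp, self.fn)[1]

    @property
    def f1(self) -> float:
        return prf(self.tp, self.fp, self.fn)[2]


@dataclass
class EvalReport:
    """Per-type and micro scores for one match mode.

    In the type-relaxed modes a matched pair may join a gold and a
    prediction of different types; the pair counts as TP under the gold
    annotation's type, and unmatched predictions count as FP under theirs.
    Micro counts are the sums of the per-type counts.
    """

    mode: str = "strict"
    per_type: Dict[str, TypeScores] = field(default_factory=dict)

    @property
    def micro(self) -> TypeScores:
        return TypeScores(
            tp=sum(t.tp for t in self.per_type.values()),
            fp=sum(t.fp for t in self.per_type.values()),
            fn=sum(t.fn for t in self.per_type.values()),
        )

    def table(self) -> str:
        lines = ["%-14s%10s%10s%10s%10s" %
                 ("Entity", "Precision", "Recall", "F1", "Support")]
        rows = sorted(self.per_type.items()) + [("Micro average", self.micro)]
        for name, t in rows:
            lines.append(
                "%-14s%10.2f%10.2f%10.2f%10d"
                % (name, t.precision, t.recall, t.f1, t.support)
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        out = {"mode": self.mode, "per_type": {}, "micro": {}}
        for name, t in {**self.per_type, "micro": self.micro}.items():
            d = {
                "tp": t.tp, "fp": t.fp, "fn": t.fn, "support": t.support,
                "precision": round(t.precision, 2),
                "recall": round(t.recall, 2),
                "f1": round(t.f1, 2),
            }
            if name == "micro":
                out["micro"] = d
            else:
                out["per_type"][name] = d
        return out


def compute_prf(
    counts: Mapping[str, Tuple[int, int, int]], mode: str = "strict"
) -> EvalReport:
    """Assemble an :class:`EvalReport` from per-type (TP, FP, FN) counts."""
    report = EvalReport(mode=mode)
    for etype, (tp, fp, fn) in counts.items():
        if min(tp, fp, fn) < 0:
            raise ValueError(f"negative counts for {etype}")
        report.per_type[etype] = TypeScores(tp, fp, fn)
    return report


def evaluate_documents(
    docs,
    gold_set: str = "gold",
    pred_set: str = "pred",
    mode: str = "strict",
) -> EvalReport:
    """Corpus-level evaluation: match per document, pool counts per type."""
    counts: Dict[str, TypeScores] = {}

    def scores(etype: str) -> TypeScores:
        return counts.setdefault(etype, TypeScores())

    for doc in docs:
        gold = doc.get_set(gold_set)
        pred = doc.annotations.get(pred_set, set())
        _tp, _fp, _fn, pairs = match_annotations(gold, pred, mode)
        matched_g = {id(g) for g, _ in pairs}
        matched_p = {id(p) for _, p in pairs}
        by_id_g = {id(a): a for a in gold}
        by_id_p = {id(a): a for a in pred}
        for g, _p in pairs:
            scores(g.entity_type).tp += 1
        for i, a in by_id_g.items():
            if i not in matched_g:
                scores(a.entity_type).fn += 1
        for i, a in by_id_p.items():
            if i not in matched_p:
                scores(a.entity_type).fp += 1
    return EvalReport(
        mode=mode, per_type={k: v for k, v in sorted(counts.items())}
    )


# --- inter-annotator agreement ---------------------------------------------


@dataclass
class AgreementReport:
    """Category percentages and the strict/relax agreement F1 scores.

    ``fa + ca + pa + da + sn == 100`` up to float error; ``n_units`` is the
    number of agreement units (matched pairs plus singles).  ``degenerate``
    marks the empty-vs-empty case, reported as perfect agreement by
    convention.
    """

    fa: float
    ca: float
    pa: float
    da: float
    sn: float
    n_units: int = 0
    counts: Dict[str, int] = field(default_factory=dict)
    degenerate: bool = False

    @property
    def strict_f1(self) -> float:
        if self.degenerate:
            return 100.0
        return 100.0 * self.fa / (100.0 - self.sn / 2.0)

    @property
    def relax_f1(self) -> float:
        if self.degenerate:
            return 100.0
        agree = self.fa + self.ca + self.pa + self.da
        return 100.0 * agree / (100.0 - self.sn / 2.0)

    @classmethod
    def from_components(
        cls, fa: float, ca: float, pa: float, da: float, sn: float
    ) -> "AgreementReport":
        """Build a report directly from category percentages."""
        total = fa + ca + pa + da + sn
        if abs(total - 100.0) > 1e-6:
            raise ValueError(f"categories must sum to 100, got {total}")
        return cls(fa=fa, ca=ca, pa=pa, da=da, sn=sn)

    @classmethod
    def from_counts(
        cls, counts: Mapping[str, int]
    ) -> "AgreementReport":
        n = sum(counts.get(c, 0) for c in (*CATEGORIES, "SN"))
        if n == 0:
            return cls(0.0, 0.0, 0.0, 0.0, 0.0, n_units=0,
                       counts=dict(counts), degenerate=True)
        pct = {c: 100.0 * counts.get(c, 0) / n for c in (*CATEGORIES, "SN")}
        return cls(pct["FA"], pct["CA"], pct["PA"], pct["DA"], pct["SN"],
                   n_units=n, counts=dict(counts))

    def to_dict(self) -> dict:
        return {
            "FA": round(self.fa, 2), "CA": round(self.ca, 2),
            "PA": round(self.pa, 2), "DA": round(self.da, 2),
            "SN": round(self.sn, 2),
            "strict_f1": round(self.strict_f1, 2),
            "relax_f1": round(self.relax_f1, 2),
            "n_units": self.n_units,
            "degenerate": self.degenerate,
        }

    def table(self) -> str:
        head = "%8s%8s%8s%8s%8s%12s%12s" % (
            "FA(%)", "CA(%)", "PA(%)", "DA(%)", "SN(%)",
            "Strict F1", "Relax F1",
        )
        row = "%8.2f%8.2f%8.2f%8.2f%8.2f%12.2f%12.2f" % (
            self.fa, self.ca, self.pa, self.da, self.sn,
            self.strict_f1, self.relax_f1,
        )
        return head + "\n" + row


def _agreement_counts(
    set_a: Iterable[Annotation], set_b: Iterable[Annotation]
) -> Dict[str, int]:
    """Category counts for one pair of annotation sets (any documents).

    Pairing per document is by maximum matching; among maximum matchings the
    one maximizing FA, then CA, then PA counts is chosen.  Lexicographic
    weights make that count vector unique, so the result is symmetric in
    its arguments.
    """
    by_doc: Dict[str, Tuple[List[Annotation], List[Annotation]]] = {}
    for a in set_a:
        by_doc.setdefault(a.doc_id, ([], []))[0].append(a)
    for b in set_b:
        by_doc.setdefault(b.doc_id, ([], []))[1].append(b)

    counts = {c: 0 for c in (*CATEGORIES, "SN")}
    bonus = {"FA": 3, "CA": 2, "PA": 1, "DA": 0}
    for doc_id in sorted(by_doc):
        left, right = by_doc[doc_id]
        left.sort()
        right.sort()
        base = float(max(len(left), len(right)) + 1)

        def weight(a: Annotation, b: Annotation, _base=base) -> float:
            cat = _category(a, b)
            if cat is None:
                return 0.0
            return _base ** 4 + _base ** bonus[cat]

        pairs = _optimal_pairs(left, right, weight)
        for i, j in pairs:
            counts[_category(left[i], right[j])] += 1
        counts["SN"] += (len(left) - len(pairs)) + (len(right) - len(pairs))
    return counts


def pairwise_agreement(
    set_a: Iterable[Annotation], set_b: Iterable[Annotation]
) -> AgreementReport:
    """Agreement between two annotators' annotation sets.

    Both iterables may cover several documents; annotations are paired
    within each document only.
    """
    return AgreementReport.from_counts(_agreement_counts(set_a, set_b))


def multi_agreement(
    sets: Sequence[Iterable[Annotation]],
) -> AgreementReport:
    """Agreement across ≥2 annotators: pairwise counts, micro-pooled.

    Category counts from every annotator pair are summed before percentages
    and the F1 formulas are applied.
    """
    sets = [list(s) for s in sets]
    if len(sets) < 2:
        raise ValueError("need at least 2 annotation sets")
    pooled = {c: 0 for c in (*CATEGORIES, "SN")}
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            for cat, n in _agreement_counts(sets[i], sets[j]).items():
                pooled[cat] += n
    return AgreementReport.from_counts(pooled)
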