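"""Synthetic lexicons, abstracts, gold annotations, and perturbations.

Every other module is testable without external data: the generator plants
lexicon surfaces into sentence templates at recorded offsets, so the ledger
it returns is an exact oracle for the tagger, the group classifier, the
corpus statistics and the evaluators.  Perturbation operators mirror the
error types seen in real annotation projects — missed mentions (deletions),
spurious mentions (insertions), entity-type confusions (flips) and boundary
errors (span shifts).

The defaults emulate the real antibody/antigen corpus: group proportions of
roughly 60% both-entity abstracts, 3% antibody-only, 33% antigen-only and
4% untagged, with on average 3.5 antibody and 6.5 antigen mentions per
abstract.  What the generator does not emulate: real biomedical syntax,
context-dependent mentions, or nested/discontinuous entities.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

from .corpus_io import Annotation, Document, TokenizerConfig, tokenize_text
from .lexicon import (
    DEFAULT_STOPWORDS,
    Lexicon,
    LexiconEntry,
    extract_from_compound,
)
from .splitter import GROUPS, largest_remainder

_SINGLE_LETTER_TRAPS = list("EGSNML")
_WORD_TRAPS = sorted(DEFAULT_STOPWORDS) + ["Fab", "mAb", "IgG"]

_GREEK = ["alpha", "beta", "gamma", "delta", "kappa"]


@dataclass
class SynthConfig:
    """Corpus-shape knobs; defaults follow the real corpus's proportions."""

    n_docs: int = 200
    group_mix: Tuple[float, float, float, float] = (0.596, 0.029, 0.331, 0.044)
    mean_ab_mentions: float = 3.5
    mean_ag_mentions: float = 6.5
    repeat_rate: float = 0.25
    confusable_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.group_mix) - 1.0) > 1e-9:
            raise ValueError("group_mix must sum to 1")
        for r in (self.repeat_rate, self.confusable_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must be in [0, 1]")


@dataclass
class PerturbConfig:
    delete_rate: float = 0.0
    insert_rate: float = 0.0
    type_flip_rate: float = 0.0
    span_shift_rate: float = 0.0
    max_shift: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.delete_rate, self.insert_rate,
                  self.type_flip_rate, self.span_shift_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if self.max_shift < 1:
            raise ValueError("max_shift must be >= 1")


def _clone_id(rng: random.Random) -> str:
    """Antibody-clone-style name: letter/digit mixes like 2Rs15d or 1D05."""
    style = rng.randrange(3)
    if style == 0:
        return (f"{rng.randrange(1, 10)}{chr(rng.randrange(65, 91))}"
                f"{chr(rng.randrange(97, 123))}{rng.randrange(10, 100)}"
                f"{chr(rng.randrange(97, 123))}")
    if style == 1:
        return (f"{rng.randrange(1, 10)}{chr(rng.randrange(65, 91))}"
                f"{rng.randrange(10, 100):02d}")
    return (f"{chr(rng.randrange(97, 123))}{chr(rng.randrange(65, 91))}"
            f"{chr(rng.randrange(65, 91))}{chr(rng.randrange(97, 123))}"
            f"{chr(rng.randrange(65, 91))}{rng.randrange(1, 10)}")


def _gene_symbol(rng: random.Random) -> str:
    """Antigen gene-symbol-style name, e.g. ABCC6, PCSK9, IL-6R."""
    style = rng.randrange(4)
    letters = "".join(chr(rng.randrange(65, 91)) for _ in range(rng.randrange(3, 6)))
    if style == 0:
        return f"{letters}{rng.randrange(1, 100)}"
    if style == 1:
        return f"{letters[:2]}-{rng.randrange(1, 20)}{chr(rng.randrange(65, 91))}"
    if style == 2:
        return f"{letters}{rng.randrange(1, 10)} {rng.choice(_GREEK)}"
    return f"{letters}{rng.randrange(1, 10)}"


def generate_lexicon(
    n_ab: int,
    n_ag: int,
    seed: int = 0,
    n_traps: int = 12,
    n_compounds: int = 0,
) -> Tuple[Lexicon, List[LexiconEntry]]:
    """Deterministic lexicon of clone-ID antibodies and gene-symbol antigens.

    A fraction of antigens carries a species prefix ("human X"); optional
    ``anti-AG-AB`` compound names contribute extracted entries.  Returns the
    (unfiltered) lexicon together with the planted trap entries, each of
    which violates at least one filter rule by construction.
    """
    rng = random.Random(seed)
    entries: Set[LexiconEntry] = set()
    ab_surfaces: Set[str] = set()
    while len(ab_surfaces) < n_ab:
        ab_surfaces.add(_clone_id(rng))
    for s in sorted(ab_surfaces):
        entries.add(LexiconEntry(s, "Antibody"))
    ag_surfaces: Set[str] = set()
    while len(ag_surfaces) < n_ag:
        name = _gene_symbol(rng)
        if rng.random() < 0.25:
            name = f"{rng.choice(['human', 'murine'])} {name}"
        if name not in ab_surfaces:
            ag_surfaces.add(name)
    for s in sorted(ag_surfaces):
        entries.add(LexiconEntry(s, "Antigen"))

    for _ in range(n_compounds):
        compound = f"anti-{_gene_symbol(rng).split()[0]}-{_clone_id(rng)}"
        pair = extract_from_compound(compound)
        if pair:
            ag, ab = pair
            entries.add(LexiconEntry(ag, "Antigen", "compound_extracted"))
            entries.add(LexiconEntry(ab, "Antibody", "compound_extracted"))

    traps: List[LexiconEntry] = []
    for i in range(n_traps):
        kind = i % 3
        etype = "Antibody" if i % 2 else "Antigen"
        if kind == 0:
            surface = _SINGLE_LETTER_TRAPS[(i // 3) % len(_SINGLE_LETTER_TRAPS)]
        elif kind == 1:
            surface = str(rng.randrange(1, 1000))
        else:
            surface = _WORD_TRAPS[(i // 3) % len(_WORD_TRAPS)]
        traps.append(LexiconEntry(surface, etype))
    entries.update(traps)
    return Lexicon(entries=entries), traps


# Templates; {AB}/{AG} slots are filled with lexicon surfaces.  Words are
# chosen so no template word can extend a planted surface into a longer
# lexicon match.
_T_BOTH = [
    "The antibody {AB} binds {AG} with high affinity .",
    "Treatment with {AB} reduced circulating {AG} levels in vivo .",
    "We show that {AB} recognizes an epitope of {AG} .",
    "Neutralization of {AG} by {AB} was dose dependent .",
]
_T_AB = [
    "The clone {AB} was characterized by surface plasmon resonance .",
    "Affinity maturation improved binding of {AB} substantially .",
]
_T_AG = [
    "Expression of {AG} was elevated in patient samples .",
    "The structure of {AG} reveals a conserved binding pocket .",
    "{AG} is implicated in disease progression .",
]
_T_FILLER = [
    "These findings suggest a potential therapeutic strategy .",
    "Further experiments are required to confirm this mechanism .",
    "Results were consistent across three independent replicates .",
    "The assay was performed under physiological conditions .",
]
_T_TRAP = [
    "A dose of {TRAP} was administered to each cohort .",
    "The {TRAP} fragment preparation was stored at low temperature .",
]


def _pick_surface(
    rng: random.Random,
    pool: Sequence[str],
    used: List[str],
    repeat_rate: float,
) -> str:
    if used and rng.random() < repeat_rate:
        return rng.choice(used)
    return rng.choice(pool)


def generate_corpus(
    lex: Lexicon,
    cfg: Optional[SynthConfig] = None,
    trap_words: Optional[Sequence[str]] = None,
) -> Tuple[List[Document], Dict]:
    """Assemble abstracts from templates with exactly recorded mention offsets.

    Group membership follows ``group_mix`` exactly up to largest-remainder
    rounding.  The returned ledger records, per document, its group and every
    planted mention (start, end, type, surface) and trap word; gold
    annotations are attached to each document under the set name "gold".
    """
    cfg = cfg or SynthConfig()
    rng = random.Random(cfg.seed)
    ab_pool = sorted(lex.surfaces("Antibody"))
    ag_pool = sorted(lex.surfaces("Antigen"))
    traps = list(trap_words) if trap_words else ["mAb", "Fab", "250", "IgG"]

    group_counts = largest_remainder(cfg.n_docs, cfg.group_mix)
    doc_groups = [g for g, k in zip(GROUPS, group_counts) for _ in range(k)]
    rng.shuffle(doc_groups)

    def poisson(mean: float) -> int:
        # Knuth's method; means here are tiny
        import math
        limit, k, p = math.exp(-mean), 0, 1.0
        while p > limit:
            p *= rng.random()
            k += 1
        return k - 1

    docs: List[Document] = []
    ledger: Dict = {"config": cfg, "docs": {}, "totals": {
        "Antibody": 0, "Antigen": 0, "groups": dict(zip(GROUPS, group_counts)),
    }}
    for di, group in enumerate(doc_groups):
        doc_id = f"synth{di:04d}"
        n_ab = max(1, poisson(cfg.mean_ab_mentions)) if group in ("both", "antibody_only") else 0
        n_ag = max(1, poisson(cfg.mean_ag_mentions)) if group in ("both", "antigen_only") else 0
        if (n_ab and not ab_pool) or (n_ag and not ag_pool):
            raise ValueError("lexicon lacks surfaces for requested mentions")
        used_ab: List[str] = []
        used_ag: List[str] = []
        queue: List[Tuple[str, str]] = []
        for _ in range(n_ab):
            s = _pick_surface(rng, ab_pool, used_ab, cfg.repeat_rate)
            used_ab.append(s)
            queue.append(("Antibody", s))
        for _ in range(n_ag):
            s = _pick_surface(rng, ag_pool, used_ag, cfg.repeat_rate)
            used_ag.append(s)
            queue.append(("Antigen", s))
        rng.shuffle(queue)

        planted: List[Tuple[int, int, str, str]] = []
        doc_traps: List[str] = []
        text_parts: List[str] = []
        sent_spans: List[Tuple[int, int]] = []
        pos = 0

        def emit(sentence: str, fills: List[Tuple[str, str]]) -> None:
            """Append a sentence, replacing slots and recording offsets."""
            nonlocal pos
            if text_parts:
                text_parts.append(" ")
                pos += 1
            start = pos
            rest = sentence
            while rest:
                idx_ab = rest.find("{AB}")
                idx_ag = rest.find("{AG}")
                idx_tr = rest.find("{TRAP}")
                idxs = [i for i in (idx_ab, idx_ag, idx_tr) if i != -1]
                if not idxs:
                    text_parts.append(rest)
                    pos += len(rest)
                    break
                cut = min(idxs)
                text_parts.append(rest[:cut])
                pos += cut
                if cut == idx_tr:
                    token = "{TRAP}"
                    word = fills.pop(0)[1]
                    doc_traps.append(word)
                else:
                    token = "{AB}" if cut == idx_ab else "{AG}"
                    etype, word = fills.pop(0)
                    planted.append((pos, pos + len(word), etype, word))
                text_parts.append(word)
                pos += len(word)
                rest = rest[cut + len(token):]
            sent_spans.append((start, pos))

        while queue:
            have_ab = any(t == "Antibody" for t, _ in queue)
            have_ag = any(t == "Antigen" for t, _ in queue)
            if have_ab and have_ag and rng.random() < 0.7:
                ab = next(m for m in queue if m[0] == "Antibody")
                ag = next(m for m in queue if m[0] == "Antigen")
                queue.remove(ab)
                queue.remove(ag)
                tpl = rng.choice(_T_BOTH)
                slots = []
                for part in tpl.split():
                    if part == "{AB}":
                        slots.append(ab)
                    elif part == "{AG}":
                        slots.append(ag)
                emit(tpl, slots)
            else:
                etype, surface = queue.pop(0)
                tpl = rng.choice(_T_AB if etype == "Antibody" else _T_AG)
                emit(tpl, [(etype, surface)])
            if rng.random() < 0.3:
                emit(rng.choice(_T_FILLER), [])
        if rng.random() < cfg.confusable_rate:
            emit(rng.choice(_T_TRAP), [("trap", rng.choice(traps))])
        while len(sent_spans) < 2:
            emit(rng.choice(_T_FILLER), [])

        text = "".join(text_parts)
        anns = {
            Annotation(doc_id, s, e, t, text[s:e])
            for s, e, t, _surface in planted
        }
        doc = Document(doc_id=doc_id, text=text, sentences=sent_spans,
                       annotations={"gold": anns})
        doc.validate()
        docs.append(doc)
        ledger["docs"][doc_id] = {
            "group": group,
            "mentions": sorted(planted),
            "traps": doc_traps,
        }
        for _s, _e, t, _surf in planted:
            ledger["totals"][t] += 1
    return docs, ledger


def perturb_annotations(
    doc: Document,
    cfg: PerturbConfig,
    set_name: str = "gold",
) -> Tuple[Set[Annotation], List[Tuple[Optional[Annotation], str]]]:
    """Apply controlled errors to one document's annotation set.

    Each annotation is independently deleted, type-flipped and/or
    span-shifted at the configured rates; spurious annotations are inserted
    over unannotated token spans.  Span shifts are clamped to keep at least
    one character of overlap with the original and to never collide with
    another annotation, so the expected agreement category of every output
    is known.  Returns the perturbed set and a ledger of
    (annotation-or-None, expected category) where the category is one of
    FA/CA/PA/DA (surviving annotations), "SN_gold" (a deletion: the gold
    side becomes a single) or "SN_pred" (an insertion).
    """
    rng = random.Random(cfg.seed)
    gold = sorted(doc.get_set(set_name))
    occupied: List[Tuple[int, int]] = [(a.start, a.end) for a in gold]
    out: Set[Annotation] = set()
    ledger: List[Tuple[Optional[Annotation], str]] = []

    def collides(s: int, e: int, ignore: Optional[Tuple[int, int]] = None) -> bool:
        for os, oe in occupied:
            if (os, oe) == ignore:
                continue
            if s < oe and os < e:
                return True
        return False

    for a in gold:
        if rng.random() < cfg.delete_rate:
            ledger.append((None, "SN_gold"))
            continue
        etype = a.entity_type
        flipped = rng.random() < cfg.type_flip_rate
        if flipped:
            etype = "Antigen" if etype == "Antibody" else "Antibody"
        s, e = a.start, a.end
        shifted = False
        if rng.random() < cfg.span_shift_rate:
            for _attempt in range(8):
                ns = s + rng.randint(-cfg.max_shift, cfg.max_shift)
                ne = e + rng.randint(-cfg.max_shift, cfg.max_shift)
                ns = max(0, ns)
                ne = min(len(doc.text), ne)
                if (ns, ne) == (s, e) or ns >= ne:
                    continue
                if ns >= a.end or ne <= a.start:  # must keep overlap
                    continue
                if collides(ns, ne, ignore=(a.start, a.end)):
                    continue
                s, e, shifted = ns, ne, True
                break
        # the original span stays reserved too: an insertion landing there
        # could overlap the gold annotation and steal its pairing
        if (s, e) != (a.start, a.end):
            occupied.append((s, e))
        ann = Annotation(doc.doc_id, s, e, etype, doc.text[s:e])
        out.add(ann)
        category = ("DA" if flipped else "PA") if shifted else \
                   ("CA" if flipped else "FA")
        ledger.append((ann, category))

    if cfg.insert_rate > 0:
        tokens = [t for t in tokenize_text(doc.text)
                  if len(t[0]) > 1 and not collides(t[1], t[2])]
        n_ins = sum(1 for _ in gold if rng.random() < cfg.insert_rate)
        rng.shuffle(tokens)
        for tok, s, e in tokens[:n_ins]:
            if collides(s, e):
                continue
            occupied.append((s, e))
            etype = rng.choice(("Antibody", "Antigen"))
            ann = Annotation(doc.doc_id, s, e, etype, doc.text[s:e])
            out.add(ann)
            ledger.append((ann, "SN_pred"))
    return out, ledger


def perturb_corpus(
    docs: Sequence[Document],
    cfg: PerturbConfig,
    gold_set: str = "gold",
    pred_set: str = "pred",
) -> Dict[str, List[Tuple[Optional[Annotation], str]]]:
    """Perturb every document, attaching results as ``pred_set``.

    Per-document seeds are derived from ``cfg.seed`` so the whole corpus is
    reproducible.  Returns the per-document expected-category ledgers.
    """
    ledgers = {}
    for i, doc in enumerate(docs):
        doc_cfg = PerturbConfig(
            delete_rate=cfg.delete_rate, insert_rate=cfg.insert_rate,
            type_flip_rate=cfg.type_flip_rate,
            span_shift_rate=cfg.span_shift_rate,
            max_shift=cfg.max_shift,
            seed=(cfg.seed * 1_000_003 + i) % (2 ** 31),
        )
        perturbed, led = perturb_annotations(doc, doc_cfg, set_name=gold_set)
        doc.annotations[pred_set] = perturbed
        ledgers[doc.doc_id] = led
    return ledgers
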