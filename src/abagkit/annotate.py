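"""Dictionary-based automatic pre-annotation (string-match tagging).

Every lexicon surface is searched in the abstract text; matches must align
with token boundaries so "HER2" never fires inside "HER2something".
Overlapping candidates are resolved longest-first, then leftmost — the same
preference a human pre-annotator applies, and the reason "human ABCC6" wins
over its embedded "ABCC6".  The output of this stage is meant for manual
revision; :func:`diff_annotations` quantifies what that revision changed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set, Tuple

from .corpus_io import Annotation, Document, TokenizerConfig, tokenize_text
from .lexicon import Lexicon

#: Surfaces this long or shorter always match case-sensitively under the
#: "smart" policy: short clone IDs like "1D05" are case-critical, while long
#: names tolerate synonym case variance.
SMART_CASE_MAX_LEN = 4


@dataclass
class TaggerConfig:
    match_case: str = "smart"  # sensitive | insensitive | smart
    boundary_required: bool = True
    overlap_policy: str = "longest_leftmost"
    type_conflict: str = "emit_both_flagged"

    def __post_init__(self) -> None:
        if self.match_case not in ("sensitive", "insensitive", "smart"):
            raise ValueError(f"unknown case policy: {self.match_case!r}")
        if self.overlap_policy != "longest_leftmost":
            raise ValueError(f"unknown overlap policy: {self.overlap_policy!r}")
        if self.type_conflict not in (
            "prefer_antibody", "prefer_antigen", "emit_both_flagged"
        ):
            raise ValueError(f"unknown conflict policy: {self.type_conflict!r}")


def _case_sensitive(surface: str, policy: str) -> bool:
    if policy == "sensitive":
        return True
    if policy == "insensitive":
        return False
    return len(surface) <= SMART_CASE_MAX_LEN


def _find_occurrences(text: str, surface: str, sensitive: bool) -> List[int]:
    hay = text if sensitive else text.lower()
    needle = surface if sensitive else surface.lower()
    out, i = [], hay.find(needle)
    while i != -1:
        out.append(i)
        i = hay.find(needle, i + 1)
    return out


def find_candidates(
    doc: Document,
    lex: Lexicon,
    cfg: Optional[TaggerConfig] = None,
    tok_cfg: Optional[TokenizerConfig] = None,
) -> Set[Tuple[int, int, str]]:
    """All (start, end, entity_type) lexicon matches, before resolution."""
    cfg = cfg or TaggerConfig()
    tokens = tokenize_text(doc.text, tok_cfg or TokenizerConfig())
    starts = {s for _t, s, _e in tokens}
    ends = {e for _t, _s, e in tokens}
    out: Set[Tuple[int, int, str]] = set()
    for entry in lex.entries:
        sensitive = _case_sensitive(entry.surface, cfg.match_case)
        for i in _find_occurrences(doc.text, entry.surface, sensitive):
            j = i + len(entry.surface)
            if cfg.boundary_required and (i not in starts or j not in ends):
                continue
            out.add((i, j, entry.entity_type))
    return out


def tag_document(
    doc: Document,
    lex: Lexicon,
    cfg: Optional[TaggerConfig] = None,
    tok_cfg: Optional[TokenizerConfig] = None,
) -> Set[Annotation]:
    """String-match tag a document against a (filtered) lexicon.

    Candidates are accepted longest-first, then leftmost; an accepted span
    suppresses everything overlapping it.  When the same span matches under
    both entity types, the ``type_conflict`` policy decides: prefer one type,
    or (default) emit a single annotation flagged ``type_conflict`` for
    human review.  The result is mutually non-overlapping.
    """
    cfg = cfg or TaggerConfig()
    candidates = find_candidates(doc, lex, cfg, tok_cfg)

    by_span: Dict[Tuple[int, int], Set[str]] = {}
    for s, e, t in candidates:
        by_span.setdefault((s, e), set()).add(t)

    resolved: List[Tuple[int, int, str, frozenset]] = []
    for (s, e), types in by_span.items():
        if len(types) == 1:
            resolved.append((s, e, next(iter(types)), frozenset()))
        elif cfg.type_conflict == "prefer_antibody":
            resolved.append((s, e, "Antibody", frozenset()))
        elif cfg.type_conflict == "prefer_antigen":
            resolved.append((s, e, "Antigen", frozenset()))
        else:
            # one flagged annotation; type chosen deterministically
            resolved.append((s, e, "Antibody", frozenset({"type_conflict"})))

    resolved.sort(key=lambda c: (-(c[1] - c[0]), c[0], c[2]))
    accepted: List[Tuple[int, int, str, frozenset]] = []
    for s, e, t, fl in resolved:
        if all(e <= s2 or e2 <= s for s2, e2, _t2, _f in accepted):
            accepted.append((s, e, t, fl))
    return {
        Annotation(doc.doc_id, s, e, t, doc.text[s:e], fl)
        for s, e, t, fl in accepted
    }


@dataclass
class AnnotationDiff:
    """Change summary between an automatic and a revised annotation set.

    Counts are per entity type.  ``removed``/``added`` count annotations with
    no overlapping counterpart (keyed by the auto / revised type resp.);
    ``retyped`` counts same-span pairs whose type changed; ``re_bounded``
    counts overlapping pairs whose span changed (whether or not the type
    also changed).
    """

    added: Dict[str, int] = field(default_factory=dict)
    removed: Dict[str, int] = field(default_factory=dict)
    retyped: Dict[str, int] = field(default_factory=dict)
    re_bounded: Dict[str, int] = field(default_factory=dict)

    def total(self, category: str) -> int:
        return sum(getattr(self, category).values())


def diff_annotations(
    auto: Set[Annotation], revised: Set[Annotation]
) -> AnnotationDiff:
    """Partition the symmetric difference of two sets into change categories.

    Pairs are formed by overlap, preferring same-span pairs, then longest
    overlap, deterministically by position.  Identical annotations cancel out.
    """
    doc_ids = {a.doc_id for a in auto} | {a.doc_id for a in revised}
    if len(doc_ids) > 1:
        raise ValueError(f"annotations from multiple documents: {doc_ids}")

    common = auto & revised
    left = sorted(auto - common)
    right = sorted(revised - common)

    pairs: List[Tuple[Annotation, Annotation]] = []
    candidates = [
        (a, r) for a in left for r in right if a.overlaps(r)
    ]
    # same span first, then longest overlap, then position
    candidates.sort(
        key=lambda p: (
            not p[0].same_span(p[1]),
            -(min(p[0].end, p[1].end) - max(p[0].start, p[1].start)),
            p[0].start, p[1].start,
        )
    )
    used_a: Set[Annotation] = set()
    used_r: Set[Annotation] = set()
    for a, r in candidates:
        if a in used_a or r in used_r:
            continue
        used_a.add(a)
        used_r.add(r)
        pairs.append((a, r))

    diff = AnnotationDiff()

    def bump(counter: Dict[str, int], etype: str) -> None:
        counter[etype] = counter.get(etype, 0) + 1

    for a, r in pairs:
        if a.same_span(r):
            bump(diff.retyped, r.entity_type)
        else:
            bump(diff.re_bounded, r.entity_type)
    for a in left:
        if a not in used_a:
            bump(diff.removed, a.entity_type)
    for r in right:
        if r not in used_r:
            bump(diff.added, r.entity_type)
    return diff
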