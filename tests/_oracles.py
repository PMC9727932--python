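"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's own algorithms: matching is done by
exhaustive search over one-to-one assignments (bitmask DP), tagging by
regex-based substring enumeration, compound splitting by enumerating every
possible split point.
"""

from __future__ import annotations

import re
from functools import lru_cache
from typing import Dict, List, Optional, Sequence, Tuple


def oracle_max_matching(n_left: int, n_right: int, admissible) -> int:
    """Maximum cardinality of a one-to-one matching, by exhaustive search.

    ``admissible(i, j)`` says whether left i may pair with right j.
    """
    pairs = [
        [j for j in range(n_right) if admissible(i, j)]
        for i in range(n_left)
    ]

    @lru_cache(maxsize=None)
    def best(i: int, mask: int) -> int:
        if i == n_left:
            return 0
        out = best(i + 1, mask)
        for j in pairs[i]:
            if not mask & (1 << j):
                out = max(out, 1 + best(i + 1, mask | (1 << j)))
        return out

    result = best(0, 0)
    best.cache_clear()
    return result


def oracle_agreement_counts(
    left: Sequence, right: Sequence
) -> Dict[str, int]:
    """Exhaustive-search agreement categories for one document.

    Maximizes (pairs, FA, CA, PA, DA) lexicographically over all one-to-one
    pairings of overlapping annotations; everything unpaired is SN.
    """

    def category(a, b) -> Optional[str]:
        if not (a.start < b.end and b.start < a.end):
            return None
        if (a.start, a.end) == (b.start, b.end):
            return "FA" if a.entity_type == b.entity_type else "CA"
        return "PA" if a.entity_type == b.entity_type else "DA"

    cats = [[category(a, b) for b in right] for a in left]
    order = {"FA": 0, "CA": 1, "PA": 2, "DA": 3}

    @lru_cache(maxsize=None)
    def best(i: int, mask: int) -> Tuple[int, int, int, int, int]:
        if i == len(left):
            return (0, 0, 0, 0, 0)
        out = best(i + 1, mask)
        for j, cat in enumerate(cats[i]):
            if cat is None or mask & (1 << j):
                continue
            sub = best(i + 1, mask | (1 << j))
            cand = list(sub)
            cand[0] += 1
            cand[1 + order[cat]] += 1
            out = max(out, tuple(cand))
        return out

    k, fa, ca, pa, da = best(0, 0)
    best.cache_clear()
    return {
        "FA": fa, "CA": ca, "PA": pa, "DA": da,
        "SN": (len(left) - k) + (len(right) - k),
    }


_SPLIT_CLASS = re.escape("−~/:+()'][\",_.>*•#-")
_TOKEN_RE = re.compile(rf"[^\s{_SPLIT_CLASS}]+|[{_SPLIT_CLASS}]")


def oracle_token_spans(text: str) -> List[Tuple[int, int]]:
    """Token spans via a regex, independent of the scanning tokenizer."""
    return [m.span() for m in _TOKEN_RE.finditer(text)]


def oracle_tag(text: str, entries, smart_max_len: int = 4) -> set:
    """Dictionary tagging by full substring enumeration + greedy resolution.

    Enumerates every surface at every position, keeps token-boundary
    matches, resolves longest-first then leftmost.  Equal-span type
    conflicts collapse to a single Antibody-typed span (mirroring the
    flagged-conflict convention).
    """
    spans = oracle_token_spans(text)
    starts = {s for s, _ in spans}
    ends = {e for _, e in spans}
    candidates = set()
    for entry in entries:
        surf = entry.surface
        sensitive = len(surf) <= smart_max_len
        for i in range(len(text) - len(surf) + 1):
            window = text[i:i + len(surf)]
            hit = window == surf if sensitive else window.lower() == surf.lower()
            if hit and i in starts and (i + len(surf)) in ends:
                candidates.add((i, i + len(surf), entry.entity_type))
    by_span: Dict[Tuple[int, int], set] = {}
    for s, e, t in candidates:
        by_span.setdefault((s, e), set()).add(t)
    resolved = [
        (s, e, next(iter(ts)) if len(ts) == 1 else "Antibody")
        for (s, e), ts in by_span.items()
    ]
    resolved.sort(key=lambda c: (-(c[1] - c[0]), c[0], c[2]))
    accepted: List[Tuple[int, int, str]] = []
    for s, e, t in resolved:
        if all(e <= s2 or e2 <= s for s2, e2, _ in accepted):
            accepted.append((s, e, t))
    return {(s, e, t) for s, e, t in accepted}


def oracle_compound_splits(name: str) -> List[Tuple[str, str]]:
    """All possible (antigen, antibody) splits of an anti-X-Y compound."""
    if not name.lower().startswith("anti-"):
        return []
    rest = name[5:]
    return [
        (rest[:i], rest[i + 1:])
        for i in range(len(rest))
        if rest[i] == "-" and rest[:i] and rest[i + 1:]
    ]
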