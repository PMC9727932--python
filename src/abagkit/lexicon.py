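"""Antibody/antigen name lexicon: parsing, compound-name extraction, filtering.

The lexicon is the list of known surface forms (antibody clone IDs,
antigen/gene symbols and their synonyms) that drives dictionary-based
pre-annotation.  Raw name tables are noisy: they contain single-letter
protein abbreviations ("E", "G", "S"), plain numbers easily confused with
measurements, and generic words ("antibody", "mab", "fab").  ``filter_lexicon``
removes these classes of misleading entries.  Compound names of the shape
``anti-<antigen>-<antibody>`` (e.g. ``anti-HER2-2Rs15d``) are mined for the
two embedded names via :func:`extract_from_compound`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Tuple

ENTITY_TYPES = ("Antibody", "Antigen")

#: Generic words stripped from lexicons by default; extensible via FilterConfig.
DEFAULT_STOPWORDS = frozenset(
    {"antigen", "antibody", "fab", "mab", "vhh", "mg"}
)

SOURCES = ("table", "compound_extracted", "user")


@dataclass(frozen=True, order=True)
class LexiconEntry:
    """A typed surface form.

    ``surface`` is stored verbatim apart from whitespace trimming; character
    case is never altered because corpus tokens are case sensitive.
    """

    surface: str
    entity_type: str
    source: str = field(default="table", compare=False)

    def __post_init__(self) -> None:
        if not self.surface or self.surface != self.surface.strip():
            raise ValueError(
                f"surface must be non-empty and stripped: {self.surface!r}"
            )
        if self.entity_type not in ENTITY_TYPES:
            raise ValueError(f"unknown entity type: {self.entity_type!r}")
        if self.source not in SOURCES:
            raise ValueError(f"unknown source: {self.source!r}")


@dataclass
class Lexicon:
    """A deduplicated set of :class:`LexiconEntry`.

    Duplicate (surface, entity_type) pairs collapse to one entry.  The same
    surface may appear under both entity types; resolving such conflicts is
    the tagger's job, not the lexicon's.
    """

    entries: set = field(default_factory=set)
    case_policy: str = "smart"  # sensitive | insensitive | smart

    def __post_init__(self) -> None:
        if self.case_policy not in ("sensitive", "insensitive", "smart"):
            raise ValueError(f"unknown case policy: {self.case_policy!r}")
        self.entries = set(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(sorted(self.entries))

    def __contains__(self, item) -> bool:
        return item in self.entries

    def add(self, entry: LexiconEntry) -> None:
        self.entries.add(entry)

    def surfaces(self, entity_type: Optional[str] = None) -> set:
        return {
            e.surface
            for e in self.entries
            if entity_type is None or e.entity_type == entity_type
        }


@dataclass
class FilterConfig:
    """Rules for dropping misleading lexicon names.

    ``min_number``: pure unsigned-integer surfaces strictly below this value
    are removed (they collide with measurements in text).  ``stopwords`` are
    compared lowercase.  ``drop_single_letter`` removes one-character names.
    """

    stopwords: frozenset = DEFAULT_STOPWORDS
    min_number: int = 1000
    drop_single_letter: bool = True

    def __post_init__(self) -> None:
        if self.min_number <= 0:
            raise ValueError("min_number must be positive")
        self.stopwords = frozenset(w.lower() for w in self.stopwords)


class NameTableError(ValueError):
    """A row of a raw name table could not be interpreted."""


def parse_name_table(
    rows: Sequence[Tuple[str, str]], source: str = "table"
) -> Lexicon:
    """Build a deduplicated lexicon from (surface, entity_type) rows.

    Surfaces are whitespace-trimmed but otherwise untouched.  A row whose
    entity type is not ``Antibody`` or ``Antigen`` raises
    :class:`NameTableError` naming the offending row index.
    """
    entries = set()
    for i, (surface, entity_type) in enumerate(rows):
        surface = surface.strip()
        if not surface:
            raise NameTableError(f"row {i}: empty surface")
        if entity_type not in ENTITY_TYPES:
            raise NameTableError(
                f"row {i}: unknown entity type {entity_type!r}"
            )
        entries.add(LexiconEntry(surface, entity_type, source))
    return Lexicon(entries=entries)


def extract_from_compound(
    name: str, split: str = "last"
) -> Optional[Tuple[str, str]]:
    """Split an ``anti-<antigen>-<antibody>`` compound into its two names.

    The leading ``anti-`` is matched case-insensitively.  Because antigen
    names frequently contain hyphens themselves (IL-6R, SARS-CoV-2) while
    antibody clone IDs rarely do, the default splits at the *last* hyphen:
    ``anti-IL-6R-tocilizumab`` -> ``("IL-6R", "tocilizumab")``.  ``split`` may
    be ``"first"`` to split at the first hyphen after the prefix instead.
    Returns ``None`` when the pattern is absent or either side would be empty.
    """
    if split not in ("last", "first"):
        raise ValueError(f"unknown split mode: {split!r}")
    if len(name) < 5 or name[:5].lower() != "anti-":
        return None
    rest = name[5:]
    idx = rest.rfind("-") if split == "last" else rest.find("-")
    if idx <= 0 or idx == len(rest) - 1:
        return None
    antigen, antibody = rest[:idx], rest[idx + 1:]
    return antigen, antibody


def _is_small_number(surface: str, threshold: int) -> bool:
    # Only pure unsigned integer strings qualify; "3.5" or "1e3" do not.
    return surface.isdigit() and int(surface) < threshold


def filter_lexicon(lex: Lexicon, cfg: Optional[FilterConfig] = None) -> Lexicon:
    """Drop misleading entries; keep everything else unchanged.

    Removes single-character surfaces, pure integers below ``cfg.min_number``,
    and surfaces whose lowercase form is a stopword.  Idempotent; the result
    is always a subset of the input.
    """
    cfg = cfg or FilterConfig()

    def keep(e: LexiconEntry) -> bool:
        if cfg.drop_single_letter and len(e.surface) == 1:
            return False
        if _is_small_number(e.surface, cfg.min_number):
            return False
        if e.surface.lower() in cfg.stopwords:
            return False
        return True

    return Lexicon(
        entries={e for e in lex.entries if keep(e)},
        case_policy=lex.case_policy,
    )


def write_lexicon_tsv(lex: Lexicon, path) -> None:
    """Write ``surface<TAB>entity_type`` lines, UTF-8, sorted for stability."""
    lines = [f"{e.surface}\t{e.entity_type}" for e in sorted(lex.entries)]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), "utf-8")


def read_lexicon_tsv(path) -> Lexicon:
    rows = []
    for line in Path(path).read_text("utf-8").splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise NameTableError(f"malformed lexicon line: {line!r}")
        rows.append((parts[0], parts[1]))
    return parse_name_table(rows)


def read_stopwords(path) -> frozenset:
    """One stopword per line; blank lines and '#' comments ignored."""
    words = set()
    for line in Path(path).read_text("utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            words.add(line.lower())
    return frozenset(words)


def build_lexicon(
    rows: Iterable[Tuple[str, str]],
    cfg: Optional[FilterConfig] = None,
    extract_compounds: bool = True,
) -> Lexicon:
    """Full lexicon pipeline: parse, mine compounds, filter.

    Antibody surfaces matching the ``anti-<AG>-<AB>`` pattern contribute
    their embedded antigen and antibody names as additional entries
    (source ``compound_extracted``) before filtering.
    """
    lex = parse_name_table(list(rows))
    if extract_compounds:
        extra = set()
        for e in lex.entries:
            pair = extract_from_compound(e.surface)
            if pair is not None:
                ag, ab = pair
                extra.add(LexiconEntry(ag, "Antigen", "compound_extracted"))
                extra.add(LexiconEntry(ab, "Antibody", "compound_extracted"))
        lex.entries |= extra
    return filter_lexicon(lex, cfg)
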