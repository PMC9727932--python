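"""Document model, tokenization, CoNLL-IOB and BioC-XML input/output.

Abstracts are plain text with standoff annotations: typed character spans
(0-based, half-open, in character units).  Tokenization splits on whitespace
and then again at a fixed set of special characters (hyphens, slashes,
brackets, ...), each emitted as its own token so that character offsets stay
recoverable; token case is never altered.  CoNLL output labels tokens with
the IOB scheme over B/I-Antibody, B/I-Antigen and O.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from lxml import etree

from .lexicon import ENTITY_TYPES

#: Characters that always separate tokens, besides whitespace.  The Unicode
#: minus and bullet occur in PubMed text alongside their ASCII lookalikes.
DEFAULT_SPLIT_CHARS = frozenset("−~/:+()'][\",_.>*•#-")

IOB_LABELS = ("B-Antibody", "I-Antibody", "B-Antigen", "I-Antigen", "O")


class CorpusError(ValueError):
    """Invalid document, annotation, or corpus file."""


@dataclass(frozen=True, order=True)
class Annotation:
    """A typed character span over one document's text."""

    doc_id: str
    start: int
    end: int
    entity_type: str
    text: str
    flags: frozenset = field(default_factory=frozenset, compare=False)

    def __post_init__(self) -> None:
        if self.entity_type not in ENTITY_TYPES:
            raise CorpusError(f"unknown entity type: {self.entity_type!r}")
        if not (0 <= self.start < self.end):
            raise CorpusError(
                f"bad span [{self.start}, {self.end}) in {self.doc_id}"
            )

    def overlaps(self, other: "Annotation") -> bool:
        return self.start < other.end and other.start < self.end

    def same_span(self, other: "Annotation") -> bool:
        return self.start == other.start and self.end == other.end


@dataclass
class Document:
    """An abstract: text, sentence spans, and named annotation sets.

    Annotation sets are keyed by name ("gold", "pred", "annotatorA", ...);
    each is a set of :class:`Annotation` whose covered text must equal the
    document substring.
    """

    doc_id: str
    text: str
    sentences: List[Tuple[int, int]] = field(default_factory=list)
    annotations: Dict[str, Set[Annotation]] = field(default_factory=dict)

    def validate(self) -> None:
        prev_end = 0
        for s, e in self.sentences:
            if not (prev_end <= s < e <= len(self.text)):
                raise CorpusError(
                    f"{self.doc_id}: bad sentence span ({s}, {e})"
                )
            prev_end = e
        for name, anns in self.annotations.items():
            for a in anns:
                if a.doc_id != self.doc_id:
                    raise CorpusError(
                        f"{self.doc_id}: annotation belongs to {a.doc_id}"
                    )
                if a.end > len(self.text):
                    raise CorpusError(
                        f"{self.doc_id}: span [{a.start}, {a.end}) "
                        f"outside text of length {len(self.text)}"
                    )
                covered = self.text[a.start:a.end]
                if a.text != covered:
                    raise CorpusError(
                        f"{self.doc_id}: annotation text {a.text!r} != "
                        f"covered text {covered!r} at [{a.start}, {a.end})"
                    )

    def get_set(self, name: str) -> Set[Annotation]:
        if name not in self.annotations:
            raise CorpusError(f"{self.doc_id}: no annotation set {name!r}")
        return self.annotations[name]


@dataclass
class TokenizerConfig:
    split_chars: frozenset = DEFAULT_SPLIT_CHARS
    keep_separators: bool = True

    def __post_init__(self) -> None:
        if not self.split_chars:
            raise CorpusError("split_chars must be non-empty")
        self.split_chars = frozenset(self.split_chars)


@dataclass
class TokenSequence:
    """Tokens with exact offsets, optional IOB labels, sentence starts.

    ``sentence_starts`` holds token indices beginning each sentence (always
    including 0 when non-empty), so CoNLL writers know where blank lines go.
    """

    tokens: List[Tuple[str, int, int]]
    labels: Optional[List[str]] = None
    sentence_starts: List[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.labels is not None and len(self.labels) != len(self.tokens):
            raise CorpusError("labels and tokens differ in length")
        if self.tokens and not self.sentence_starts:
            self.sentence_starts = [0]

    def token_texts(self) -> List[str]:
        return [t[0] for t in self.tokens]


def tokenize_text(
    text: str, cfg: Optional[TokenizerConfig] = None, offset: int = 0
) -> List[Tuple[str, int, int]]:
    """Split ``text`` on whitespace and the special characters.

    Each special character becomes its own single-character token when
    ``keep_separators``; offsets are absolute (shifted by ``offset``) and
    exact.  Case is preserved.
    """
    cfg = cfg or TokenizerConfig()
    tokens: List[Tuple[str, int, int]] = []
    run_start: Optional[int] = None
    for i, ch in enumerate(text):
        if ch.isspace() or ch in cfg.split_chars:
            if run_start is not None:
                tokens.append((text[run_start:i], offset + run_start, offset + i))
                run_start = None
            if not ch.isspace() and cfg.keep_separators:
                tokens.append((ch, offset + i, offset + i + 1))
        elif run_start is None:
            run_start = i
    if run_start is not None:
        tokens.append((text[run_start:], offset + run_start, offset + len(text)))
    return tokens


def tokenize(doc: Document, cfg: Optional[TokenizerConfig] = None) -> TokenSequence:
    """Tokenize a document sentence by sentence.

    Documents without recorded sentence spans are treated as one sentence.
    """
    cfg = cfg or TokenizerConfig()
    spans = doc.sentences or ([(0, len(doc.text))] if doc.text else [])
    tokens: List[Tuple[str, int, int]] = []
    starts: List[int] = []
    for s, e in spans:
        starts.append(len(tokens))
        tokens.extend(tokenize_text(doc.text[s:e], cfg, offset=s))
    # sentences that tokenized to nothing contribute no boundary
    starts = sorted({i for i in starts if i < len(tokens)})
    return TokenSequence(tokens=tokens, sentence_starts=starts)


def _split_at_boundaries(
    tokens: List[Tuple[str, int, int]], boundaries: Set[int]
) -> List[Tuple[str, int, int]]:
    """Split any token that an annotation boundary falls strictly inside.

    Gold spans are preserved exactly rather than snapped to token edges.
    """
    out: List[Tuple[str, int, int]] = []
    for text, s, e in tokens:
        cuts = sorted(b for b in boundaries if s < b < e)
        prev = s
        for b in cuts + [e]:
            out.append((text[prev - s:b - s], prev, b))
            prev = b
    return out


def to_conll(
    doc: Document,
    set_name: str = "gold",
    cfg: Optional[TokenizerConfig] = None,
) -> TokenSequence:
    """Convert a document's annotation set to IOB-labelled tokens.

    The first token covered by an annotation of type X gets ``B-X``,
    subsequent covered tokens ``I-X``, everything else ``O``.  Overlapping
    annotations within the set are rejected.
    """
    anns = sorted(doc.get_set(set_name))
    for a, b in zip(anns, anns[1:]):
        if a.overlaps(b):
            raise CorpusError(
                f"{doc.doc_id}: overlapping annotations "
                f"[{a.start},{a.end}) and [{b.start},{b.end})"
            )
    seq = tokenize(doc, cfg)
    boundaries = {a.start for a in anns} | {a.end for a in anns}
    sent_offsets = [seq.tokens[i][1] for i in seq.sentence_starts]
    tokens = _split_at_boundaries(seq.tokens, boundaries)

    labels: List[str] = []
    ai = 0
    prev_inside = False
    for text, s, e in tokens:
        while ai < len(anns) and anns[ai].end <= s:
            ai += 1
            prev_inside = False
        if ai < len(anns) and anns[ai].start <= s and e <= anns[ai].end:
            prefix = "I" if prev_inside else "B"
            labels.append(f"{prefix}-{anns[ai].entity_type}")
            prev_inside = True
        else:
            labels.append("O")
            prev_inside = False
    starts = sorted(
        {next(i for i, t in enumerate(tokens) if t[1] >= off)
         for off in sent_offsets}
    ) if tokens else []
    return TokenSequence(tokens=tokens, labels=labels, sentence_starts=starts)


def _valid_transition(prev: Optional[str], label: str) -> bool:
    if not label.startswith("I-"):
        return True
    return prev is not None and prev[2:] == label[2:] and prev != "O"


def from_conll(lines: Iterable[str], doc_id: str = "conll") -> Document:
    """Rebuild a Document from two-column ``token<TAB>label`` lines.

    Tokens are joined with single spaces, sentences likewise (blank lines
    separate sentences).  Annotations are recovered from maximal B/I runs.
    An ``I-X`` with no matching open entity is repaired to ``B-X`` with a
    warning.  Ragged rows are rejected with their line number.  The round
    trip ``to_conll(from_conll(L))`` reproduces L's token and label columns
    for any L produced by :func:`to_conll`.
    """
    sentences_tokens: List[List[Tuple[str, str]]] = [[]]
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            if sentences_tokens[-1]:
                sentences_tokens.append([])
            continue
        parts = line.split("\t")
        if len(parts) != 2 or not parts[0] or parts[1] not in IOB_LABELS:
            raise CorpusError(f"line {lineno}: malformed row {line!r}")
        sentences_tokens[-1].append((parts[0], parts[1]))
    if not sentences_tokens[-1]:
        sentences_tokens.pop()

    text_parts: List[str] = []
    sent_spans: List[Tuple[int, int]] = []
    annotations: Set[Annotation] = set()
    pos = 0
    open_start: Optional[int] = None
    open_type: Optional[str] = None
    open_end: Optional[int] = None

    def close_entity() -> None:
        nonlocal open_start, open_type, open_end
        if open_start is not None:
            covered = "".join(text_parts)[open_start:open_end]
            annotations.add(
                Annotation(doc_id, open_start, open_end, open_type, covered)
            )
        open_start = open_type = open_end = None

    prev_label: Optional[str] = None
    for si, sent in enumerate(sentences_tokens):
        if si > 0:
            text_parts.append(" ")
            pos += 1
        sent_start = pos
        for ti, (tok, label) in enumerate(sent):
            if ti > 0:
                text_parts.append(" ")
                pos += 1
            if label.startswith("I-") and not _valid_transition(prev_label, label):
                warnings.warn(
                    f"illegal {label} start repaired to B-{label[2:]}",
                    stacklevel=2,
                )
                label = "B-" + label[2:]
            s, e = pos, pos + len(tok)
            text_parts.append(tok)
            pos = e
            if label == "O":
                close_entity()
            elif label.startswith("B-"):
                close_entity()
                open_start, open_end, open_type = s, e, label[2:]
            else:  # I-
                open_end = e
            prev_label = label
        close_entity()
        prev_label = None
        sent_spans.append((sent_start, pos))

    return Document(
        doc_id=doc_id,
        text="".join(text_parts),
        sentences=sent_spans,
        annotations={"gold": annotations},
    )


def write_conll(seq: TokenSequence, path) -> None:
    """Write ``token<TAB>label`` lines with blank lines between sentences."""
    labels = seq.labels or ["O"] * len(seq.tokens)
    breaks = set(seq.sentence_starts[1:])
    lines: List[str] = []
    for i, ((tok, _s, _e), lab) in enumerate(zip(seq.tokens, labels)):
        if i in breaks:
            lines.append("")
        lines.append(f"{tok}\t{lab}")
    Path(path).write_text("\n".join(lines) + "\n", "utf-8")


def read_conll(path, doc_id: Optional[str] = None) -> Document:
    p = Path(path)
    return from_conll(
        p.read_text("utf-8").splitlines(), doc_id=doc_id or p.stem
    )


# --- BioC XML ---------------------------------------------------------------
# Dialect: one passage per abstract at offset 0; annotation locations in
# document coordinates; entity type in an infon keyed "type"; annotation set
# name in an infon keyed "set"; sentence offsets as <sentence> elements.


def write_bioc(docs: Sequence[Document], path) -> None:
    collection = etree.Element("collection")
    etree.SubElement(collection, "source").text = "abagkit"
    for doc in docs:
        doc.validate()
        d = etree.SubElement(collection, "document")
        etree.SubElement(d, "id").text = doc.doc_id
        p = etree.SubElement(d, "passage")
        if doc.annotations:
            # empty sets would otherwise vanish on the round trip
            names = etree.SubElement(p, "infon", key="annotation_sets")
            names.text = ",".join(sorted(doc.annotations))
        etree.SubElement(p, "offset").text = "0"
        etree.SubElement(p, "text").text = doc.text
        for s, e in doc.sentences:
            sent = etree.SubElement(p, "sentence")
            etree.SubElement(sent, "offset").text = str(s)
            etree.SubElement(sent, "text").text = doc.text[s:e]
        n = 0
        for set_name in sorted(doc.annotations):
            for a in sorted(doc.annotations[set_name]):
                el = etree.SubElement(p, "annotation", id=f"A{n}")
                n += 1
                t = etree.SubElement(el, "infon", key="type")
                t.text = a.entity_type
                sn = etree.SubElement(el, "infon", key="set")
                sn.text = set_name
                if a.flags:
                    fl = etree.SubElement(el, "infon", key="flags")
                    fl.text = ",".join(sorted(a.flags))
                etree.SubElement(
                    el, "location",
                    offset=str(a.start), length=str(a.end - a.start),
                )
                etree.SubElement(el, "text").text = a.text
    tree = etree.ElementTree(collection)
    tree.write(str(path), xml_declaration=True, encoding="UTF-8",
               pretty_print=True)


def read_bioc(path) -> List[Document]:
    """Read a BioC collection; validates offsets against the passage text."""
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise CorpusError(f"malformed XML in {path}: {exc}") from exc
    docs: List[Document] = []
    for d in tree.getroot().iter("document"):
        doc_id = d.findtext("id") or f"doc{len(docs)}"
        passage = d.find("passage")
        if passage is None:
            raise CorpusError(f"{doc_id}: document has no passage")
        text = passage.findtext("text") or ""
        sentences: List[Tuple[int, int]] = []
        for sent in passage.iter("sentence"):
            off = int(sent.findtext("offset") or 0)
            stext = sent.findtext("text") or ""
            sentences.append((off, off + len(stext)))
        annotations: Dict[str, Set[Annotation]] = {}
        for infon in passage.findall("infon"):
            if infon.get("key") == "annotation_sets" and infon.text:
                for name in infon.text.split(","):
                    annotations.setdefault(name, set())
        for el in passage.iter("annotation"):
            loc = el.find("location")
            if loc is None:
                raise CorpusError(f"{doc_id}: annotation without location")
            start = int(loc.get("offset"))
            end = start + int(loc.get("length"))
            etype = None
            set_name = "gold"
            flags: frozenset = frozenset()
            for infon in el.iter("infon"):
                if infon.get("key") == "type":
                    etype = infon.text
                elif infon.get("key") == "set":
                    set_name = infon.text or "gold"
                elif infon.get("key") == "flags" and infon.text:
                    flags = frozenset(infon.text.split(","))
            if etype not in ENTITY_TYPES:
                raise CorpusError(f"{doc_id}: bad annotation type {etype!r}")
            if end > len(text):
                raise CorpusError(
                    f"{doc_id}: annotation offsets outside text"
                )
            ann = Annotation(doc_id, start, end, etype,
                             el.findtext("text") or text[start:end], flags)
            annotations.setdefault(set_name, set()).add(ann)
        doc = Document(doc_id=doc_id, text=text, sentences=sentences,
                       annotations=annotations)
        doc.validate()
        docs.append(doc)
    return docs
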