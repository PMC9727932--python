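import pytest
from hypothesis import given
from hypothesis import strategies as st

from abagkit import (
    Annotation,
    CorpusError,
    Document,
    from_conll,
    read_bioc,
    to_conll,
    tokenize,
    tokenize_text,
    write_bioc,
)

from _oracles import oracle_token_spans


class TestTokenize:
    def test_special_chars_become_tokens_with_offsets(self):
        assert tokenize_text("anti-HER2") == [
            ("anti", 0, 4), ("-", 4, 5), ("HER2", 5, 9)
        ]

    def test_plain_words(self):
        doc = Document("d", "mEChC6 targets human ABCC6",
                       annotations={"gold": set()})
        assert tokenize(doc).token_texts() == \
            ["mEChC6", "targets", "human", "ABCC6"]

    def test_whitespace_only(self):
        doc = Document("d", " ", annotations={"gold": set()})
        assert tokenize(doc).tokens == []

    def test_unicode_minus_and_ascii_hyphen_equivalent(self):
        assert [t for t, _, _ in tokenize_text("a−b")] == ["a", "−", "b"]
        assert [t for t, _, _ in tokenize_text("a-b")] == ["a", "-", "b"]
        assert [t for t, _, _ in tokenize_text("x•y#z")] == \
            ["x", "•", "y", "#", "z"]

    def test_case_never_altered(self):
        toks = tokenize_text("AbC dEf (GHI)")
        assert "".join(t for t, _, _ in toks) == "AbCdEf(GHI)"

    @given(st.text(min_size=0, max_size=120))
    def test_partition_of_non_whitespace(self, text):
        """Token spans exactly tile the non-whitespace characters."""
        covered = set()
        for tok, s, e in tokenize_text(text):
            assert text[s:e] == tok
            assert not covered & set(range(s, e))
            covered |= set(range(s, e))
        expected = {i for i, c in enumerate(text) if not c.isspace()}
        assert covered == expected

    @given(st.text(min_size=0, max_size=120))
    def test_matches_regex_oracle(self, text):
        assert [(s, e) for _, s, e in tokenize_text(text)] == \
            oracle_token_spans(text)


class TestToConll:
    def test_iob_labels(self, abcc6_doc):
        seq = to_conll(abcc6_doc)
        assert seq.labels == ["B-Antibody", "O", "B-Antigen", "I-Antigen"]

    def test_no_annotations_all_outside(self):
        doc = Document("d", "no entities here", annotations={"gold": set()})
        assert to_conll(doc).labels == ["O", "O", "O"]

    def test_single_token_annotation_is_b_only(self):
        doc = Document("d", "PCSK9 binds", annotations={"gold": {
            Annotation("d", 0, 5, "Antigen", "PCSK9")}})
        assert to_conll(doc).labels == ["B-Antigen", "O"]

    def test_separator_inside_annotation_labelled_inside(self):
        text = "anti-PCSK9 antibody"
        doc = Document("d", text, annotations={"gold": {
            Annotation("d", 5, 10, "Antigen", "PCSK9")}})
        seq = to_conll(doc)
        assert list(zip(seq.token_texts(), seq.labels)) == [
            ("anti", "O"), ("-", "O"), ("PCSK9", "B-Antigen"),
            ("antibody", "O"),
        ]

    def test_boundary_inside_token_splits_token(self):
        # annotation covers "HER2" inside the unbroken token "xHER2y"
        text = "see xHER2y here"
        doc = Document("d", text, annotations={"gold": {
            Annotation("d", 5, 9, "Antigen", "HER2")}})
        seq = to_conll(doc)
        assert list(zip(seq.token_texts(), seq.labels)) == [
            ("see", "O"), ("x", "O"), ("HER2", "B-Antigen"), ("y", "O"),
            ("here", "O"),
        ]

    def test_overlapping_annotations_rejected(self):
        doc = Document("d", "abcdef ghi", annotations={"gold": {
            Annotation("d", 0, 6, "Antigen", "abcdef"),
            Annotation("d", 3, 10, "Antibody", "def ghi")}})
        with pytest.raises(CorpusError, match="overlapping"):
            to_conll(doc)

    def test_adjacent_annotations_both_begin(self):
        doc = Document("d", "PCSK9 1D05", annotations={"gold": {
            Annotation("d", 0, 5, "Antigen", "PCSK9"),
            Annotation("d", 6, 10, "Antibody", "1D05")}})
        assert to_conll(doc).labels == ["B-Antigen", "B-Antibody"]


class TestFromConll:
    def test_round_trip_on_synthetic_corpus(self, small_corpus):
        docs, _ = small_corpus
        for doc in docs:
            seq = to_conll(doc)
            lines = [f"{t}\t{l}" for (t, _, _), l
                     in zip(seq.tokens, seq.labels)]
            # re-insert sentence breaks
            out = []
            breaks = set(seq.sentence_starts[1:])
            for i, line in enumerate(lines):
                if i in breaks:
                    out.append("")
                out.append(line)
            rebuilt = from_conll(out, doc_id=doc.doc_id)
            seq2 = to_conll(rebuilt)
            assert seq2.token_texts() == seq.token_texts()
            assert seq2.labels == seq.labels

    def test_illegal_inside_start_repaired_with_warning(self):
        with pytest.warns(UserWarning, match="repaired"):
            doc = from_conll(["ABCC6\tI-Antigen"])
        (ann,) = doc.annotations["gold"]
        assert (ann.start, ann.end, ann.entity_type) == (0, 5, "Antigen")

    def test_type_switch_without_begin_repaired(self):
        with pytest.warns(UserWarning):
            doc = from_conll(["a\tB-Antigen", "b\tI-Antibody"])
        types = sorted(a.entity_type for a in doc.annotations["gold"])
        assert types == ["Antibody", "Antigen"]

    def test_empty_input(self):
        doc = from_conll([])
        assert doc.text == ""
        assert doc.annotations["gold"] == set()

    def test_ragged_row_rejected_with_line_number(self):
        with pytest.raises(CorpusError, match="line 2"):
            from_conll(["a\tO", "b\tO\textra"])


class TestBioc:
    def test_write_read_identity(self, small_corpus, tmp_path):
        docs, _ = small_corpus
        path = tmp_path / "corpus.xml"
        write_bioc(docs[:5], path)
        back = read_bioc(path)
        assert len(back) == 5
        for a, b in zip(docs[:5], back):
            assert a.doc_id == b.doc_id
            assert a.text == b.text
            assert a.sentences == b.sentences
            assert a.annotations == b.annotations

    def test_minimal_handwritten_file(self, tmp_path):
        xml = """<?xml version='1.0' encoding='UTF-8'?>
<collection><source>test</source><document><id>pmid1</id>
<passage><offset>0</offset><text>PCSK9 is a target</text>
<annotation id="A0"><infon key="type">Antigen</infon>
<location offset="0" length="5"/><text>PCSK9</text></annotation>
</passage></document></collection>"""
        path = tmp_path / "mini.xml"
        path.write_text(xml, "utf-8")
        (doc,) = read_bioc(path)
        (ann,) = doc.annotations["gold"]
        assert (ann.start, ann.end, ann.entity_type, ann.text) == \
            (0, 5, "Antigen", "PCSK9")

    def test_offset_text_disagreement_rejected_with_doc_id(self, tmp_path):
        xml = """<collection><document><id>bad1</id>
<passage><offset>0</offset><text>PCSK9 is a target</text>
<annotation id="A0"><infon key="type">Antigen</infon>
<location offset="0" length="5"/><text>WRONG</text></annotation>
</passage></document></collection>"""
        path = tmp_path / "bad.xml"
        path.write_text(xml, "utf-8")
        with pytest.raises(CorpusError, match="bad1"):
            read_bioc(path)

    def test_malformed_xml_rejected(self, tmp_path):
        path = tmp_path / "broken.xml"
        path.write_text("<collection><docu", "utf-8")
        with pytest.raises(CorpusError, match="malformed"):
            read_bioc(path)

    def test_offsets_outside_text_rejected(self, tmp_path):
        xml = """<collection><document><id>oob</id>
<passage><offset>0</offset><text>short</text>
<annotation id="A0"><infon key="type">Antigen</infon>
<location offset="2" length="50"/><text>x</text></annotation>
</passage></document></collection>"""
        path = tmp_path / "oob.xml"
        path.write_text(xml, "utf-8")
        with pytest.raises(CorpusError, match="oob"):
            read_bioc(path)


def test_document_validate_catches_bad_annotation():
    doc = Document("d", "short", annotations={"gold": {
        Annotation("d", 0, 4, "Antigen", "WRONG")}})
    with pytest.raises(CorpusError):
        doc.validate()
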