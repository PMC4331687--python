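import pytest

from chemner.corpus import (
    CorpusParseError,
    Document,
    Mention,
    MentionValidationError,
    lint_annotations,
    rank_mentions,
    read_abstracts,
    read_annotations,
    read_predictions,
    resolve_nested,
    write_abstracts,
    write_annotations,
    write_predictions,
)


def M(doc="d", sec="A", start=0, end=5, text=None, **kw):
    return Mention(doc, sec, start, end,
                   text if text is not None else "x" * (end - start), **kw)


class TestAbstracts:
    def test_three_field_line_roundtrip(self, tmp_path):
        p = tmp_path / "abs.tsv"
        p.write_text("23064325\tSomeTitle\tSomeAbstract\n", encoding="utf-8")
        docs = read_abstracts(p)
        assert docs == [Document("23064325", "SomeTitle", "SomeAbstract")]
        write_abstracts(docs, p)
        assert read_abstracts(p) == docs

    def test_empty_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "abs.tsv"
        p.write_text("", encoding="utf-8")
        assert read_abstracts(p) == []

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "abs.tsv"
        p.write_text("ok\tt\ta\nbad\tonly-two\n", encoding="utf-8")
        with pytest.raises(CorpusParseError, match=":2"):
            read_abstracts(p)


class TestAnnotations:
    def test_span_length_must_match_text(self, tmp_path):
        p = tmp_path / "ann.tsv"
        p.write_text("23064325\tA\t1138\t1152\tpolysorbate 80\tTRIVIAL\n",
                     encoding="utf-8")
        (m,) = read_annotations(p)
        assert m.end - m.start == 14 == len("polysorbate 80")
        assert m.cem_class == "TRIVIAL"

    @pytest.mark.parametrize("line", [
        "X\tT\t3\t3\tabc\tFAMILY",     # empty span
        "X\tT\t0\t3\tabcd\tFAMILY",    # length 4 != 3
    ])
    def test_invalid_record_raises(self, tmp_path, line):
        p = tmp_path / "ann.tsv"
        p.write_text(line + "\n", encoding="utf-8")
        with pytest.raises(MentionValidationError):
            read_annotations(p)

    def test_drop_invalid_discards_with_warning(self, tmp_path):
        p = tmp_path / "ann.tsv"
        p.write_text("X\tT\t0\t3\tabcd\tFAMILY\nY\tA\t0\t2\tab\t\n",
                     encoding="utf-8")
        with pytest.warns(UserWarning):
            kept = read_annotations(p, drop_invalid=True)
        assert [m.doc_id for m in kept] == ["Y"]

    def test_gold_roundtrip_lossless(self, tmp_path):
        mentions = [
            Mention("1", "A", 0, 5, "abcde", cem_class="FORMULA"),
            Mention("2", "T", 3, 7, "wxyz", cem_class=None),
        ]
        p = tmp_path / "ann.tsv"
        write_annotations(mentions, p)
        back = read_annotations(p)
        assert [(m.doc_id, m.section, m.start, m.end, m.text, m.cem_class)
                for m in back] == [
            (m.doc_id, m.section, m.start, m.end, m.text, m.cem_class)
            for m in mentions]

    def test_lint_reports_substring_mismatch(self):
        doc = Document("1", "alpha beta", "")
        good = Mention("1", "T", 0, 5, "alpha")
        bad = Mention("1", "T", 0, 5, "lphab")
        issues = lint_annotations([good, bad], [doc])
        assert len(issues) == 1 and "lphab" in issues[0]


class TestResolveNested:
    def test_keeps_larger_of_nested_pair(self):
        outer = M(start=1138, end=1152)
        inner = M(start=1138, end=1149)
        assert resolve_nested([inner, outer]) == [outer]

    def test_disjoint_spans_untouched(self):
        a, b = M(start=0, end=5), M(start=10, end=15)
        assert resolve_nested([a, b]) == [a, b]

    def test_chain_of_containment_keeps_maximal(self):
        # Brute-force pairwise containment keeping maximal spans.
        a, b, c = M(start=0, end=10), M(start=0, end=6), M(start=2, end=6)
        assert resolve_nested([a, b, c]) == [a]

    def test_partial_overlap_both_kept(self):
        a, b = M(start=0, end=6), M(start=4, end=10)
        assert resolve_nested([a, b]) == [a, b]

    def test_idempotent_and_no_growth(self):
        ms = [M(start=0, end=10), M(start=2, end=6), M(start=8, end=14)]
        once = resolve_nested(ms)
        assert resolve_nested(once) == once
        assert len(once) <= len(ms)

    def test_different_sections_not_nested(self):
        a = M(sec="T", start=0, end=10)
        b = M(sec="A", start=2, end=6)
        assert resolve_nested([a, b]) == [a, b]


class TestPredictions:
    def test_single_record_serialization(self, tmp_path):
        p = tmp_path / "pred.tsv"
        write_predictions([M(doc="1", start=5, end=9, confidence=0.9)], p)
        assert p.read_text() == "1\tA:5:9\t1\t0.900000\n"

    def test_rank_by_descending_confidence(self, tmp_path):
        p = tmp_path / "pred.tsv"
        low = M(start=0, end=2, confidence=0.8)
        high = M(start=5, end=9, confidence=0.9)
        write_predictions([low, high], p)
        lines = p.read_text().splitlines()
        assert lines[0].endswith("A:5:9\t1\t0.900000")
        assert lines[1].endswith("A:0:2\t2\t0.800000")

    def test_equal_confidence_tie_breaks_on_span(self):
        a = M(start=10, end=12, confidence=0.7)
        b = M(start=3, end=5, confidence=0.7)
        ranked = rank_mentions([a, b])
        assert [(m.start, r) for m, r in ranked] == [(3, 1), (10, 2)]

    def test_missing_confidence_errors(self, tmp_path):
        with pytest.raises(ValueError, match="confidence"):
            write_predictions([M()], tmp_path / "p.tsv")

    def test_prediction_file_roundtrip_keys(self, tmp_path):
        p = tmp_path / "pred.tsv"
        ms = [M(doc="7", start=4, end=9, confidence=0.5)]
        write_predictions(ms, p)
        back = read_predictions(p)
        assert [m.key for m in back] == [m.key for m in ms]
        assert back[0].confidence == pytest.approx(0.5)
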