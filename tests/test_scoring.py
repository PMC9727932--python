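import random

import pytest

from abagkit import (
    AgreementReport,
    Annotation,
    compute_prf,
    evaluate_documents,
    f1_score,
    match_annotations,
    multi_agreement,
    pairwise_agreement,
)
from abagkit.scoring import _agreement_counts

from conftest import random_annotations
from _oracles import oracle_agreement_counts, oracle_max_matching


def ann(doc, s, e, t):
    return Annotation(doc, s, e, t, "x" * (e - s))


class TestMatchModes:
    def test_identity_matches_in_every_mode(self):
        g = {ann("d", 0, 5, "Antibody")}
        for mode in ("strict", "type_relax", "span_relax", "both_relax"):
            tp, fp, fn, _ = match_annotations(g, set(g), mode)
            assert (tp, fp, fn) == (1, 0, 0)

    def test_span_mismatch(self):
        # gold "human ABCC6" vs predicted "ABCC6"
        gold = {Annotation("d", 0, 11, "Antigen", "human ABCC6")}
        pred = {Annotation("d", 6, 11, "Antigen", "ABCC6")}
        assert match_annotations(gold, pred, "strict")[:3] == (0, 1, 1)
        assert match_annotations(gold, pred, "span_relax")[:3] == (1, 0, 0)

    def test_type_mismatch(self):
        gold = {ann("d", 0, 5, "Antibody")}
        pred = {ann("d", 0, 5, "Antigen")}
        assert match_annotations(gold, pred, "strict")[0] == 0
        assert match_annotations(gold, pred, "type_relax")[0] == 1
        assert match_annotations(gold, pred, "span_relax")[0] == 0
        assert match_annotations(gold, pred, "both_relax")[0] == 1

    def test_disjoint_spans_never_match(self):
        gold = {ann("d", 0, 5, "Antigen")}
        pred = {ann("d", 5, 9, "Antigen")}  # touching, no shared character
        for mode in ("strict", "type_relax", "span_relax", "both_relax"):
            assert match_annotations(gold, pred, mode)[0] == 0

    def test_mixed_doc_ids_rejected(self):
        with pytest.raises(ValueError):
            match_annotations({ann("a", 0, 2, "Antibody")},
                              {ann("b", 0, 2, "Antibody")})

    def test_matching_is_optimal_not_greedy(self):
        # a greedy pairing of the wide gold to the wide pred leaves the
        # narrow pred unmatched; optimal matching pairs both
        gold = {ann("d", 0, 10, "Antigen"), ann("d", 9, 12, "Antigen")}
        pred = {ann("d", 0, 12, "Antigen"), ann("d", 9, 10, "Antigen")}
        tp, fp, fn, _ = match_annotations(gold, pred, "span_relax")
        assert (tp, fp, fn) == (2, 0, 0)


class TestAgainstOracle:
    def test_counts_equal_exhaustive_search(self):
        """Evaluator equals brute-force matching on 500 random documents."""
        rng = random.Random(99)
        for i in range(500):
            gold = sorted(random_annotations(rng, f"d{i}", 40, max_n=8))
            pred = sorted(random_annotations(rng, f"d{i}", 40, max_n=8))
            for mode in ("strict", "type_relax", "span_relax", "both_relax"):
                tp, fp, fn, _ = match_annotations(gold, pred, mode)
                from abagkit.scoring import _admissible
                expect = oracle_max_matching(
                    len(gold), len(pred),
                    lambda a, b: _admissible(gold[a], pred[b], mode),
                )
                assert tp == expect
                assert fp == len(pred) - expect
                assert fn == len(gold) - expect

    def test_relax_monotonicity(self):
        """strict <= type_relax and strict <= span_relax <= both_relax."""
        rng = random.Random(7)
        for i in range(300):
            gold = random_annotations(rng, f"d{i}", 30, max_n=6)
            pred = random_annotations(rng, f"d{i}", 30, max_n=6)
            tp = {m: match_annotations(gold, pred, m)[0]
                  for m in ("strict", "type_relax", "span_relax",
                            "both_relax")}
            assert tp["strict"] <= tp["type_relax"] <= tp["both_relax"]
            assert tp["strict"] <= tp["span_relax"] <= tp["both_relax"]

    def test_agreement_categories_equal_exhaustive_search(self):
        rng = random.Random(31)
        for i in range(300):
            a = sorted(random_annotations(rng, f"d{i}", 30, max_n=6))
            b = sorted(random_annotations(rng, f"d{i}", 30, max_n=6))
            assert _agreement_counts(a, b) == oracle_agreement_counts(a, b)


class TestComputePrf:
    @pytest.mark.parametrize("p,r,f1", [
        (86.15, 90.36, 88.20),
        (74.60, 81.84, 78.05),
        (78.40, 84.72, 81.44),
    ])
    def test_f1_arithmetic(self, p, r, f1):
        assert round(f1_score(p, r), 2) == f1

    def test_f1_of_equal_pr(self):
        assert f1_score(73.0, 73.0) == pytest.approx(73.0)

    def test_zero_denominators_give_zero(self):
        report = compute_prf({"Antibody": (0, 0, 0)})
        t = report.per_type["Antibody"]
        assert (t.precision, t.recall, t.f1) == (0.0, 0.0, 0.0)

    def test_micro_pools_counts(self):
        report = compute_prf({"Antibody": (8, 2, 1), "Antigen": (12, 3, 4)})
        m = report.micro
        assert (m.tp, m.fp, m.fn) == (20, 5, 5)
        assert m.precision == pytest.approx(80.0)
        assert m.support == 25

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_prf({"Antibody": (1, -1, 0)})


class TestAgreement:
    def test_formulas_on_published_components(self):
        r = AgreementReport.from_components(86.54, 0.20, 2.46, 0.03, 10.77)
        assert r.strict_f1 == pytest.approx(91.46, abs=0.02)
        assert r.relax_f1 == pytest.approx(94.31, abs=0.02)

    def test_identical_sets_full_agreement(self):
        a = {ann("d", 0, 5, "Antigen"), ann("d", 10, 20, "Antibody")}
        r = pairwise_agreement(a, set(a))
        assert r.fa == 100.0 and r.sn == 0.0
        assert r.strict_f1 == r.relax_f1 == 100.0

    def test_half_partial_agreement(self):
        a = {ann("d", 0, 5, "Antigen"), ann("d", 10, 20, "Antibody")}
        b = {ann("d", 0, 5, "Antigen"), ann("d", 12, 20, "Antibody")}
        r = pairwise_agreement(a, b)
        assert (r.fa, r.pa, r.sn) == (50.0, 50.0, 0.0)
        assert r.strict_f1 == pytest.approx(50.0)
        assert r.relax_f1 == pytest.approx(100.0)

    def test_empty_vs_empty_degenerate(self):
        r = pairwise_agreement(set(), set())
        assert r.degenerate
        assert r.strict_f1 == r.relax_f1 == 100.0

    def test_symmetry_and_sum_to_100(self):
        rng = random.Random(5)
        for i in range(200):
            a = random_annotations(rng, f"d{i}", 30, max_n=6)
            b = random_annotations(rng, f"d{i}", 30, max_n=6)
            r1 = pairwise_agreement(a, b)
            r2 = pairwise_agreement(b, a)
            assert (r1.fa, r1.ca, r1.pa, r1.da, r1.sn) == \
                (r2.fa, r2.ca, r2.pa, r2.da, r2.sn)
            if not r1.degenerate:
                assert r1.fa + r1.ca + r1.pa + r1.da + r1.sn == \
                    pytest.approx(100.0)

    def test_components_must_sum_to_100(self):
        with pytest.raises(ValueError):
            AgreementReport.from_components(50, 0, 0, 0, 40)


class TestMultiAgreement:
    def test_three_identical_sets(self):
        a = {ann("d", 0, 5, "Antigen")}
        r = multi_agreement([a, set(a), set(a)])
        assert r.fa == 100.0 and r.strict_f1 == 100.0

    def test_two_sets_equal_pairwise(self):
        rng = random.Random(13)
        a = random_annotations(rng, "d", 30, max_n=6)
        b = random_annotations(rng, "d", 30, max_n=6)
        assert multi_agreement([a, b]).to_dict() == \
            pairwise_agreement(a, b).to_dict()

    def test_one_deletion_pools_as_expected(self):
        full = {ann("d", 0, 5, "Antigen"), ann("d", 10, 14, "Antibody")}
        partial = {ann("d", 0, 5, "Antigen")}
        r = multi_agreement([full, set(full), partial])
        # pairs: (1,2): 2 FA; (1,3) and (2,3): 1 FA + 1 SN each
        # pooled: FA=4, SN=2, units=6
        assert r.counts == {"FA": 4, "CA": 0, "PA": 0, "DA": 0, "SN": 2}
        assert r.fa == pytest.approx(100 * 4 / 6)
        assert r.sn == pytest.approx(100 * 2 / 6)
        # strict F1 = (400/6)/(100 - (200/6)/2) * 100
        assert r.strict_f1 == pytest.approx(
            (400 / 6) / (100 - (100 / 6)) * 100
        )

    def test_fewer_than_two_sets_rejected(self):
        with pytest.raises(ValueError):
            multi_agreement([set()])


def test_evaluate_documents_micro(small_corpus):
    docs, _ = small_corpus
    for d in docs:
        d.annotations["predcopy"] = set(d.annotations["gold"])
    report = evaluate_documents(docs, "gold", "predcopy", "strict")
    m = report.micro
    assert m.precision == m.recall == 100.0
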