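"""Overlap matching, metric arithmetic, agreement, adjudication."""

import random

import networkx as nx
import pytest
from hypothesis import given, settings, strategies as st

from spokenmeds import (
    AnnotationSet,
    apply_adjudication,
    build_adjudication,
    compute_metrics,
    evaluate,
    evaluate_corpus,
    iaa,
    match_overlap,
)
from spokenmeds.evaluation import percent

from conftest import make_ann, make_set


class TestComputeMetrics:
    # printed (TP, FP, FN) rows with their published percentage cells
    @pytest.mark.parametrize(
        "tp,fp,fn,p,r,f",
        [
            (291, 46, 40, 86.4, 87.9, 87.1),      # validation set
            (1062, 168, 206, 86.3, 83.8, 85.0),   # evaluation set
            (1119, 2814, 163, 28.5, 87.3, 42.9),  # cTAKES baseline
            (830, 1215, 292, 40.6, 74.0, 52.4),   # MedEx-UIMA baseline
            (832, 318, 432, 72.3, 65.8, 68.9),    # MedXN baseline
        ],
    )
    def test_reproduces_published_rows(self, tp, fp, fn, p, r, f):
        rep = compute_metrics(tp, fp, fn)
        assert (rep.precision_pct, rep.recall_pct, rep.f_score_pct) == (p, r, f)

    def test_degenerate_denominators_are_zero(self):
        rep = compute_metrics(0, 0, 0)
        assert (rep.precision, rep.recall, rep.f_score) == (0.0, 0.0, 0.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(-1, 0, 0)

    def test_f_between_p_and_r(self):
        rep = compute_metrics(50, 30, 10)
        assert min(rep.precision, rep.recall) <= rep.f_score \
            <= max(rep.precision, rep.recall)

    def test_percent_rounds_half_away_from_zero(self):
        assert percent(0.86345) == 86.3
        assert percent(0.8625) == 86.3  # .25 rounds up, not to even
        assert percent(1.0) == 100.0


class TestMatchOverlap:
    def test_partial_overlap_is_a_match(self):
        m = match_overlap(make_set([(0, 8)]), make_set([(0, 3)]))
        assert len(m.pairs) == 1 and not m.unmatched_gold

    def test_identical_sets_fully_matched(self):
        spans = [(0, 5), (10, 15), (20, 30)]
        m = match_overlap(make_set(spans), make_set(spans))
        assert len(m.pairs) == 3
        assert not m.unmatched_gold and not m.unmatched_pred

    def test_disjoint_sets_no_pairs(self):
        m = match_overlap(make_set([(0, 5)]), make_set([(10, 15)]))
        assert not m.pairs
        assert len(m.unmatched_gold) == len(m.unmatched_pred) == 1

    def test_one_to_one_prediction_cannot_absorb_two_golds(self):
        m = match_overlap(make_set([(0, 5), (5, 10)]), make_set([(0, 10)]))
        assert len(m.pairs) == 1 and len(m.unmatched_gold) == 1

    def test_tie_broken_by_smaller_predicted_start(self):
        m = match_overlap(make_set([(5, 9)]), make_set([(3, 7), (7, 11)]))
        (pair,) = m.pairs
        assert pair[1].start == 3

    def _greedy_count(self, gold, pred):
        return len(match_overlap(make_set(gold), make_set(pred)).pairs)

    def _max_matching_count(self, gold, pred):
        """Independent oracle: maximum-cardinality bipartite matching over
        the overlap graph."""
        g = nx.Graph()
        g.add_nodes_from(("g", i) for i in range(len(gold)))
        g.add_nodes_from(("p", i) for i in range(len(pred)))
        for i, (gs, ge) in enumerate(gold):
            for j, (ps, pe) in enumerate(pred):
                if min(ge, pe) - max(gs, ps) > 0:
                    g.add_edge(("g", i), ("p", j))
        return len(nx.bipartite.maximum_matching(
            g, top_nodes=[("g", i) for i in range(len(gold))])) // 2

    def test_greedy_matches_maximum_matching_on_random_instances(self):
        rng = random.Random(20260101)
        for _ in range(200):
            gold = [(s, s + rng.randint(1, 6))
                    for s in rng.sample(range(40), rng.randint(0, 8))]
            pred = [(s, s + rng.randint(1, 6))
                    for s in rng.sample(range(40), rng.randint(0, 8))]
            assert self._greedy_count(gold, pred) == \
                self._max_matching_count(gold, pred), (gold, pred)


class TestEvaluate:
    def test_hand_counted_mixed_case(self):
        rep = evaluate(make_set([(0, 7), (20, 30)]), make_set([(3, 9), (40, 45)]))
        assert (rep.tp, rep.fp, rep.fn) == (1, 1, 1)
        assert rep.precision_pct == rep.recall_pct == rep.f_score_pct == 50.0

    def test_perfect_prediction(self):
        rep = evaluate(make_set([(0, 5), (9, 14)]), make_set([(0, 5), (9, 14)]))
        assert rep.precision == rep.recall == rep.f_score == 1.0

    def test_empty_prediction(self):
        rep = evaluate(make_set([(0, 5)]), make_set([]))
        assert (rep.precision, rep.recall) == (0.0, 0.0)

    def test_doc_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            evaluate(make_set([], doc_id="a"), make_set([], doc_id="b"))

    def test_duplicate_spans_deduplicated_before_counting(self):
        gold = make_set([(0, 5), (0, 5)])
        rep = evaluate(gold, make_set([(0, 5)]))
        assert (rep.tp, rep.fp, rep.fn) == (1, 0, 0)

    @given(st.lists(st.tuples(st.integers(0, 30), st.integers(1, 6)), max_size=6),
           st.lists(st.tuples(st.integers(0, 30), st.integers(1, 6)), max_size=6))
    @settings(max_examples=150)
    def test_swapping_arguments_swaps_p_and_r(self, a, b):
        sa = make_set([(s, s + n) for s, n in a])
        sb = make_set([(s, s + n) for s, n in b])
        fwd, rev = evaluate(sa, sb), evaluate(sb, sa)
        assert (fwd.tp, fwd.fp, fwd.fn) == (rev.tp, rev.fn, rev.fp)
        assert fwd.precision == rev.recall and fwd.recall == rev.precision
        assert fwd.f_score == pytest.approx(rev.f_score)

    def test_corpus_micro_average_pools_counts(self):
        docs = [
            (make_set([(0, 5)], doc_id="a"), make_set([(0, 5)], doc_id="a")),
            (make_set([(0, 5)], doc_id="b"), make_set([(9, 12)], doc_id="b")),
        ]
        rep = evaluate_corpus(docs)
        assert (rep.tp, rep.fp, rep.fn) == (1, 1, 1)
        assert set(rep.per_document) == {"a", "b"}


class TestIaa:
    def test_identical_sets(self):
        assert iaa(make_set([(0, 5)]), make_set([(0, 5)])) == 1.0

    def test_disjoint_nonempty_sets(self):
        assert iaa(make_set([(0, 5)]), make_set([(9, 12)])) == 0.0

    def test_three_vs_one_with_one_match(self):
        a = make_set([(0, 5), (10, 15), (20, 25)])
        b = make_set([(0, 5)])
        assert iaa(a, b) == 0.5  # 2*1 / (3+1)

    def test_both_empty_defined_as_one(self):
        assert iaa(make_set([]), make_set([])) == 1.0

    def test_symmetric(self):
        a = make_set([(0, 5), (8, 12)])
        b = make_set([(3, 7)])
        assert iaa(a, b) == iaa(b, a)


class TestAdjudication:
    def test_identical_sets_all_agreed(self):
        q = build_adjudication(make_set([(0, 5)]), make_set([(0, 5)]))
        assert len(q.agreed) == 1 and not q.disputed

    def test_single_annotator_annotation_is_disputed(self):
        q = build_adjudication(make_set([(0, 5)]), make_set([]))
        assert not q.agreed and len(q.disputed) == 1

    def test_overlap_counts_as_agreement_with_span_from_a(self):
        q = build_adjudication(make_set([(0, 8)]), make_set([(0, 3)]))
        assert [a.span for a in q.agreed] == [(0, 8)] and not q.disputed

    def test_union_span_mode(self):
        q = build_adjudication(make_set([(2, 8)]), make_set([(0, 5)]),
                               span_from="union")
        assert [a.span for a in q.agreed] == [(0, 8)]

    def test_all_reject_keeps_only_agreed(self):
        q = build_adjudication(make_set([(0, 5), (10, 14)]), make_set([(0, 5)]))
        gold = apply_adjudication(
            q, {d: "reject" for d in q.disputed}, doc_id="d"
        )
        assert gold.spans() == [(0, 5)]

    def test_all_keep_recovers_union(self):
        a, b = make_set([(0, 5)]), make_set([(10, 14)])
        q = build_adjudication(a, b)
        gold = apply_adjudication(q, {d: "keep" for d in q.disputed}, doc_id="d")
        assert gold.spans() == [(0, 5), (10, 14)]

    def test_agreed_plus_kept_plus_extras_count(self):
        a = make_set([(0, 5), (10, 14), (20, 24)])
        b = make_set([(0, 5), (10, 14), (30, 34)])
        q = build_adjudication(a, b)
        decisions = {d: ("keep" if d.span == (20, 24) else "reject")
                     for d in q.disputed}
        gold = apply_adjudication(q, decisions, extras=[make_ann(40, 44)],
                                  doc_id="d")
        assert len(gold) == 4

    def test_undecided_item_rejected_with_listing(self):
        q = build_adjudication(make_set([(0, 5)]), make_set([]))
        with pytest.raises(ValueError, match=r"\[0,5\)"):
            apply_adjudication(q, {}, doc_id="d")
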