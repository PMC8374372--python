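"""Overlap-based span evaluation, inter-annotator agreement, adjudication.

A gold and a predicted annotation count as a match when their character
spans overlap at all — the lenient criterion appropriate for compound
medication names, where one annotator marks "flu shot" and the other "flu".
Matching is one-to-one (a single prediction cannot absorb several gold
mentions) and maximum-cardinality: a greedy largest-overlap pass seeds the
pairing and augmenting paths repair the rare instances where pure greedy
assignment would strand a matchable pair.  Precision, recall and F-score
follow from the matched-pair count;
corpora pool TP/FP/FN across documents (micro-average).

Inter-annotator agreement is positive (proportionate) agreement
``2m / (|a| + |b|)`` with ``m`` overlap-matched pairs — the standard
corpus-linguistics agreement measure when true negatives are undefined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .annotate import Annotation, AnnotationSet

__all__ = [
    "Matching",
    "EvalReport",
    "AdjudicationQueue",
    "match_overlap",
    "compute_metrics",
    "evaluate",
    "evaluate_corpus",
    "iaa",
    "iaa_corpus",
    "build_adjudication",
    "apply_adjudication",
    "dedupe_spans",
    "percent",
]


def percent(proportion: float) -> float:
    """Display rounding: proportion -> percentage with one decimal, rounding
    half away from zero (so 0.86345 -> 86.3, 0.87915 -> 87.9)."""
    return float(
        Decimal(proportion * 100).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    )


@dataclass
class Matching:
    """One-to-one overlap matching between a gold and a predicted set."""

    pairs: list[tuple[Annotation, Annotation]]
    unmatched_gold: list[Annotation]
    unmatched_pred: list[Annotation]


@dataclass
class EvalReport:
    """TP/FP/FN counts with derived precision, recall and F-score
    (proportions in [0, 1]; use :attr:`precision_pct` etc. for display)."""

    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f_score: float
    per_document: dict[str, "EvalReport"] = field(default_factory=dict)

    @property
    def precision_pct(self) -> float:
        return percent(self.precision)

    @property
    def recall_pct(self) -> float:
        return percent(self.recall)

    @property
    def f_score_pct(self) -> float:
        return percent(self.f_score)


def dedupe_spans(anns: AnnotationSet) -> AnnotationSet:
    """One annotation per distinct (start, end) span, first in sort order."""
    seen, kept = set(), []
    for a in anns:
        if a.span not in seen:
            seen.add(a.span)
            kept.append(a)
    return AnnotationSet(anns.doc_id, kept)


def _overlap(a: Annotation, b: Annotation) -> int:
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def match_overlap(gold: AnnotationSet, pred: AnnotationSet) -> Matching:
    """One-to-one maximum-cardinality matching on span overlap.

    A greedy pass iterates gold annotations by (start, end) and pairs each
    with the still-unmatched predicted annotation of maximal positive
    character overlap, ties broken by the smaller predicted start.  Greedy
    assignment alone can strand a matchable pair (about 3% of random dense
    instances), so an augmenting-path repair then grows the matching to
    maximum cardinality, re-pairing greedy choices only when that recovers
    an otherwise unmatched annotation.  Deterministic for fixed input.
    """
    golds = sorted(gold, key=lambda a: (a.start, a.end))
    preds = sorted(pred, key=lambda a: (a.start, a.end))
    # adjacency: predicted indices overlapping each gold, best overlap first
    adj = [
        sorted(
            (j for j, p in enumerate(preds) if _overlap(g, p) > 0),
            key=lambda j: (-_overlap(g, preds[j]), preds[j].start, preds[j].end),
        )
        for g in golds
    ]
    match_of_pred: dict[int, int] = {}  # pred index -> gold index
    match_of_gold: dict[int, int] = {}
    for gi in range(len(golds)):  # greedy seeding
        for j in adj[gi]:
            if j not in match_of_pred:
                match_of_pred[j] = gi
                match_of_gold[gi] = j
                break

    def augment(gi: int, seen: set[int]) -> bool:
        for j in adj[gi]:
            if j in seen:
                continue
            seen.add(j)
            holder = match_of_pred.get(j)
            if holder is None or augment(holder, seen):
                match_of_pred[j] = gi
                match_of_gold[gi] = j
                return True
        return False

    for gi in range(len(golds)):
        if gi not in match_of_gold:
            augment(gi, set())

    pairs = [(golds[gi], preds[j]) for gi, j in sorted(match_of_gold.items())]
    unmatched_gold = [g for gi, g in enumerate(golds) if gi not in match_of_gold]
    unmatched_pred = [p for j, p in enumerate(preds) if j not in match_of_pred]
    return Matching(pairs, unmatched_gold, unmatched_pred)


def compute_metrics(tp: int, fp: int, fn: int) -> EvalReport:
    """Precision, recall and F-score from raw counts.

    ``P = tp/(tp+fp)``, ``R = tp/(tp+fn)``, ``F = 2PR/(P+R)`` computed on
    unrounded P and R; each metric is 0 when its denominator is 0.
    """
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return EvalReport(tp=tp, fp=fp, fn=fn, precision=p, recall=r, f_score=f)


def evaluate(gold: AnnotationSet, pred: AnnotationSet) -> EvalReport:
    """Score one document: overlap-match after span-deduplication, then
    derive metrics from the pair/unmatched counts."""
    if gold.doc_id != pred.doc_id:
        raise ValueError(
            f"document mismatch: gold {gold.doc_id!r} vs pred {pred.doc_id!r}"
        )
    m = match_overlap(dedupe_spans(gold), dedupe_spans(pred))
    return compute_metrics(len(m.pairs), len(m.unmatched_pred), len(m.unmatched_gold))


def evaluate_corpus(
    docs: list[tuple[AnnotationSet, AnnotationSet]]
) -> EvalReport:
    """Score a corpus of (gold, pred) pairs by pooling TP/FP/FN across
    documents (micro-average); per-document reports are attached."""
    tp = fp = fn = 0
    per_doc = {}
    for gold, pred in docs:
        rep = evaluate(gold, pred)
        per_doc[gold.doc_id] = rep
        tp, fp, fn = tp + rep.tp, fp + rep.fp, fn + rep.fn
    pooled = compute_metrics(tp, fp, fn)
    pooled.per_document = per_doc
    return pooled


def iaa(a: AnnotationSet, b: AnnotationSet) -> float:
    """Positive agreement between two annotators on one document:
    ``2m / (|a| + |b|)`` with overlap counting as agreement.  Symmetric;
    defined as 1.0 when both sets are empty."""
    a, b = dedupe_spans(a), dedupe_spans(b)
    if not len(a) and not len(b):
        return 1.0
    m = len(match_overlap(a, b).pairs)
    return 2 * m / (len(a) + len(b))


def iaa_corpus(docs: list[tuple[AnnotationSet, AnnotationSet]]) -> float:
    """Pooled positive agreement across documents."""
    total_m = total_n = 0
    for a, b in docs:
        a, b = dedupe_spans(a), dedupe_spans(b)
        total_m += len(match_overlap(a, b).pairs)
        total_n += len(a) + len(b)
    return 2 * total_m / total_n if total_n else 1.0


@dataclass
class AdjudicationQueue:
    """Agreement partition of two annotators' sets: overlap-matched
    annotations are agreed (span taken from annotator a by default);
    annotations present in exactly one set await a keep/reject decision."""

    agreed: list[Annotation]
    disputed: list[Annotation]


def build_adjudication(
    a: AnnotationSet, b: AnnotationSet, *, span_from: str = "a"
) -> AdjudicationQueue:
    """Partition two annotators' work into agreed and disputed annotations.

    ``span_from="a"`` keeps annotator a's span for agreed pairs;
    ``span_from="union"`` takes the union of the two spans.
    """
    if a.doc_id != b.doc_id:
        raise ValueError(f"document mismatch: {a.doc_id!r} vs {b.doc_id!r}")
    m = match_overlap(dedupe_spans(a), dedupe_spans(b))
    if span_from == "a":
        agreed = [ga for ga, _ in m.pairs]
    elif span_from == "union":
        from dataclasses import replace

        agreed = []
        for ga, pb in m.pairs:
            start, end = min(ga.start, pb.start), max(ga.end, pb.end)
            agreed.append(replace(ga, start=start, end=end, covered_text=""))
    else:
        raise ValueError(f"unknown span_from {span_from!r}")
    return AdjudicationQueue(
        agreed=agreed, disputed=[*m.unmatched_gold, *m.unmatched_pred]
    )


def apply_adjudication(
    queue: AdjudicationQueue,
    decisions: dict[Annotation, str],
    extras: list[Annotation] = (),
    *,
    doc_id: str = "",
) -> AnnotationSet:
    """Resolve an adjudication queue into a gold-standard set.

    Every disputed annotation needs a "keep" or "reject" decision; ``extras``
    are mentions missed by both annotators, added by the adjudicator.  The
    result is agreed + kept + extras, span-deduplicated.
    """
    undecided = [d for d in queue.disputed if d not in decisions]
    if undecided:
        raise ValueError(
            "undecided disputed annotation(s): "
            + ", ".join(f"[{d.start},{d.end}) {d.covered_text!r}" for d in undecided)
        )
    bad = {v for v in decisions.values()} - {"keep", "reject"}
    if bad:
        raise ValueError(f"unknown decision(s): {sorted(bad)}")
    kept = [d for d in queue.disputed if decisions[d] == "keep"]
    return dedupe_spans(
        AnnotationSet(doc_id, [*queue.agreed, *kept, *extras])
    )
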