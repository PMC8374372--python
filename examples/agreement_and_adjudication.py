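"""Inter-annotator agreement and adjudication on one document.

Two simulated annotators mark medication mentions in the same transcript;
overlapping spans count as agreement ("flu shot" vs "flu" is a match).  The
example reports positive agreement, builds the adjudication queue, resolves
the disputes, and scores one annotator against the merged gold standard.
"""

from spokenmeds import (
    Annotation,
    AnnotationSet,
    apply_adjudication,
    build_adjudication,
    evaluate,
    iaa,
)

text = "PT: I got my flu shot and I take aspirin and fish oil every night.\n"
#       0123456789...
ann = lambda s, e: Annotation(s, e, text[s:e], "MEDICATION")

annotator_a = AnnotationSet("visit", [ann(13, 21), ann(33, 40), ann(45, 53)])
annotator_b = AnnotationSet("visit", [ann(13, 16), ann(33, 40)])
for name, anns in (("A", annotator_a), ("B", annotator_b)):
    print(f"annotator {name}:", [a.covered_text for a in anns])

agreement = iaa(annotator_a, annotator_b)
print(f"\npositive agreement 2m/(|A|+|B|) = {agreement:.3f}")

queue = build_adjudication(annotator_a, annotator_b)
print("agreed:  ", [a.covered_text for a in queue.agreed])
print("disputed:", [a.covered_text for a in queue.disputed])

# the adjudicator keeps the disputed 'fish oil' mention
gold = apply_adjudication(
    queue, {d: "keep" for d in queue.disputed}, doc_id="visit"
)
print("gold:    ", [a.covered_text for a in gold])

report = evaluate(gold, annotator_b)
print(f"\nannotator B vs gold: TP={report.tp} FP={report.fp} FN={report.fn} "
      f"-> P={report.precision_pct} R={report.recall_pct} F={report.f_score_pct}")
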