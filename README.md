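# spokenmeds

Rule-based annotation of **medication mentions in transcripts of primary-care
visit conversations**, with the span-overlap evaluation protocol used to score
such systems.

Conversations between patients and clinicians are a very different substrate
from clinical notes: they are punctuation-light, full of fillers ("um",
"aha"), and everyday words double as drug names ("today" is also ToDAY, a
veterinary antibiotic in the UMLS; "gold" is a registered medication). A
plain dictionary lookup over a drug vocabulary therefore drowns in false
positives, while missing lay mentions such as "flu shot" or over-the-counter
supplements. This package is for clinical-NLP practitioners and research
teams who need a transparent, auditable medication annotator for
conversational transcripts — e.g. to index visit recordings so patients can
revisit what was said about their medications.

## The method

Candidates come from **sentence-windowed dictionary matching** against a
concept lexicon (surface term → concept id, UMLS semantic types/TUIs,
preferred text), followed by **most-specific-span consumption**: a hit whose
span is strictly contained in another hit is discarded ("colon cancer"
suppresses "colon" and "cancer"). Candidates can also be ingested from
cTAKES CAS-XMI output. A six-stage cascade then edits the candidate set:

| stage | action | rule |
|---|---|---|
| 1 common words | remove | mention is one of the most common English words, unless on a 24-word exception list (17 common drug names + herb/supplement/vitamin (+plurals) + "flu") |
| 2 chemical elements | remove | mention names one of 71 elements not typically taken as medication (gold, potassium, ...; iron/zinc/calcium deliberately not listed) |
| 3 semantic types | remove | all drug-relevant TUIs of the concept are in {T114, T122, T123, T125, T130, T197} (nucleic acids, biomedical materials, biologically active substances, hormones, reagents, inorganic chemicals) |
| 4 allergens | remove | concept's preferred text contains "allergenic" ("Coconut allergenic extract") |
| 5 immunizations | add | a **diagnosis** annotation sharing a sentence with "vaccine", "shot", "booster" or "pill" is re-annotated as a medication over the diagnosis span |
| 6 supplements | add | matches of a common herb/supplement dictionary become medications unless already covered |

Evaluation follows the span-overlap protocol: a gold and a predicted
annotation match when their character spans overlap at all (one-to-one,
maximum cardinality), then micro-averaged `P = TP/(TP+FP)`,
`R = TP/(TP+FN)`, `F = 2PR/(P+R)`. Inter-annotator agreement is positive
agreement `2m/(|A|+|B|)`, and a two-annotator adjudication merge
(agreed + kept disputes + adjudicator extras) builds gold standards.

Because real visit transcripts contain protected health information, the
package ships a deterministic **synthetic corpus generator** (dyadic DR:/PT:
conversations with planted mentions and per-stage false-positive traps) and
a ~340-entry synthetic fixture lexicon standing in for the
non-redistributable RxNorm/SNOMED-CT dictionary.

## Worked example

```python
from spokenmeds import (Transcript, default_filter_config,
                        load_default_lexicon, run_pipeline)

text = ("DR: Your labs came back fine today.\n"
        "PT: My ring is white gold, does that matter?\n"
        "DR: No. Did you get your flu shot this year?\n"
        "PT: Yes, and I still take my insulin and my lisinopril.\n")
result = run_pipeline(Transcript("demo", text),
                      load_default_lexicon(), default_filter_config())
```

Running `python examples/annotate_transcript.py` (the same text) prints:

```
Final medication mentions:
  [106,109)  'flu'          via immunization_addition
  [155,162)  'insulin'      via dictionary
  [170,180)  'lisinopril'   via dictionary

Removals and additions along the cascade:
  removed 'today'        at stage common_word (common_word)
  removed 'gold'         at stage chemical_element (chemical_element)
  added   'flu'          at stage immunization_addition (trigger_cooccurrence)
```

"today" and "gold" were dictionary hits (both are drug names) removed by
stages 1 and 2; "flu" alone is a diagnosis, but co-occurring with the
trigger "shot" it is added back as a medication; "insulin" is a common word
that survives via the exception list. Every decision carries an audit
record, exportable with the annotations as Knowtator/eHOST XML or JSON
standoff (see `examples/standoff_io.py`).

The other examples: `examples/evaluate_synthetic_corpus.py` scores the
pipeline on a generated corpus and ablates each stage (full cascade:
P = R = F = 100.0 on 120 planted mentions; e.g. switching off the
common-word filter drops precision to 75.0);
`examples/agreement_and_adjudication.py` walks through IAA and adjudication.

A thin CLI wraps the same library calls:

```sh
spokenmeds gen-fixtures --n-docs 10 --seed 1 --out corpus/
spokenmeds annotate corpus/corpus out/
spokenmeds evaluate corpus/ out/ --report report.tsv
spokenmeds iaa annotatorA/ annotatorB/
```

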