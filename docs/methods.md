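# Methods

This note documents the annotation model, its tunable constants, the
synthetic evaluation corpus, and the numerical and design choices the
implementation makes where more than one reasonable option existed.

## Pipeline model and assumptions

The annotator treats medication-mention detection as dictionary lookup plus
rule-based repair, not as sequence labelling. The underlying assumptions:

* The inventory of medication names is effectively closed (drug
  vocabularies enumerate it), so recall is primarily a dictionary-coverage
  problem and precision a word-sense problem.
* Transcribed conversation is punctuation-light and sentence boundaries are
  noisy, so no stage may depend on parse trees or part-of-speech tags.
* Every systematic false-positive class observed in conversational text —
  common words that double as drug names, chemical elements, non-drug
  biochemical semantic classes, allergen-extract concepts — can be removed
  by an independent set-membership test, which keeps every decision
  auditable.

Processing order: sentence segmentation → sentence-windowed token-sequence
matching → most-specific-span consumption → the four removal filters →
the two addition stages → final consumption and span-deduplication.
Removal filters are set-intersection tests and commute with each other;
their order only determines which stage an audit record attributes a
removal to (presentation order is used). Additions run after removals and
bypass them; the "flu" entry on the exception list exists so that
dictionary-derived "flu" mentions also survive stage 1.

### Candidate generation

Tokens are alphanumeric runs; internal apostrophes stay inside a token
("john's"), hyphens break tokens (drug names are rarely hyphen-internal,
and conversational transcription uses hyphens erratically). A multi-token
term matches only when the gap between its tokens is pure whitespace, so
every candidate's covered text normalizes back to a lexicon term (no
"colon . cancer" matches). Matches never cross sentence boundaries,
mirroring the sentence lookup window of the dictionary annotator this
pipeline post-processes.

A hit becomes a MEDICATION candidate when its semantic types intersect the
drug-like candidate TUIs *or* the six excluded TUIs. The union is
deliberate: the reference dictionary annotator emits hormones, inorganic
chemicals, etc. as medication mentions, and removing them is the
semantic-type filter's job. Without the union the filter would be dead code
on native matches and the trap-ablation experiments could not demonstrate
its effect. Disorder-type TUIs yield DIAGNOSIS candidates (the input to the
immunization stage); hits with neither type are discarded.

### Span consumption

`consume_most_specific` removes every annotation whose span is a *proper*
subset of another annotation's span. Identical spans are never consumed
(two concepts may legitimately share a surface form); overlap without
containment keeps both. The operation is idempotent and independent of
input order, and is verified against a brute-force pairwise oracle.

## Tunable constants (defaults)

| constant | default | rationale |
|---|---|---|
| excluded TUIs | T114, T122, T123, T125, T130, T197 | the six published semantic classes that produce almost exclusively false positives |
| chemical elements | 71 names | the published list; element *names* only, never symbols ("Au" would collide with conversational text); elements in therapeutic use (iron, zinc, calcium, magnesium, lithium, iodine, selenium) deliberately absent |
| trigger words | vaccine, shot, booster, pill | whole-token, case-insensitive, within the diagnosis's sentence; substring matching would fire on "pillow" |
| exception list | 24 words | 17 single-token common medication names (only "ambien" and "insulin" are fixed by the published rule; the other 15 are an editable package default) + herb/supplement/vitamin and plurals + "flu" |
| allergen marker | "allergenic" | case-insensitive substring of the concept's preferred text |
| candidate TUIs | T109, T110, T116, T121, T127, T195, T200 | drug-like UMLS classes mirroring a MedicationMention's coverage |
| diagnosis TUIs | T019–T050 (disorder types), T184, T190, T191 | standard disorder semantic group |
| TUI filter mode | "all" | remove only when *every* drug-relevant TUI is excluded; a term that is both hormone and pharmacologic substance survives. Whether the original rule removed mixed-TUI terms is unknowable without the source data, so `"any"` is available as a configuration |

The common-word list bundled with the package is a curated ~1.2k-entry
subset built from genuinely common-English sources (a 980-word common-words
dataset plus standard stop words plus hand-curated conversational and
drug-ambiguous terms); it stands in for the 10 000-word Google Trillion
Word Corpus list, which `scripts/vendor_common_words.py` vendors verbatim
when a network is available. Element names are excluded from the bundled
list so each removal is attributable to exactly one stage. The supplement
list and the ~340-entry concept lexicon are likewise authored synthetic
stand-ins (their filenames say so) for the non-redistributable MedlinePlus
index and RxNorm/SNOMED-CT dictionary.

## Sentence segmentation

Deterministic and rule-based: breaks at newlines (transcripts are
turn-per-line) and at runs of `.?!` followed by whitespace and a capital
letter, guarded by a small abbreviation list (personal titles and single
initials). Sentence spans are trimmed to their non-whitespace extent; text
without terminal punctuation is one sentence. The segmenter is pluggable —
any list of half-open spans covering the non-whitespace text is accepted.

## Evaluation protocol

Overlap matching is one-to-one and maximum-cardinality: a greedy pass
visits gold annotations in (start, end) order and pairs each with the
unmatched prediction of largest character overlap (ties to the smaller
predicted start), then an augmenting-path repair grows the matching to
maximum cardinality. Pure greedy assignment strands a matchable pair on
roughly 3% of dense random instances (e.g. gold {[16,19), [20,25)} vs
predicted {[17,20), [16,22)}), which would undercount true positives, so
the repair step is part of the protocol; it is verified against an
independent maximum-matching oracle. One-to-one pairing prevents a single
wide prediction from absorbing several gold mentions.

Counts pool across documents before metrics (micro-average). Metrics are
computed on unrounded proportions; each is defined as 0 when its
denominator is 0; percentage display rounds half away from zero to one
decimal. Inter-annotator agreement is positive agreement `2m/(|A|+|B|)` —
chance-corrected coefficients are out of scope because true negatives are
undefined for span annotation — and is 1.0 by convention when both sets are
empty. In adjudication, the span of an agreed pair is taken from annotator
A (configurable to span-union); both conventions appear in practice and
overlap scoring makes the choice nearly immaterial.

Annotation sets are span-deduplicated before scoring, so multiple concepts
on one span count once.

## Synthetic corpus: what it does and does not show

Each generated document alternates DR:/PT: turns built from sentence
templates with conversational noise, planting at recorded offsets: true
medication mentions (drawn from the fixture lexicon, including multi-word
and exception-list names), supplement mentions recoverable only through the
supplement dictionary, immunization mentions (diagnosis + trigger in one
sentence), and one trap per filter stage per document by default
(common-word drugs like "today"/"sonata", filler abbreviations "aha"/"hmm",
elements, excluded-TUI terms, allergen extracts, and trigger-less diagnoses
that the immunization stage must ignore). Gold is the planted true mentions
only. Documents are generated from a seeded generator with the document
index mixed into the seed: independent but reproducible.

Template vocabulary is deliberately disjoint from the lexicon, supplement
and trigger vocabularies, so the corpus is *separable*: with the full
cascade the pipeline scores P = R = 1.0, and disabling any one stage
strictly hurts exactly one metric. This validates the plumbing — stage
logic, span arithmetic, audit bookkeeping, format round-trips — not
real-world accuracy. Real transcripts contain out-of-lexicon lay terms,
ambiguity the rules cannot resolve ("clot", lab-result discussions),
transcription errors, and overlapping trap categories; published
performance on real conversations is in the mid-80s percent, not 100.

## Problem sizes and runtime

Default verification sizes: a 50-document synthetic corpus (~300 planted
gold mentions) for end-to-end recovery and ablations, 1000 random instances
each for the consumption and matching oracles, and 200 random annotation
sets for standoff round-trips. The full test suite runs in a few seconds on
one CPU; the acceptance script in well under a minute.

## Known limitations

* Dictionary coverage bounds recall; there is no fuzzy or contextual
  matching, and no negation or speaker attribution ("I stopped the
  statin" still yields a mention — by design, mentions are the unit).
* Contiguous matching only; token-order permutations within a lookup
  window are not attempted.
* Dosage, frequency, route and relation extraction are out of scope.
* The semantic-type filter's mixed-TUI behaviour ("all" vs "any") is a
  documented choice, configurable because the original rule is
  under-specified.
* The bundled lexicon is a fixture: real deployments should vendor a
  licensed RxNorm/SNOMED-CT dictionary in the same TSV schema
  (`term, concept_id, tuis, preferred_text, source`).
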