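"""The filter/addition cascade: four false-positive removal filters and two
addition stages, composed into the published pipeline.

Removal stages (applied to medication candidates, in presentation order):

1. **common_word** — drop single-token candidates that are common English
   words (e.g. "today", which is also ToDAY, a veterinary antibiotic),
   unless on the 24-word exception list (common medication names like
   "insulin", generic terms like "vitamin", and "flu").
2. **chemical_element** — drop the 71 chemical elements not typically taken
   as medication or supplement ("gold", "potassium", ...).
3. **semantic_type** — drop candidates whose UMLS semantic types fall in the
   six excluded TUIs (hormones, inorganic chemicals, reagents, ...).
4. **allergen** — drop allergen-extract concepts, recognized by the word
   "allergenic" in their preferred text ("Coconut allergenic extract").

Addition stages (applied after the filters; additions bypass the filters):

5. **immunization_addition** — a diagnosis annotation sharing a sentence
   with "vaccine", "shot", "booster" or "pill" is re-annotated as a
   medication over the diagnosis span ("Did you get your flu shot?").
6. **supplement_addition** — matches of a common herb/supplement dictionary
   become medication annotations unless already covered by an existing one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .annotate import (
    DIAGNOSIS,
    MEDICATION,
    Annotation,
    AnnotationSet,
    AuditRecord,
    Transcript,
    consume_most_specific,
    find_term_matches,
    match_candidates,
    _TOKEN,
)
from .lexicon import (
    CANDIDATE_TUIS,
    FilterConfig,
    Lexicon,
    TermList,
    WordList,
    normalize_term,
)

__all__ = [
    "PipelineResult",
    "filter_common_words",
    "filter_chemical_elements",
    "filter_semantic_types",
    "filter_allergens",
    "add_immunizations",
    "add_supplements",
    "run_pipeline",
    "STAGES",
]

#: Stage names in cascade order; also the valid keys for stage toggles.
STAGES = (
    "common_word",
    "chemical_element",
    "semantic_type",
    "allergen",
    "immunization_addition",
    "supplement_addition",
)


@dataclass
class PipelineResult:
    """Final medication annotations plus full audit and per-stage counts."""

    final: AnnotationSet
    audit: list[AuditRecord]
    stage_counts: dict[str, tuple[int, int, int]]  # stage -> (kept, removed, added)

    @property
    def n_candidates(self) -> int:
        """Medication candidates entering the cascade (post span-consumption)."""
        kept, removed, _ = self.stage_counts["candidates"]
        return kept + removed


def _apply_removal(
    anns: AnnotationSet, stage: str, reason: str, should_remove
) -> AnnotationSet:
    kept, audit = [], []
    for a in anns:
        if should_remove(a):
            audit.append(AuditRecord(a, stage, "removed", reason))
        else:
            kept.append(a)
    return anns.with_annotations(kept, audit)


def filter_common_words(
    anns: AnnotationSet, common: WordList, exceptions: WordList
) -> AnnotationSet:
    """Remove candidates whose normalized text is a common English word and
    not on the exception list.  Multi-word spans never match a single-token
    word list, so only single-token candidates are affected."""
    return _apply_removal(
        anns,
        "common_word",
        "common_word",
        lambda a: (t := normalize_term(a.covered_text)) in common
        and t not in exceptions,
    )


def filter_chemical_elements(
    anns: AnnotationSet, elements: WordList
) -> AnnotationSet:
    """Remove candidates naming one of the filtered chemical elements."""
    return _apply_removal(
        anns,
        "chemical_element",
        "chemical_element",
        lambda a: normalize_term(a.covered_text) in elements,
    )


def filter_semantic_types(
    anns: AnnotationSet,
    excluded_tuis: frozenset[str],
    candidate_tuis: frozenset[str] = CANDIDATE_TUIS,
    mode: str = "all",
) -> AnnotationSet:
    """Remove candidates carrying excluded semantic types.

    In the default ``mode="all"`` an annotation is removed only when every
    drug-relevant TUI it carries is excluded (a term that is both a hormone
    and a pharmacologic substance survives); ``mode="any"`` removes on any
    excluded TUI.
    """
    if mode not in ("all", "any"):
        raise ValueError(f"unknown semantic-type filter mode {mode!r}")
    drug_tuis = candidate_tuis - excluded_tuis

    def should_remove(a: Annotation) -> bool:
        if not a.tuis & excluded_tuis:
            return False
        return mode == "any" or not (a.tuis & drug_tuis)

    return _apply_removal(anns, "semantic_type", "semantic_type", should_remove)


def filter_allergens(anns: AnnotationSet, marker: str) -> AnnotationSet:
    """Remove candidates whose preferred text contains the allergen marker
    (case-insensitive substring, default "allergenic")."""
    marker = marker.lower()
    return _apply_removal(
        anns,
        "allergen",
        "allergen",
        lambda a: marker in a.preferred_text.lower(),
    )


def add_immunizations(
    transcript: Transcript,
    diagnosis_anns: AnnotationSet,
    trigger_words: frozenset[str],
) -> list[Annotation]:
    """Medication annotations for diagnoses co-occurring with a trigger word.

    For each diagnosis annotation whose sentence also contains a trigger
    word as a whole token (case-insensitive), emit a MEDICATION annotation
    over the diagnosis span.  One annotation per distinct span.
    """
    triggers = {t.lower() for t in trigger_words}
    added: dict[tuple[int, int], Annotation] = {}
    for a in diagnosis_anns:
        if a.label != DIAGNOSIS or a.span in added:
            continue
        sent = transcript.sentence_at(a.start)
        if sent is None:
            continue
        tokens = {t.lower() for t in _TOKEN.findall(transcript.sentence_text(sent))}
        if tokens & triggers:
            added[a.span] = replace(
                a, label=MEDICATION, provenance="immunization_addition"
            )
    return list(added.values())


def add_supplements(
    transcript: Transcript,
    supplements: TermList,
    existing: AnnotationSet,
) -> list[Annotation]:
    """Medication annotations for herb/supplement dictionary matches.

    Maximal sentence-internal matches of supplement terms become MEDICATION
    annotations; matches whose span is contained in (or equal to) an existing
    retained annotation's span are suppressed.
    """
    matches = find_term_matches(transcript, supplements.terms)
    spans = {(s, e) for s, e, _ in matches}
    existing_spans = existing.spans()
    added = []
    for start, end, term in sorted(matches):
        contained_in_match = any(
            s <= start and end <= e and (s, e) != (start, end) for s, e in spans
        )
        covered = any(s <= start and end <= e for s, e in existing_spans)
        if contained_in_match or covered:
            continue
        added.append(
            Annotation(
                start=start,
                end=end,
                covered_text=transcript.text[start:end],
                label=MEDICATION,
                preferred_text=term,
                provenance="supplement_addition",
            )
        )
    return added


def run_pipeline(
    transcript: Transcript,
    lexicon: Lexicon,
    config: FilterConfig,
    *,
    disabled_stages: frozenset[str] | set[str] = frozenset(),
) -> PipelineResult:
    """Run the full cascade on one transcript.

    segment -> dictionary match -> most-specific-span consumption -> the
    four removal filters in order -> the two addition stages -> final span
    consumption and deduplication.  ``disabled_stages`` (names from
    :data:`STAGES`) switches individual stages off for ablation.

    Returns the final MEDICATION annotations with the complete audit trail;
    identical output for identical input and configuration.
    """
    unknown = set(disabled_stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    if not transcript.sentences:
        transcript.segment()

    candidates = match_candidates(
        transcript,
        lexicon,
        config.candidate_tuis,
        diagnosis_tuis=config.diagnosis_tuis,
        excluded_tuis=config.excluded_tuis,
    )
    consumed = consume_most_specific(candidates)
    meds = AnnotationSet(
        transcript.doc_id, consumed.filtered(MEDICATION), consumed.audit
    )
    diagnoses = AnnotationSet(transcript.doc_id, consumed.filtered(DIAGNOSIS))

    stage_counts: dict[str, tuple[int, int, int]] = {
        "candidates": (len(meds), len(candidates.filtered(MEDICATION)) - len(meds), 0)
    }

    def record(stage: str, before: int, after: AnnotationSet) -> None:
        stage_counts[stage] = (len(after), before - len(after), 0)

    if "common_word" not in disabled_stages:
        n = len(meds)
        meds = filter_common_words(meds, config.common_words, config.exception_words)
        record("common_word", n, meds)
    if "chemical_element" not in disabled_stages:
        n = len(meds)
        meds = filter_chemical_elements(meds, config.chemical_elements)
        record("chemical_element", n, meds)
    if "semantic_type" not in disabled_stages:
        n = len(meds)
        meds = filter_semantic_types(
            meds, config.excluded_tuis, config.candidate_tuis, config.tui_filter_mode
        )
        record("semantic_type", n, meds)
    if "allergen" not in disabled_stages:
        n = len(meds)
        meds = filter_allergens(meds, config.allergen_marker)
        record("allergen", n, meds)

    if "immunization_addition" not in disabled_stages:
        added = add_immunizations(transcript, diagnoses, config.trigger_words)
        meds = meds.with_annotations(
            [*meds, *added],
            [AuditRecord(a, "immunization_addition", "added", "trigger_cooccurrence")
             for a in added],
        )
        stage_counts["immunization_addition"] = (len(meds), 0, len(added))
    if "supplement_addition" not in disabled_stages:
        added = add_supplements(transcript, config.supplement_terms, meds)
        meds = meds.with_annotations(
            [*meds, *added],
            [AuditRecord(a, "supplement_addition", "added", "supplement_dictionary")
             for a in added],
        )
        stage_counts["supplement_addition"] = (len(meds), 0, len(added))

    n = len(meds)
    meds = consume_most_specific(meds)
    # span-deduplication: one annotation per distinct span in the final output
    seen: set[tuple[int, int]] = set()
    kept, audit = [], []
    for a in meds:
        if a.span in seen:
            audit.append(AuditRecord(a, "dedup", "removed", "duplicate_span"))
        else:
            seen.add(a.span)
            kept.append(a)
    meds = meds.with_annotations(kept, audit)
    stage_counts["finalize"] = (len(meds), n - len(meds), 0)

    return PipelineResult(final=meds, audit=list(meds.audit), stage_counts=stage_counts)
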