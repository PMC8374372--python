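"""The four removal filters, the two addition stages, and the full cascade."""

import pytest

from spokenmeds import (
    MEDICATION,
    Annotation,
    AnnotationSet,
    Transcript,
    add_immunizations,
    add_supplements,
    filter_allergens,
    filter_chemical_elements,
    filter_common_words,
    filter_semantic_types,
    run_pipeline,
    write_json,
)
from spokenmeds.filters import STAGES
from spokenmeds.lexicon import TermList, WordList


def med(start, end, text, tuis=(), preferred=""):
    return Annotation(
        start=start, end=end, covered_text=text, label=MEDICATION,
        tuis=frozenset(tuis), preferred_text=preferred or text,
    )


def med_set(*anns):
    return AnnotationSet("doc", anns)


COMMON = WordList(frozenset({"today", "insulin", "flu", "aha"}), "common")
EXCEPTIONS = WordList(frozenset({"insulin", "flu"}), "exceptions")


class TestCommonWordFilter:
    def test_common_word_removed(self):
        out = filter_common_words(med_set(med(0, 5, "today")), COMMON, EXCEPTIONS)
        assert len(out) == 0
        assert out.audit[0].reason == "common_word"

    def test_exception_word_kept(self):
        out = filter_common_words(med_set(med(0, 7, "Insulin")), COMMON, EXCEPTIONS)
        assert len(out) == 1

    def test_non_member_kept(self):
        out = filter_common_words(med_set(med(0, 9, "metformin")), COMMON, EXCEPTIONS)
        assert len(out) == 1

    def test_multiword_span_never_matches_single_token_list(self):
        out = filter_common_words(
            med_set(med(0, 8, "flu shot")),
            WordList(frozenset({"flu", "shot"})), EXCEPTIONS,
        )
        assert len(out) == 1


class TestChemicalElementFilter:
    ELEMENTS = WordList(frozenset({"gold", "potassium"}), "elements")

    @pytest.mark.parametrize(
        "text,kept", [("Gold", 0), ("potassium", 0), ("iron", 1)]
    )
    def test_membership(self, text, kept):
        out = filter_chemical_elements(
            med_set(med(0, len(text), text)), self.ELEMENTS
        )
        assert len(out) == kept


class TestSemanticTypeFilter:
    EXCLUDED = frozenset({"T114", "T122", "T123", "T125", "T130", "T197"})

    @pytest.mark.parametrize(
        "tuis,kept",
        [({"T125"}, 0), ({"T121"}, 1), ({"T197"}, 0), ({"T125", "T121"}, 1)],
    )
    def test_all_mode(self, tuis, kept):
        out = filter_semantic_types(
            med_set(med(0, 4, "term", tuis=tuis)), self.EXCLUDED
        )
        assert len(out) == kept

    def test_any_mode_removes_mixed_tuis(self):
        out = filter_semantic_types(
            med_set(med(0, 4, "term", tuis={"T125", "T121"})),
            self.EXCLUDED, mode="any",
        )
        assert len(out) == 0

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            filter_semantic_types(med_set(), self.EXCLUDED, mode="maybe")


class TestAllergenFilter:
    @pytest.mark.parametrize(
        "preferred,kept",
        [
            ("Coconut allergenic extract", 0),
            ("Lisinopril", 1),
            ("ALLERGENIC extract, ragweed", 0),
        ],
    )
    def test_marker_substring(self, preferred, kept):
        out = filter_allergens(
            med_set(med(0, 4, "term", preferred=preferred)), "allergenic"
        )
        assert len(out) == kept


TRIGGERS = frozenset({"vaccine", "shot", "booster", "pill"})


def diagnosis_at(transcript, term):
    start = transcript.text.index(term)
    return AnnotationSet(
        transcript.doc_id,
        [Annotation(start, start + len(term), term, "DIAGNOSIS",
                    concept_id="C_dx")],
    )


class TestImmunizationAddition:
    def test_trigger_in_sentence_adds_medication_over_diagnosis_span(self):
        t = Transcript("d", "Did you get your flu shot?").segment()
        (a,) = add_immunizations(t, diagnosis_at(t, "flu"), TRIGGERS)
        assert (a.covered_text, a.label) == ("flu", MEDICATION)
        assert a.provenance == "immunization_addition"

    def test_no_trigger_no_addition(self):
        t = Transcript("d", "She had chickenpox as a kid.").segment()
        assert add_immunizations(t, diagnosis_at(t, "chickenpox"), TRIGGERS) == []

    def test_booster_trigger(self):
        t = Transcript("d", "You are due for a tetanus booster.").segment()
        (a,) = add_immunizations(t, diagnosis_at(t, "tetanus"), TRIGGERS)
        assert a.covered_text == "tetanus"

    def test_trigger_must_be_whole_token(self):
        t = Transcript("d", "I fluffed the pillow with my tetanus hands.").segment()
        assert add_immunizations(t, diagnosis_at(t, "tetanus"), TRIGGERS) == []

    def test_trigger_in_other_sentence_does_not_fire(self):
        t = Transcript("d", "I had the flu. Then a shot of espresso.").segment()
        assert add_immunizations(t, diagnosis_at(t, "flu"), TRIGGERS) == []


class TestSupplementAddition:
    SUPPS = TermList(frozenset({"ginkgo", "fish oil"}), "supps")

    def test_supplement_term_added(self):
        t = Transcript("d", "I started taking ginkgo").segment()
        (a,) = add_supplements(t, self.SUPPS, AnnotationSet("d"))
        assert a.covered_text == "ginkgo"
        assert a.provenance == "supplement_addition"

    def test_span_covered_by_existing_annotation_suppressed(self):
        t = Transcript("d", "I take fish oil daily").segment()
        existing = AnnotationSet("d", [med(7, 15, "fish oil")])
        assert add_supplements(t, self.SUPPS, existing) == []

    def test_empty_supplement_list(self):
        t = Transcript("d", "I take fish oil daily").segment()
        assert add_supplements(t, TermList(frozenset()), AnnotationSet("d")) == []


CASCADE_TEXT = (
    "DR: Your labs show gold levels are fine.\n"
    "PT: I got my flu shot today at the pharmacy.\n"
    "DR: Keep taking the insulin and the lisinopril.\n"
)


class TestRunPipeline:
    def test_cascade_hand_trace(self, lexicon, config):
        """today -> common-word removal, gold -> element removal, flu ->
        immunization addition, insulin -> exception survivor, lisinopril ->
        plain dictionary survivor."""
        t = Transcript("doc", CASCADE_TEXT)
        result = run_pipeline(t, lexicon, config)
        finals = sorted(a.covered_text for a in result.final)
        assert finals == ["flu", "insulin", "lisinopril"]
        removed = {
            r.annotation.covered_text: r.stage
            for r in result.audit if r.action == "removed"
        }
        assert removed["today"] == "common_word"
        assert removed["gold"] == "chemical_element"
        added = {r.annotation.covered_text: r.stage
                 for r in result.audit if r.action == "added"
                 and r.stage != "match"}
        assert added["flu"] == "immunization_addition"

    def test_exception_word_alone_survives(self, lexicon, config):
        t = Transcript("doc", "insulin")
        result = run_pipeline(t, lexicon, config)
        assert [a.covered_text for a in result.final] == ["insulin"]

    def test_no_hits_empty_result(self, lexicon, config):
        t = Transcript("doc", "PT: nothing relevant was discussed at all.\n")
        assert len(run_pipeline(t, lexicon, config).final) == 0

    def test_final_contains_only_medications(self, lexicon, config):
        t = Transcript("doc", "PT: my asthma and my metformin.\n")
        result = run_pipeline(t, lexicon, config)
        assert {a.label for a in result.final} == {MEDICATION}
        assert [a.covered_text for a in result.final] == ["metformin"]

    def test_bookkeeping_balances(self, lexicon, config):
        result = run_pipeline(Transcript("doc", CASCADE_TEXT), lexicon, config)
        counts = result.stage_counts
        start = counts["candidates"][0]
        removed = sum(v[1] for k, v in counts.items() if k != "candidates")
        added = sum(v[2] for v in counts.values())
        assert start - removed + added == len(result.final)

    def test_deterministic_output_bytes(self, lexicon, config, tmp_path):
        outs = []
        for i in range(2):
            result = run_pipeline(Transcript("doc", CASCADE_TEXT), lexicon, config)
            p = tmp_path / f"run{i}.json"
            write_json(result.final, p)
            outs.append(p.read_bytes())
        assert outs[0] == outs[1]

    def test_unknown_stage_name_rejected(self, lexicon, config):
        with pytest.raises(ValueError, match="unknown stage"):
            run_pipeline(Transcript("d", "x"), lexicon, config,
                         disabled_stages={"typo"})

    def test_stage_monotonicity(self, lexicon, config):
        """Disabling a removal stage can only grow the final set; disabling
        an addition stage can only shrink it."""
        t_full = run_pipeline(Transcript("doc", CASCADE_TEXT), lexicon, config)
        n_full = len(t_full.final)
        for stage in STAGES:
            n = len(
                run_pipeline(Transcript("doc", CASCADE_TEXT), lexicon, config,
                             disabled_stages={stage}).final
            )
            if stage.endswith("_addition"):
                assert n <= n_full, stage
            else:
                assert n >= n_full, stage
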