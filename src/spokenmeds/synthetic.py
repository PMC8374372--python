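"""Deterministic synthetic visit-transcript corpus with gold annotations.

Real primary-care visit transcripts contain protected health information and
cannot ship with the package, so every pipeline stage is exercised against
generated dyadic conversations instead: alternating clinician ("DR:") and
patient ("PT:") turns built from sentence templates, salted with
conversational noise ("um", "you know", unfinished fragments).

Each document plants, at recorded character offsets:

* true medication mentions drawn from the bundled lexicon,
* herb/supplement mentions recoverable only through the supplement
  dictionary,
* immunization mentions (a diagnosis term sharing a sentence with a trigger
  word such as "shot"), and
* configurable false-positive traps, one vocabulary per filter stage
  (:class:`TrapKind`).

Gold annotations are the planted true mentions only; traps are planted but
excluded from gold, so a perfect cascade scores P = R = 1 on this corpus and
disabling any single stage measurably hurts.  Identical spec + seed produce
byte-identical corpora.
"""

from __future__ import annotations

import csv
import enum
import random
from dataclasses import dataclass, field
from pathlib import Path

from .annotate import MEDICATION, Annotation, AnnotationSet, Transcript
from .io_formats import write_knowtator

__all__ = ["TrapKind", "CorpusSpec", "generate_transcript", "generate_corpus"]


class TrapKind(str, enum.Enum):
    """False-positive trap categories; each maps to exactly one filter stage
    or behaviour under test."""

    common_word_drug = "common_word_drug"          # common_word filter
    chemical_element = "chemical_element"          # chemical_element filter
    allergen = "allergen"                          # allergen filter
    excluded_tui_term = "excluded_tui_term"        # semantic_type filter
    filler_abbreviation = "filler_abbreviation"    # common_word filter (fillers)
    diagnosis_no_trigger = "diagnosis_no_trigger"  # immunization stage must not fire


def _default_trap_mix() -> dict[TrapKind, int]:
    return {kind: 1 for kind in TrapKind}


def _default_med_mix() -> dict[str, int]:
    return {"medication": 3, "supplement": 2, "immunization": 1}


@dataclass
class CorpusSpec:
    """Shape of a generated corpus; identical spec + seed -> identical text."""

    n_docs: int = 50
    turns_per_doc: tuple[int, int] = (8, 14)
    seed: int = 0
    trap_mix: dict[TrapKind, int] = field(default_factory=_default_trap_mix)
    med_mix: dict[str, int] = field(default_factory=_default_med_mix)

    def __post_init__(self) -> None:
        counts = [*self.trap_mix.values(), *self.med_mix.values(), self.n_docs]
        if any(c < 0 for c in counts):
            raise ValueError("counts must be non-negative")


# ---------------------------------------------------------------------------
# planting vocabulary — all true-mention items exist in the bundled fixture
# lexicon/supplement list; all trap items belong to their stage's vocabulary

_MEDICATIONS = [
    "lisinopril", "metformin", "atorvastatin", "omeprazole", "gabapentin",
    "sertraline", "albuterol", "amoxicillin", "losartan", "amlodipine",
    "levothyroxine", "metoprolol", "furosemide", "prednisone", "tramadol",
    "naproxen", "doxycycline", "citalopram", "trazodone", "warfarin",
    "insulin", "aspirin", "insulin glargine", "vitamin d", "fish oil",
]
_SUPPLEMENTS = [
    "ginkgo", "turmeric", "echinacea", "melatonin", "glucosamine",
    "ashwagandha", "milk thistle", "zinc", "magnesium",
]
# (diagnosis term, immunization cue) pairs; cue is one of the trigger words
_IMMUNIZATIONS = [
    ("flu", "shot"), ("tetanus", "booster"), ("pertussis", "vaccine"),
    ("shingles", "vaccine"), ("hepatitis", "shot"), ("measles", "vaccine"),
    ("hpv", "vaccine"),
]
_TRAP_VOCAB: dict[TrapKind, list[str]] = {
    TrapKind.common_word_drug: ["today", "sonata", "soma", "paxil", "celexa"],
    TrapKind.chemical_element: ["gold", "potassium", "platinum", "titanium", "mercury"],
    TrapKind.allergen: ["coconut", "peanut", "ragweed"],
    TrapKind.excluded_tui_term: ["estrogen", "cortisol", "collagen", "saline",
                                 "testosterone"],
    TrapKind.filler_abbreviation: ["hmm", "aha"],
    TrapKind.diagnosis_no_trigger: ["chickenpox", "asthma", "diabetes", "arthritis"],
}

# sentence templates; "{item}" marks the planted span.  Template vocabulary
# deliberately avoids lexicon terms, supplement terms, trigger words and
# element names so only planted items generate annotations.
_MED_TEMPLATES = [
    "I want you to keep taking the {item} every day.",
    "I ran out of my {item} last week.",
    "We could go up a little on the {item} if needed.",
    "Does the {item} ever upset your stomach?",
    "So you are still on {item}, is that right?",
    "Um, I think the {item} has been helping.",
    "Let's keep the {item} where it is for now.",
]
_SUPP_TEMPLATES = [
    "I also started taking {item} on my own.",
    "My neighbor said {item} might help, so I tried it.",
    "Is it okay to stay on the {item} I picked up?",
    "I read about {item} online, you know, for energy.",
]
_IMMU_TEMPLATES = [
    "Are you due for your {item} {cue} this fall?",
    "We should get you the {item} {cue} before winter.",
    "Did you ever get that {item} {cue} we talked about?",
]
_TRAP_TEMPLATES: dict[TrapKind, list[str]] = {
    TrapKind.common_word_drug: [
        "I have been feeling a bit better {item}, actually.",
        "We can start that {item} if you like.",
        "It came up just {item} at the front desk.",
    ],
    TrapKind.chemical_element: [
        "Your {item} looked a little low on the lab work.",
        "The bloodwork shows the {item} level is fine.",
        "We will recheck the {item} at your next draw.",
    ],
    TrapKind.allergen: [
        "I use {item} in my cooking sometimes.",
        "Does {item} bother you at all?",
        "There was {item} in the salad, I think.",
    ],
    TrapKind.excluded_tui_term: [
        "Your {item} level came back normal.",
        "I heard {item} is good for the skin.",
        "The panel included {item} this time.",
    ],
    TrapKind.filler_abbreviation: [
        "{item}, I am not sure about that.",
        "{item}, that makes sense to me.",
    ],
    TrapKind.diagnosis_no_trigger: [
        "I had {item} as a kid.",
        "My sister deals with {item} too.",
        "We talked about your {item} last time.",
    ],
}
_FILLERS = [
    "How have you been feeling since the last visit?",
    "Pretty good overall, you know, just busy.",
    "Let me pull up your chart here.",
    "Um, I think so, more or less.",
    "Any changes at home I should know about?",
    "Not really, um, the usual.",
    "Okay, let's have a listen to your heart and lungs.",
    "That all sounds reasonable to me.",
    "And you are still walking most mornings?",
    "Yeah, when the weather lets me.",
]


def _plant(template: str, item: str, cue: str | None = None) -> tuple[str, int, int]:
    """Fill a template; return (sentence, item_start, item_end) within it."""
    prefix = template.split("{item}")[0].format(cue=cue) if cue else \
        template.split("{item}")[0]
    sentence = template.format(item=item, cue=cue) if cue else \
        template.format(item=item)
    start = len(prefix)
    return sentence, start, start + len(item)


def generate_transcript(
    spec: CorpusSpec, doc_index: int
) -> tuple[Transcript, AnnotationSet, list[dict]]:
    """One synthetic visit transcript with its gold annotations.

    Returns (transcript, gold, manifest rows).  Gold contains only the
    planted true mentions (medications, supplements, immunization
    diagnoses); traps appear in the text and manifest but not in gold.
    """
    rng = random.Random(f"{spec.seed}:{doc_index}")
    doc_id = f"visit{doc_index:03d}"

    jobs: list[tuple[str, str, str | None]] = []  # (category, item, cue)
    for _ in range(spec.med_mix.get("medication", 0)):
        jobs.append(("medication", rng.choice(_MEDICATIONS), None))
    for _ in range(spec.med_mix.get("supplement", 0)):
        jobs.append(("supplement", rng.choice(_SUPPLEMENTS), None))
    for _ in range(spec.med_mix.get("immunization", 0)):
        dx, cue = rng.choice(_IMMUNIZATIONS)
        jobs.append(("immunization", dx, cue))
    for kind, count in spec.trap_mix.items():
        kind = TrapKind(kind)
        vocab = _TRAP_VOCAB[kind]
        for _ in range(count):
            jobs.append((kind.value, rng.choice(vocab), None))
    rng.shuffle(jobs)

    n_turns = max(rng.randint(*spec.turns_per_doc), len(jobs))
    turn_has_job = [i < len(jobs) for i in range(n_turns)]
    rng.shuffle(turn_has_job)

    text_parts: list[str] = []
    offset = 0
    gold: list[Annotation] = []
    manifest: list[dict] = []
    job_iter = iter(jobs)
    for turn_idx in range(n_turns):
        speaker = "DR" if turn_idx % 2 == 0 else "PT"
        prefix = f"{speaker}: "
        if turn_has_job[turn_idx]:
            category, item, cue = next(job_iter)
            if category == "medication":
                template = rng.choice(_MED_TEMPLATES)
            elif category == "supplement":
                template = rng.choice(_SUPP_TEMPLATES)
            elif category == "immunization":
                template = rng.choice(_IMMU_TEMPLATES)
            else:
                template = rng.choice(_TRAP_TEMPLATES[TrapKind(category)])
            sentence, s, e = _plant(template, item, cue)
            start = offset + len(prefix) + s
            end = offset + len(prefix) + e
            in_gold = category in ("medication", "supplement", "immunization")
            if in_gold:
                gold.append(
                    Annotation(
                        start=start,
                        end=end,
                        covered_text=item,
                        label=MEDICATION,
                        provenance="gold",
                    )
                )
            manifest.append(
                {
                    "doc_id": doc_id,
                    "category": category,
                    "item": item,
                    "start": start,
                    "end": end,
                    "in_gold": int(in_gold),
                }
            )
        else:
            sentence = rng.choice(_FILLERS)
        line = prefix + sentence + "\n"
        text_parts.append(line)
        offset += len(line)

    transcript = Transcript(doc_id=doc_id, text="".join(text_parts)).segment()
    gold_set = AnnotationSet(doc_id, gold)
    gold_set.validate_against(transcript.text)
    return transcript, gold_set, manifest


_MANIFEST_COLUMNS = ["doc_id", "category", "item", "start", "end", "in_gold"]


def generate_corpus(spec: CorpusSpec, out_dir: str | Path) -> list[dict]:
    """Write a corpus in eHOST project layout and return the manifest.

    Produces ``corpus/<doc>.txt``, gold ``saved/<doc>.txt.knowtator.xml``
    and ``manifest.tsv`` (one row per planted item) under ``out_dir``.
    """
    out_dir = Path(out_dir)
    (out_dir / "corpus").mkdir(parents=True, exist_ok=True)
    (out_dir / "saved").mkdir(parents=True, exist_ok=True)
    manifest: list[dict] = []
    for i in range(spec.n_docs):
        transcript, gold, rows = generate_transcript(spec, i)
        (out_dir / "corpus" / f"{transcript.doc_id}.txt").write_text(
            transcript.text, encoding="utf-8"
        )
        write_knowtator(
            gold,
            out_dir / "saved" / f"{transcript.doc_id}.txt.knowtator.xml",
            annotator="gold",
            text_source=f"{transcript.doc_id}.txt",
            creation_date="1970-01-01",
        )
        manifest.extend(rows)
    with (out_dir / "manifest.tsv").open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=_MANIFEST_COLUMNS, delimiter="\t")
        writer.writeheader()
        writer.writerows(manifest)
    return manifest
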