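"""Candidate generation: sentence segmentation, sentence-windowed dictionary
matching, and most-specific-span consumption.

The matcher emulates the behaviour this pipeline post-processes: a fast
dictionary lookup that uses sentences as its lookup window and, like the
cTAKES ``PrecisionTermConsumer``, refines overlapping hits to the most
specific variation — if "colon cancer" matches, the nested "colon" and
"cancer" hits are consumed.  Candidates can alternatively be ingested from a
cTAKES CAS-XMI file via :func:`read_ctakes_xmi`.
"""

from __future__ import annotations

import re
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field, replace

from lxml import etree

from .lexicon import (
    CANDIDATE_TUIS,
    DIAGNOSIS_TUIS,
    EXCLUDED_TUIS,
    Lexicon,
    normalize_term,
)

__all__ = [
    "MEDICATION",
    "DIAGNOSIS",
    "Sentence",
    "Transcript",
    "Annotation",
    "AuditRecord",
    "AnnotationSet",
    "segment_sentences",
    "match_candidates",
    "consume_most_specific",
    "find_term_matches",
    "read_ctakes_xmi",
    "XmiFormatError",
]

MEDICATION = "MEDICATION"
DIAGNOSIS = "DIAGNOSIS"

# alphanumeric runs; internal apostrophes stay inside a token ("john's"),
# hyphens and other punctuation break tokens
_TOKEN = re.compile(r"[A-Za-z0-9]+(?:'[A-Za-z0-9]+)*")

# Sentence-terminal punctuation followed by whitespace; a break is confirmed
# only when the next non-space character is a capital and the preceding token
# is not a guarded abbreviation.
_BREAK = re.compile(r"[.?!]+(?=\s)")
_ABBREVIATIONS = frozenset({"dr", "mr", "mrs", "ms", "prof", "jr", "sr", "st"})


@dataclass(frozen=True)
class Sentence:
    """Half-open character span of one sentence within a document."""

    start: int
    end: int
    index: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid sentence span [{self.start}, {self.end})")


@dataclass
class Transcript:
    """A visit transcript: document id, full text, sentence segmentation."""

    doc_id: str
    text: str
    sentences: list[Sentence] = field(default_factory=list)

    def segment(self) -> "Transcript":
        """Populate ``sentences`` in place (idempotent); returns self."""
        self.sentences = segment_sentences(self.text)
        return self

    def sentence_text(self, sentence: Sentence) -> str:
        return self.text[sentence.start:sentence.end]

    def sentence_at(self, offset: int) -> Sentence | None:
        """The sentence whose span contains ``offset``, if any."""
        for s in self.sentences:
            if s.start <= offset < s.end:
                return s
        return None


@dataclass(frozen=True)
class Annotation:
    """A standoff annotation: a half-open character span with its label,
    concept metadata, and the pipeline stage that produced it."""

    start: int
    end: int
    covered_text: str
    label: str
    concept_id: str = ""
    tuis: frozenset[str] = frozenset()
    preferred_text: str = ""
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty annotation span [{self.start}, {self.end})")

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class AuditRecord:
    """One kept/removed/added decision by a pipeline stage."""

    annotation: Annotation
    stage: str
    action: str  # kept | removed | added
    reason: str = ""


_SORT_KEY = lambda a: (a.start, a.end, a.label, a.concept_id)  # noqa: E731


class AnnotationSet:
    """Annotations for one document, kept ordered by (start, end), plus the
    audit trail accumulated across pipeline stages."""

    def __init__(
        self,
        doc_id: str,
        annotations: Iterable[Annotation] = (),
        audit: Iterable[AuditRecord] = (),
    ):
        self.doc_id = doc_id
        self.annotations: list[Annotation] = sorted(annotations, key=_SORT_KEY)
        self.audit: list[AuditRecord] = list(audit)

    def __iter__(self):
        return iter(self.annotations)

    def __len__(self) -> int:
        return len(self.annotations)

    def with_annotations(
        self,
        annotations: Iterable[Annotation],
        extra_audit: Iterable[AuditRecord] = (),
    ) -> "AnnotationSet":
        """A new set for the same document with the audit trail extended."""
        return AnnotationSet(
            self.doc_id, annotations, [*self.audit, *extra_audit]
        )

    def filtered(self, label: str) -> list[Annotation]:
        return [a for a in self.annotations if a.label == label]

    def spans(self) -> list[tuple[int, int]]:
        return [a.span for a in self.annotations]

    def validate_against(self, text: str) -> None:
        """Check every covered_text against the document text."""
        for a in self.annotations:
            if text[a.start:a.end] != a.covered_text:
                raise ValueError(
                    f"{self.doc_id}: annotation [{a.start},{a.end}) covers "
                    f"{text[a.start:a.end]!r}, recorded {a.covered_text!r}"
                )


def segment_sentences(text: str) -> list[Sentence]:
    """Rule-based sentence segmentation.

    Breaks at newlines and at runs of ``.?!`` followed by whitespace and a
    capital letter, with a small abbreviation guard (personal titles, single
    initials).  Each sentence span is trimmed to its non-whitespace extent;
    text without terminal punctuation yields a single sentence.  Deterministic
    for fixed input.
    """
    if not text.strip():
        return []
    cuts = {0, len(text)}
    for i, ch in enumerate(text):
        if ch == "\n":
            cuts.add(i)
            cuts.add(i + 1)
    for m in _BREAK.finditer(text):
        rest = text[m.end():]
        stripped = rest.lstrip()
        if not stripped or not stripped[0].isupper():
            continue
        before = text[:m.start()]
        tok = _TOKEN.findall(before[-12:])
        last = tok[-1].lower() if tok else ""
        if last in _ABBREVIATIONS or len(last) == 1 and last.isalpha():
            continue
        cuts.add(m.end())
    bounds = sorted(cuts)
    sentences: list[Sentence] = []
    for lo, hi in zip(bounds, bounds[1:]):
        seg = text[lo:hi]
        if not seg.strip():
            continue
        start = lo + (len(seg) - len(seg.lstrip()))
        end = hi - (len(seg) - len(seg.rstrip()))
        sentences.append(Sentence(start, end, len(sentences)))
    return sentences


def _term_tokens(term: str) -> tuple[str, ...]:
    return tuple(_TOKEN.findall(term))


def _whitespace_gaps(text: str, tokens, i: int, n: int) -> bool:
    """True when the matched tokens are separated by whitespace only, so the
    covered text normalizes back to the lexicon term (no "colon . cancer")."""
    return all(
        text[tokens[k][2]:tokens[k + 1][1]].isspace()
        for k in range(i, i + n - 1)
    )


def match_candidates(
    transcript: Transcript,
    lexicon: Lexicon,
    candidate_tuis: frozenset[str] = CANDIDATE_TUIS,
    *,
    diagnosis_tuis: frozenset[str] = DIAGNOSIS_TUIS,
    excluded_tuis: frozenset[str] = EXCLUDED_TUIS,
) -> AnnotationSet:
    """Sentence-windowed dictionary matching.

    Every case-insensitive token-sequence match of a lexicon term lying
    entirely within one sentence yields one annotation per matching concept;
    matches never cross sentence boundaries.  Tokens are alphanumeric runs
    (hyphens and other punctuation break tokens).

    Hits are labelled MEDICATION when their TUIs intersect the candidate
    drug-like types *or* the excluded six (the dictionary this emulates
    annotates hormones, inorganic chemicals, etc. as medications — removing
    them is the semantic-type filter's job, not the matcher's), DIAGNOSIS
    when they intersect the disorder types, and are discarded otherwise.
    """
    if transcript.text.strip() and not transcript.sentences:
        raise ValueError(
            f"{transcript.doc_id}: transcript must be segmented before matching"
        )
    med_tuis = candidate_tuis | excluded_tuis
    index: dict[tuple[str, ...], list] = {}
    for term in lexicon.terms:
        toks = _term_tokens(term)
        if toks:
            index.setdefault(toks, []).extend(lexicon.lookup(term))
    max_n = max((len(k) for k in index), default=0)
    annotations: list[Annotation] = []
    for sent in transcript.sentences:
        stext = transcript.sentence_text(sent)
        tokens = [
            (m.group().lower(), sent.start + m.start(), sent.start + m.end())
            for m in _TOKEN.finditer(stext)
        ]
        for i in range(len(tokens)):
            for n in range(1, min(max_n, len(tokens) - i) + 1):
                key = tuple(t[0] for t in tokens[i:i + n])
                if n > 1 and key in index and not _whitespace_gaps(
                    transcript.text, tokens, i, n
                ):
                    continue
                for entry in index.get(key, ()):
                    start, end = tokens[i][1], tokens[i + n - 1][2]
                    if entry.tuis & med_tuis:
                        label = MEDICATION
                    elif entry.tuis & diagnosis_tuis:
                        label = DIAGNOSIS
                    else:
                        continue
                    annotations.append(
                        Annotation(
                            start=start,
                            end=end,
                            covered_text=transcript.text[start:end],
                            label=label,
                            concept_id=entry.concept_id,
                            tuis=entry.tuis,
                            preferred_text=entry.preferred_text,
                            provenance="dictionary",
                        )
                    )
    result = AnnotationSet(transcript.doc_id, annotations)
    result.audit = [
        AuditRecord(a, "match", "added", "dictionary_hit") for a in result
    ]
    return result


def consume_most_specific(annotations: AnnotationSet) -> AnnotationSet:
    """Keep only the most specific spans: drop every annotation whose span is
    strictly contained in another annotation's span.  Identical spans are not
    consumed.  Idempotent and independent of input order."""
    spans = set(annotations.spans())
    kept: list[Annotation] = []
    audit: list[AuditRecord] = []
    for a in annotations:
        consumed = any(
            s <= a.start and a.end <= e and (s, e) != a.span for s, e in spans
        )
        if consumed:
            audit.append(
                AuditRecord(a, "most_specific", "removed", "contained_in_longer_span")
            )
        else:
            kept.append(a)
    return annotations.with_annotations(kept, audit)


def find_term_matches(
    transcript: Transcript, terms: Iterable[str]
) -> list[tuple[int, int, str]]:
    """All sentence-internal token-sequence matches of ``terms`` in the
    transcript, as (start, end, normalized term) triples.  Matching mirrors
    :func:`match_candidates` (case-insensitive, alphanumeric tokens)."""
    index: dict[tuple[str, ...], str] = {}
    for term in terms:
        norm = normalize_term(term)
        toks = _term_tokens(norm)
        if toks:
            index[toks] = norm
    max_n = max((len(k) for k in index), default=0)
    out: list[tuple[int, int, str]] = []
    for sent in transcript.sentences:
        stext = transcript.sentence_text(sent)
        tokens = [
            (m.group().lower(), sent.start + m.start(), sent.start + m.end())
            for m in _TOKEN.finditer(stext)
        ]
        for i in range(len(tokens)):
            for n in range(1, min(max_n, len(tokens) - i) + 1):
                key = tuple(t[0] for t in tokens[i:i + n])
                if key in index and (
                    n == 1 or _whitespace_gaps(transcript.text, tokens, i, n)
                ):
                    out.append((tokens[i][1], tokens[i + n - 1][2], index[key]))
    return out


class XmiFormatError(ValueError):
    """Raised when a CAS-XMI file lacks required mention structure."""


def _local(tag) -> str:
    return etree.QName(tag).localname if isinstance(tag, str) else ""


def read_ctakes_xmi(path) -> AnnotationSet:
    """Ingest medication/disease mention annotations from a cTAKES CAS-XMI
    file (minimal dialect).

    Recognised are elements whose tag name ends in ``MedicationMention``
    (label MEDICATION) or ``DiseaseDisorderMention`` (label DIAGNOSIS) with
    ``begin``/``end`` attributes (0-based, half-open, taken verbatim).  TUIs
    and preferred texts come from ``UmlsConcept`` elements referenced through
    ``ontologyConceptArr``; covered text is sliced from the ``Sofa``
    ``sofaString`` when present.
    """
    from pathlib import Path

    path = Path(path)
    tree = etree.parse(str(path))  # raises XMLSyntaxError on malformed input
    root = tree.getroot()
    xmi_id = "{http://www.omg.org/XMI}id"
    concepts: dict[str, dict] = {}
    sofa_text = ""
    for el in root.iter():
        name = _local(el.tag)
        if name == "UmlsConcept":
            cid = el.get(xmi_id)
            if cid:
                concepts[cid] = {
                    "tui": el.get("tui", ""),
                    "preferred": el.get("preferredText", ""),
                    "cui": el.get("cui", ""),
                }
        elif name == "Sofa" and el.get("sofaString") is not None:
            sofa_text = el.get("sofaString")
    annotations = []
    for el in root.iter():
        name = _local(el.tag)
        if name.endswith("MedicationMention"):
            label = MEDICATION
        elif name.endswith("DiseaseDisorderMention"):
            label = DIAGNOSIS
        else:
            continue
        begin, end = el.get("begin"), el.get("end")
        if begin is None or end is None:
            raise XmiFormatError(
                f"{path}: element {name} missing begin/end offsets"
            )
        begin, end = int(begin), int(end)
        tuis, preferred, cui = set(), "", ""
        for ref in (el.get("ontologyConceptArr") or "").split():
            c = concepts.get(ref)
            if c:
                if c["tui"]:
                    tuis.add(c["tui"])
                preferred = preferred or c["preferred"]
                cui = cui or c["cui"]
        annotations.append(
            Annotation(
                start=begin,
                end=end,
                covered_text=sofa_text[begin:end] if sofa_text else "",
                label=label,
                concept_id=cui,
                tuis=frozenset(tuis),
                preferred_text=preferred,
                provenance="ctakes_xmi",
            )
        )
    return AnnotationSet(path.stem, annotations)
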