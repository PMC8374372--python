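"""Lexicons, word lists, and the rule constants that drive the filter cascade.

The matcher is driven by a concept lexicon mapping surface terms to concept
identifiers and UMLS semantic types (TUIs), standing in for the prebuilt
cTAKES dictionary built from RxNorm and SNOMED-CT.  The filter cascade is
driven by plain word lists (common English words, chemical elements,
exceptions) and a handful of set-valued constants collected in
:class:`FilterConfig`.

The packaged data files are synthetic stand-ins where the original resources
cannot be redistributed: ``lexicon_synthetic.tsv`` (an authored ~340-entry
drug/diagnosis lexicon), ``supplements_synthetic.txt`` (modelled on the
MedlinePlus herb and supplement index) and ``common_words_synthetic.txt``
(a curated subset standing in for the 10 000 most common English words from
Google's Trillion Word Corpus; ``scripts/vendor_common_words.py`` fetches the
full list when a network is available).
"""

from __future__ import annotations

import logging
import re
from collections.abc import Iterable
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

__all__ = [
    "LexEntry",
    "Lexicon",
    "WordList",
    "TermList",
    "FilterConfig",
    "normalize_term",
    "load_lexicon",
    "load_wordlist",
    "load_termlist",
    "default_filter_config",
    "load_default_lexicon",
    "load_default_supplements",
    "EXCLUDED_TUIS",
    "CANDIDATE_TUIS",
    "DIAGNOSIS_TUIS",
    "TRIGGER_WORDS",
    "ALLERGEN_MARKER",
]

logger = logging.getLogger(__name__)

_WS = re.compile(r"\s+")

#: UMLS semantic types removed by the semantic-type filter: nucleic acids
#: (T114), biomedical/dental materials (T122), biologically active substances
#: (T123), hormones (T125), indicators/reagents/diagnostic aids (T130) and
#: inorganic chemicals (T197).  These types produce almost exclusively false
#: positives in conversational transcripts.
EXCLUDED_TUIS = frozenset({"T114", "T122", "T123", "T125", "T130", "T197"})

#: Drug-like semantic types that make a lexicon hit a medication candidate
#: (organic chemical, vitamin, antibiotic, clinical drug, ... — mirroring the
#: TUI coverage of a cTAKES MedicationMention).
CANDIDATE_TUIS = frozenset({"T109", "T110", "T116", "T121", "T127", "T195", "T200"})

#: Disorder-like semantic types that make a lexicon hit a diagnosis
#: annotation, the input to the immunization-addition stage.
DIAGNOSIS_TUIS = frozenset(
    {"T019", "T020", "T037", "T046", "T047", "T048", "T049", "T050",
     "T184", "T190", "T191"}
)

#: Immunization cue words: a diagnosis in the same sentence as one of these
#: is re-annotated as a medication ("flu shot", "tetanus booster", ...).
TRIGGER_WORDS = frozenset({"vaccine", "shot", "booster", "pill"})

#: Substring of the preferred text that marks food/environmental allergen
#: extract concepts ("Coconut allergenic extract").
ALLERGEN_MARKER = "allergenic"


def normalize_term(raw: str) -> str:
    """Normalize a surface term: lowercase, strip, collapse internal runs of
    whitespace to single spaces.  Idempotent; empty input maps to empty."""
    return _WS.sub(" ", raw.strip()).lower()


@dataclass(frozen=True)
class LexEntry:
    """One lexicon row: a surface term with its concept and semantic types."""

    term: str
    concept_id: str
    tuis: frozenset[str]
    preferred_text: str
    source: str = ""


class Lexicon:
    """A term-indexed collection of :class:`LexEntry`.

    Lookup is case-insensitive: both the index keys and lookup arguments go
    through :func:`normalize_term`.  Multiple concepts may share one surface
    term, so lookup returns a tuple of entries.
    """

    def __init__(self, entries: Iterable[LexEntry] = ()):
        self.entries: list[LexEntry] = []
        self._index: dict[str, list[LexEntry]] = {}
        for entry in entries:
            self.add(entry)

    def add(self, entry: LexEntry) -> None:
        key = normalize_term(entry.term)
        if not key:
            raise ValueError("lexicon term empty after normalization")
        self.entries.append(entry)
        self._index.setdefault(key, []).append(entry)

    def lookup(self, term: str) -> tuple[LexEntry, ...]:
        return tuple(self._index.get(normalize_term(term), ()))

    def __contains__(self, term: str) -> bool:
        return normalize_term(term) in self._index

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def terms(self) -> set[str]:
        """Normalized surface terms present in the index."""
        return set(self._index)

    def max_term_tokens(self) -> int:
        """Longest term length in whitespace-delimited tokens (0 if empty)."""
        if not self._index:
            return 0
        return max(len(t.split()) for t in self._index)


@dataclass(frozen=True)
class WordList:
    """A named set of lowercase single-token words (one filter vocabulary)."""

    words: frozenset[str]
    name: str = ""

    def __post_init__(self) -> None:
        bad = [w for w in self.words if not w or w != w.lower() or _WS.search(w)]
        if bad:
            raise ValueError(
                f"word list {self.name!r}: entries must be lowercase single "
                f"tokens, got {sorted(bad)[:5]!r}"
            )

    def __contains__(self, word: str) -> bool:
        return word in self.words

    def __len__(self) -> int:
        return len(self.words)


@dataclass(frozen=True)
class TermList:
    """A named set of normalized terms; unlike :class:`WordList`, multi-word
    phrases ("fish oil", "st john's wort") are allowed."""

    terms: frozenset[str]
    name: str = ""

    def __contains__(self, term: str) -> bool:
        return term in self.terms

    def __len__(self) -> int:
        return len(self.terms)


@dataclass(frozen=True)
class FilterConfig:
    """All rule constants of the filter/addition cascade in one place.

    The defaults reproduce the published configuration: the six excluded
    TUIs, the 71 chemical elements, the four immunization trigger words, the
    24-entry common-word exception list and the "allergenic" marker.
    """

    common_words: WordList
    exception_words: WordList
    chemical_elements: WordList
    supplement_terms: TermList
    excluded_tuis: frozenset[str] = EXCLUDED_TUIS
    trigger_words: frozenset[str] = TRIGGER_WORDS
    allergen_marker: str = ALLERGEN_MARKER
    candidate_tuis: frozenset[str] = CANDIDATE_TUIS
    diagnosis_tuis: frozenset[str] = DIAGNOSIS_TUIS
    #: "all": remove only when every drug-relevant TUI of the annotation is an
    #: excluded type; "any": one excluded TUI suffices for removal.
    tui_filter_mode: str = "all"


class LexiconFormatError(ValueError):
    """Raised for malformed lexicon TSV input."""


_LEXICON_COLUMNS = ["term", "concept_id", "tuis", "preferred_text", "source"]


def load_lexicon(path: str | Path) -> Lexicon:
    """Load a concept lexicon from TSV.

    Expected columns (header required): ``term``, ``concept_id``, ``tuis``
    (pipe-separated TUI codes), ``preferred_text``, ``source``.  Rows sharing
    (term, concept_id) are merged with the union of their TUI sets.
    """
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        header_line = fh.readline()
        if not header_line.strip():
            logger.warning("lexicon file %s is empty", path)
            return Lexicon()
        header = header_line.rstrip("\n").split("\t")
        missing = [c for c in _LEXICON_COLUMNS if c not in header]
        if missing:
            raise LexiconFormatError(
                f"{path}:1: missing column(s) {', '.join(missing)}"
            )
        col = {name: header.index(name) for name in _LEXICON_COLUMNS}
        merged: dict[tuple[str, str], dict] = {}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < len(header):
                raise LexiconFormatError(
                    f"{path}:{lineno}: expected {len(header)} fields, "
                    f"got {len(fields)}"
                )
            term = normalize_term(fields[col["term"]])
            if not term:
                raise LexiconFormatError(f"{path}:{lineno}: empty term")
            tuis = frozenset(t for t in fields[col["tuis"]].split("|") if t)
            if not tuis:
                raise LexiconFormatError(f"{path}:{lineno}: no TUIs for {term!r}")
            key = (term, fields[col["concept_id"]])
            if key in merged:
                merged[key]["tuis"] |= tuis
            else:
                merged[key] = {
                    "term": term,
                    "concept_id": fields[col["concept_id"]],
                    "tuis": set(tuis),
                    "preferred_text": fields[col["preferred_text"]],
                    "source": fields[col["source"]],
                }
    lex = Lexicon()
    for rec in merged.values():
        lex.add(
            LexEntry(
                term=rec["term"],
                concept_id=rec["concept_id"],
                tuis=frozenset(rec["tuis"]),
                preferred_text=rec["preferred_text"],
                source=rec["source"],
            )
        )
    if not len(lex):
        logger.warning("lexicon file %s produced no entries", path)
    return lex


def _read_token_lines(path: str | Path) -> list[str]:
    out = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line.lower())
    return out


def load_wordlist(path: str | Path, name: str = "") -> WordList:
    """Load a one-token-per-line word list; ``#`` comments and blank lines
    are ignored, entries are lowercased and deduplicated."""
    path = Path(path)
    return WordList(frozenset(_read_token_lines(path)), name or path.stem)


def load_termlist(path: str | Path, name: str = "") -> TermList:
    """Like :func:`load_wordlist` but entries may be multi-word phrases."""
    path = Path(path)
    return TermList(
        frozenset(normalize_term(t) for t in _read_token_lines(path)),
        name or path.stem,
    )


def _data_path(filename: str) -> Path:
    return Path(resources.files("spokenmeds.data") / filename)


def default_filter_config(
    common_words: WordList | None = None,
    supplements: TermList | None = None,
) -> FilterConfig:
    """Build the default :class:`FilterConfig` from the packaged word lists.

    Pass ``common_words`` to substitute e.g. the full vendored 10 000-word
    common-English list for the bundled subset.
    """
    if common_words is None:
        common_words = load_wordlist(
            _data_path("common_words_synthetic.txt"), "common_words"
        )
    if supplements is None:
        supplements = load_default_supplements()
    return FilterConfig(
        common_words=common_words,
        exception_words=load_wordlist(
            _data_path("exception_words.txt"), "exception_words"
        ),
        chemical_elements=load_wordlist(
            _data_path("chemical_elements.txt"), "chemical_elements"
        ),
        supplement_terms=supplements,
    )


def load_default_lexicon() -> Lexicon:
    """The bundled synthetic fixture lexicon (stand-in for the prebuilt
    cTAKES RxNorm + SNOMED-CT dictionary, which is not redistributable)."""
    return load_lexicon(_data_path("lexicon_synthetic.tsv"))


def load_default_supplements() -> TermList:
    """The bundled synthetic herb/supplement term list (stand-in for the
    MedlinePlus herb and supplement index)."""
    return load_termlist(_data_path("supplements_synthetic.txt"), "supplements")
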