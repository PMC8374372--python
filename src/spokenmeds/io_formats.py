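"""Reading transcripts and reading/writing standoff annotation files.

Annotations are exchanged in the Knowtator XML dialect understood by the
eHOST annotation tool, and in a stable-key JSON standoff format.  Span
convention throughout: 0-based start, exclusive end, indexing characters of
the source text (Knowtator variants disagree on this; this dialect matches
eHOST's character indexing).
"""

from __future__ import annotations

import datetime
import json
from pathlib import Path

from lxml import etree

from .annotate import MEDICATION, Annotation, AnnotationSet, Transcript

__all__ = [
    "DEFAULT_ANNOTATOR",
    "read_transcript",
    "write_knowtator",
    "read_knowtator",
    "write_json",
    "read_json",
    "write_ehost_project",
    "KnowtatorFormatError",
]

DEFAULT_ANNOTATOR = "spokenmeds-v1"


class KnowtatorFormatError(ValueError):
    """Raised for structurally invalid Knowtator XML."""


def read_transcript(path: str | Path) -> Transcript:
    """Read a UTF-8 transcript verbatim; doc_id is the file stem."""
    path = Path(path)
    with path.open(encoding="utf-8", newline="") as fh:  # keep \r\n verbatim
        return Transcript(doc_id=path.stem, text=fh.read())


def write_knowtator(
    anns: AnnotationSet,
    path: str | Path,
    *,
    annotator: str = DEFAULT_ANNOTATOR,
    text_source: str | None = None,
    creation_date: str | None = None,
) -> Path:
    """Serialize an annotation set to Knowtator/eHOST XML.

    One ``<annotation>`` (mention reference, annotator, span, spanned text)
    plus one ``<classMention>`` per annotation; mention ids follow the
    deterministic scheme ``EHOST_Instance_<n>`` in (start, end) order.  The
    mention class is "Medication" for MEDICATION annotations, else the raw
    label.
    """
    path = Path(path)
    if creation_date is None:
        creation_date = datetime.date.today().isoformat()
    root = etree.Element(
        "annotations", textSource=text_source or f"{anns.doc_id}.txt"
    )
    for n, a in enumerate(anns, start=1):
        mention_id = f"EHOST_Instance_{n}"
        el = etree.SubElement(root, "annotation")
        etree.SubElement(el, "mention", id=mention_id)
        etree.SubElement(el, "annotator", id=annotator).text = annotator
        etree.SubElement(el, "span", start=str(a.start), end=str(a.end))
        etree.SubElement(el, "spannedText").text = a.covered_text
        etree.SubElement(el, "creationDate").text = creation_date
        cm = etree.SubElement(root, "classMention", id=mention_id)
        label = "Medication" if a.label == MEDICATION else a.label
        etree.SubElement(cm, "mentionClass", id=label).text = a.covered_text
    path.write_bytes(
        etree.tostring(
            root, xml_declaration=True, encoding="UTF-8", pretty_print=True
        )
    )
    return path


def read_knowtator(path: str | Path) -> AnnotationSet:
    """Parse Knowtator/eHOST XML back into an :class:`AnnotationSet`.

    A mention class of "Medication" (case-insensitive) maps to the
    MEDICATION label; any other class id is kept verbatim.  The document id
    is the ``textSource`` stem (``visit01.txt`` -> ``visit01``).
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise KnowtatorFormatError(f"{path}: {exc}") from exc
    root = tree.getroot()
    classes: dict[str, str] = {}
    for cm in root.iter("classMention"):
        mc = cm.find("mentionClass")
        if cm.get("id") and mc is not None:
            classes[cm.get("id")] = mc.get("id", "")
    annotations = []
    for el in root.iter("annotation"):
        mention = el.find("mention")
        mention_id = mention.get("id") if mention is not None else ""
        span = el.find("span")
        if span is None or span.get("start") is None or span.get("end") is None:
            raise KnowtatorFormatError(
                f"{path}: annotation {mention_id or '<unidentified>'} lacks a span"
            )
        spanned = el.findtext("spannedText") or ""
        label = classes.get(mention_id, "")
        if label.lower() == "medication":
            label = MEDICATION
        annotations.append(
            Annotation(
                start=int(span.get("start")),
                end=int(span.get("end")),
                covered_text=spanned,
                label=label or MEDICATION,
                provenance="knowtator",
            )
        )
    text_source = root.get("textSource", path.stem)
    doc_id = Path(text_source).stem or path.stem
    return AnnotationSet(doc_id, annotations)


def write_json(anns: AnnotationSet, path: str | Path) -> Path:
    """Write stable-key JSON standoff (sorted annotations, sorted TUI lists,
    newline-terminated); byte-identical across runs for equal input."""
    path = Path(path)
    payload = {
        "doc_id": anns.doc_id,
        "annotations": [
            {
                "start": a.start,
                "end": a.end,
                "text": a.covered_text,
                "label": a.label,
                "concept_id": a.concept_id,
                "tuis": sorted(a.tuis),
                "provenance": a.provenance,
            }
            for a in anns
        ],
    }
    path.write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return path


def read_json(path: str | Path) -> AnnotationSet:
    """Inverse of :func:`write_json`."""
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return AnnotationSet(
        payload["doc_id"],
        [
            Annotation(
                start=a["start"],
                end=a["end"],
                covered_text=a["text"],
                label=a["label"],
                concept_id=a.get("concept_id", ""),
                tuis=frozenset(a.get("tuis", ())),
                provenance=a.get("provenance", ""),
            )
            for a in payload["annotations"]
        ],
    )


def write_ehost_project(
    docs: list[tuple[Transcript, AnnotationSet]],
    project_dir: str | Path,
    *,
    annotator: str = DEFAULT_ANNOTATOR,
) -> Path:
    """Emit the eHOST project layout: ``corpus/<doc>.txt`` plus
    ``saved/<doc>.txt.knowtator.xml``, so outputs open directly in eHOST."""
    project_dir = Path(project_dir)
    corpus = project_dir / "corpus"
    saved = project_dir / "saved"
    corpus.mkdir(parents=True, exist_ok=True)
    saved.mkdir(parents=True, exist_ok=True)
    for transcript, anns in docs:
        (corpus / f"{transcript.doc_id}.txt").write_text(
            transcript.text, encoding="utf-8"
        )
        write_knowtator(
            anns,
            saved / f"{transcript.doc_id}.txt.knowtator.xml",
            annotator=annotator,
            text_source=f"{transcript.doc_id}.txt",
        )
    return project_dir
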