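"""Readers and writers for abstract corpora and extraction results.

The unit of processing is a :class:`DocumentRecord`: the title and abstract of
one PubMed/Medline citation, concatenated as ``title + " " + abstract``.  All
character offsets in this package -- including offsets carried by sidecar
annotation files -- are 0-based, half-open offsets into that concatenation,
which is the convention used by the PubTator exchange format.

Supported inputs:

* PubTator exchange format (``PMID|t|...`` / ``PMID|a|...`` blocks plus
  tab-separated mention rows), the usual carrier of pre-computed disease and
  gene annotations;
* plain text, one record per file (title line followed by abstract lines);
* PubMed XML (``PubmedArticle`` records), parsed with the standard library.

Outputs are flat association-triplet tables as TSV or JSON Lines.
"""

from __future__ import annotations

import json
import logging
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "MentionType",
    "Mention",
    "DocumentRecord",
    "CorpusFormatError",
    "read_pubtator",
    "read_plaintext",
    "read_pubmed_xml",
    "write_triplets",
    "read_triplets_jsonl",
    "TRIPLET_COLUMNS",
]


class MentionType(str, Enum):
    """Kind of text span a :class:`Mention` denotes."""

    MIR = "MIR"
    DISEASE = "DISEASE"
    GENE = "GENE"
    PROCESS = "PROCESS"
    MIR_ASPECT = "MIR_ASPECT"
    DISEASE_ASPECT = "DISEASE_ASPECT"


@dataclass(frozen=True)
class Mention:
    """A typed text span with character offsets into ``DocumentRecord.text``.

    ``norm_id`` carries a normalized concept identifier passed through from a
    sidecar file (e.g. a MEDIC id for diseases); it is only meaningful for
    DISEASE and GENE mentions.  ``subtype`` records the trigger category for
    aspect/process candidates (e.g. ``"abundance"``, ``"outcome"``).
    """

    start: int
    end: int
    surface: str
    mtype: MentionType
    norm_id: str | None = None
    subtype: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid mention span [{self.start},{self.end})")

    def shifted(self, delta: int) -> "Mention":
        return replace(self, start=self.start + delta, end=self.end + delta)


@dataclass
class DocumentRecord:
    """One title+abstract record, with optional pre-computed mentions."""

    pmid: str
    title: str
    abstract: str
    external_mentions: list[Mention] = field(default_factory=list)

    @property
    def text(self) -> str:
        """``title + single space + abstract`` (PubTator offset convention)."""
        return f"{self.title} {self.abstract}" if self.abstract else self.title


class CorpusFormatError(ValueError):
    """Raised for malformed corpus files; carries the offending PMID."""


_PUBTATOR_TEXT_RE = re.compile(r"^(?P<pmid>[^|]+)\|(?P<kind>[ta])\|(?P<text>.*)$")

_SIDECAR_TYPE_MAP = {"disease": MentionType.DISEASE, "gene": MentionType.GENE}


def _parse_pubtator_block(lines: list[str]) -> DocumentRecord:
    pmid = title = abstract = None
    rows: list[tuple[str, ...]] = []
    for line in lines:
        m = _PUBTATOR_TEXT_RE.match(line)
        if m and m.group("kind") == "t" and title is None:
            pmid, title = m.group("pmid"), m.group("text")
        elif m and m.group("kind") == "a" and abstract is None:
            abstract = m.group("text")
        else:
            rows.append(tuple(line.split("\t")))
    if pmid is None or title is None or abstract is None:
        hint = pmid or (rows[0][0] if rows and rows[0] else "<unknown>")
        raise CorpusFormatError(f"PMID {hint}: block is missing a |t| or |a| line")

    record = DocumentRecord(pmid=pmid, title=title, abstract=abstract)
    text = record.text
    for row in rows:
        if len(row) < 5:
            logger.warning("PMID %s: skipping short annotation row %r", pmid, row)
            continue
        _, start_s, end_s, surface, mtype_s = row[:5]
        norm_id = row[5] if len(row) > 5 and row[5] else None
        mtype = _SIDECAR_TYPE_MAP.get(mtype_s.strip().lower())
        if mtype is None:
            # Sidecar types other than Disease/Gene (Species, Chemical, ...)
            # are not consumed by the pipeline.
            continue
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            logger.warning("PMID %s: non-numeric offsets in row %r", pmid, row)
            continue
        if not (0 <= start < end <= len(text)) or text[start:end] != surface:
            logger.warning(
                "PMID %s: mention %r at [%s,%s) does not match text slice %r; dropped",
                pmid, surface, start, end, text[start:end] if end <= len(text) else "",
            )
            continue
        record.external_mentions.append(
            Mention(start, end, surface, mtype, norm_id=norm_id)
        )
    return record


def read_pubtator(path: str | Path) -> list[DocumentRecord]:
    """Read a PubTator-format file into a list of :class:`DocumentRecord`.

    Annotation rows of type Disease/Gene become ``external_mentions``; rows
    whose offsets do not reproduce the annotated surface string are dropped
    with a warning (the record itself is kept).  A block without both a
    ``|t|`` and an ``|a|`` line raises :class:`CorpusFormatError`.
    """
    content = Path(path).read_text(encoding="utf-8")
    records = []
    for raw_block in re.split(r"\n\s*\n", content.strip()):
        lines = [ln for ln in raw_block.splitlines() if ln.strip()]
        if lines:
            records.append(_parse_pubtator_block(lines))
    return records


_PMID_HEADER_RE = re.compile(r"^#\s*pmid\s*:\s*(\S+)\s*$", re.IGNORECASE)


def read_plaintext(path: str | Path) -> DocumentRecord:
    """Read a single plain-text record: title line, then abstract lines.

    The PMID is taken from a leading ``#pmid: <id>`` header if present,
    otherwise from the file stem.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    pmid = path.stem
    if lines and (m := _PMID_HEADER_RE.match(lines[0])):
        pmid = m.group(1)
        lines = lines[1:]
    lines = [ln for ln in (l.strip() for l in lines) if ln]
    if not lines:
        raise CorpusFormatError(f"{path}: empty plain-text record")
    return DocumentRecord(pmid=pmid, title=lines[0], abstract=" ".join(lines[1:]))


def read_pubmed_xml(path: str | Path) -> list[DocumentRecord]:
    """Read PubMed XML (``PubmedArticle`` elements) into records."""
    root = ET.parse(str(path)).getroot()
    records = []
    for art in root.iter("PubmedArticle"):
        pmid = art.findtext(".//PMID", default="").strip()
        title_el = art.find(".//ArticleTitle")
        title = "".join(title_el.itertext()).strip() if title_el is not None else ""
        abstract = " ".join(
            "".join(el.itertext()).strip() for el in art.findall(".//AbstractText")
        ).strip()
        if pmid and title:
            records.append(DocumentRecord(pmid=pmid, title=title, abstract=abstract))
    return records


# Output ------------------------------------------------------------------

TRIPLET_COLUMNS = (
    "pmid",
    "mir",
    "mir_aspect",
    "relation_category",
    "trigger",
    "disease",
    "disease_aspect",
    "linking_entities",
    "sentence_index",
    "evidence_sentence",
    "score",
)

_WS_RE = re.compile(r"[\t\n\r]+")


def _clean_cell(value: object) -> str:
    return _WS_RE.sub(" ", "" if value is None else str(value))


def triplet_row(ev) -> dict:
    """Flatten a ScoredEvidence object into an output row dict."""
    t = ev.triplet
    first = t.relations[0] if t.relations else None
    return {
        "pmid": t.pmid,
        "mir": t.mir.key,
        "mir_aspect": t.mir.aspect_surface or "",
        "relation_category": first.category if first else "",
        "trigger": first.trigger if first else "",
        "disease": t.disease.key if t.disease else "",
        "disease_aspect": (t.disease.aspect_surface or "") if t.disease else "",
        "linking_entities": ";".join(le.key for le in t.linking),
        "sentence_index": t.sentence_index,
        "evidence_sentence": t.evidence_sentence,
        "score": ev.final_score,
    }


def write_triplets(records: Sequence, path: str | Path, format: str = "tsv") -> None:
    """Write scored association triplets as TSV or JSON Lines.

    Rows are ordered by (pmid, sentence_index, order of extraction); the TSV
    has exactly the :data:`TRIPLET_COLUMNS` columns, with tabs/newlines inside
    cells replaced by single spaces so the file stays strictly tabular.
    """
    rows = [triplet_row(ev) for ev in records]
    rows.sort(key=lambda r: (str(r["pmid"]), int(r["sentence_index"])))
    path = Path(path)
    if format == "tsv":
        lines = ["\t".join(TRIPLET_COLUMNS)]
        lines += [
            "\t".join(_clean_cell(row[c]) for c in TRIPLET_COLUMNS) for row in rows
        ]
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    elif format == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for row in rows:
                fh.write(json.dumps(row, sort_keys=True) + "\n")
    else:
        raise ValueError(f"unknown output format {format!r}")


def read_triplets_jsonl(path: str | Path) -> list[dict]:
    """Read back a JSONL triplet dump (round-trip partner of write_triplets)."""
    rows = []
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                rows.append(json.loads(line))
    return rows
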