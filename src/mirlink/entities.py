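"""Detection of miR mentions, disease mentions, aspect and linking candidates.

miR mentions follow the community naming convention: a prefix (miR, MIR,
miRNA, microRNA -- plus the classical ``let`` family), an identifying number,
and optional suffixes (a letter, ``-1``, ``-3p``/``-5p``, cluster slashes).
They are detected with a single regular expression whose boundaries may not
fall inside a longer alphanumeric token ("mirage" and "smirk" contain no miR).

Disease mentions are taken from sidecar annotations when present (PubTator
rows carried on the record) and otherwise from a small bundled lexicon using
case-insensitive longest match.  Aspect terms (expression levels, mutation
state, disease outcome/diagnostic/treatment vocabulary) and linking-entity
candidates (genes, cellular processes) are detected here as *candidates*
only: they become aspects or linking entities downstream, once a syntactic
dependency ties them to a miR or disease.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .corpus_io import DocumentRecord, Mention, MentionType
from .lexicon import TriggerLexicon

__all__ = [
    "MIR_RE",
    "detect_mir_mentions",
    "normalize_mir",
    "detect_disease_mentions",
    "detect_gene_mentions",
    "detect_candidate_aspects",
    "detect_linking_candidates",
    "resolve_overlaps",
    "MiREntity",
    "DiseaseEntity",
    "LinkingEntity",
]

# Prefixes: miR/mir/MIR/miRNA/microRNA (case-insensitive), plus "let" which
# must be hyphenated (let-7...).  An optional 3-letter species code (hsa-)
# may precede.  The identifying number may carry a letter suffix, -arm tags
# (-3p/-5p), extra numeric parts (miR-17-92 clusters) and slash-joined
# cluster members (miR-221/222).
MIR_RE = re.compile(
    r"""
    (?<![A-Za-z0-9-])                       # left boundary
    (?:[a-z]{3}-)?                          # optional species prefix (hsa-)
    (?:
        (?:micro-?rna|mirna|mir)[-\s]?\d+   # miR-21, microRNA1, miR 144
      | let-\d+                             # let-7
    )
    [a-z]?                                  # family letter (miR-196a, let-7i)
    (?:-\d+[a-z]?)*                         # -1 / cluster parts (miR-17-92)
    (?:-[35]p)?                             # arm
    (?:/\d+[a-z]?(?:-[35]p)?)*              # slash clusters (miR-221/222)
    (?![A-Za-z0-9])                         # right boundary
    """,
    re.IGNORECASE | re.VERBOSE,
)


def detect_mir_mentions(text: str) -> list[Mention]:
    """All miR name mentions in ``text`` as MIR mentions."""
    return [
        Mention(m.start(), m.end(), m.group(0), MentionType.MIR)
        for m in MIR_RE.finditer(text)
    ]


_MIR_PREFIX_RE = re.compile(r"^(?:[a-z]{3}-)?(?:micro-?rna|mirna|mir)[-\s]?", re.I)


def normalize_mir(surface: str) -> str:
    """Canonical lowercase key of a miR mention.

    All prefix spellings collapse to ``mir-``: ``MicroRNA-9`` -> ``mir-9``,
    ``miRNA-143`` -> ``mir-143``; ``let-7i`` keeps its family prefix.
    A species code is dropped (hsa-miR-21 -> mir-21).
    """
    s = surface.lower().strip()
    if "let-" in s:
        return "let-" + s.split("let-", 1)[1]
    m = _MIR_PREFIX_RE.match(s)
    if m:
        return "mir-" + s[m.end():]
    return s


def _word_bounded(text_lower: str, start: int, end: int) -> bool:
    before = text_lower[start - 1] if start > 0 else " "
    after = text_lower[end] if end < len(text_lower) else " "
    return not before.isalnum() and not after.isalnum()


def _lexicon_scan(text: str, terms: list[str], mtype: MentionType) -> list[Mention]:
    """Case-insensitive longest-match scan of ``terms`` over ``text``.

    ``terms`` must be sorted longest-first; at each position the first
    (longest) matching term wins and scanning resumes after it.
    """
    low = text.lower()
    mentions: list[Mention] = []
    i = 0
    n = len(low)
    while i < n:
        if i > 0 and low[i - 1].isalnum():
            i += 1
            continue
        best = None
        for term in terms:
            end = i + len(term)
            if low.startswith(term, i) and end <= n and _word_bounded(low, i, end):
                best = end
                break  # terms are longest-first
        if best is not None:
            mentions.append(Mention(i, best, text[i:best], mtype))
            i = best
        else:
            i += 1
    return mentions


def detect_disease_mentions(
    record: DocumentRecord, lexicon: TriggerLexicon
) -> list[Mention]:
    """Disease mentions: sidecar pass-through, else bundled-lexicon lookup.

    When the record carries sidecar DISEASE mentions they are returned
    unchanged (offsets were validated at read time).  Records with no disease
    mention anywhere are skipped by the pipeline downstream.
    """
    sidecar = [m for m in record.external_mentions if m.mtype is MentionType.DISEASE]
    if sidecar:
        return sorted(sidecar, key=lambda m: m.start)
    return _lexicon_scan(record.text, lexicon.diseases, MentionType.DISEASE)


def detect_gene_mentions(
    record: DocumentRecord, lexicon: TriggerLexicon
) -> list[Mention]:
    """Gene mentions: sidecar pass-through, else bundled-lexicon lookup."""
    sidecar = [m for m in record.external_mentions if m.mtype is MentionType.GENE]
    if sidecar:
        return sorted(sidecar, key=lambda m: m.start)
    terms = sorted(lexicon.genes, key=len, reverse=True)
    return _lexicon_scan(record.text, terms, MentionType.GENE)


def resolve_overlaps(mentions: list[Mention]) -> list[Mention]:
    """Drop same-type mentions nested in or overlapping a longer one."""
    kept: list[Mention] = []
    for m in sorted(mentions, key=lambda m: (m.mtype.value, m.end - m.start), reverse=True):
        if any(
            k.mtype is m.mtype and m.start < k.end and k.start < m.end for k in kept
        ):
            continue
        kept.append(m)
    return sorted(kept, key=lambda m: (m.start, m.end))


_ASPECT_SUBTYPE = {
    "MIR_ASPECT_ABUNDANCE": ("abundance", MentionType.MIR_ASPECT),
    "MIR_ASPECT_STATE": ("state", MentionType.MIR_ASPECT),
    "DISEASE_OUTCOME": ("outcome", MentionType.DISEASE_ASPECT),
    "DISEASE_DIAGNOSTIC": ("diagnostic", MentionType.DISEASE_ASPECT),
    "DISEASE_TREATMENT": ("treatment", MentionType.DISEASE_ASPECT),
}


def detect_candidate_aspects(sentence, lexicon: TriggerLexicon) -> list[Mention]:
    """Aspect-trigger NP heads in a chunked sentence, as candidate mentions.

    These are candidates only -- a "level" or "metastasis" head becomes a miR
    or disease aspect downstream, after a noun-modification dependency links
    it to a miR/disease.  Two-token triggers ("overall survival") match via
    the head's immediate premodifier.
    """
    out: list[Mention] = []
    for np in sentence.noun_chunks():
        head = sentence.tokens[np.head]
        premod = sentence.tokens[np.head - 1].surface if np.head > np.start else None
        cat = lexicon.aspect_category(head.surface, premod)
        if cat is None:
            continue
        subtype, mtype = _ASPECT_SUBTYPE[cat]
        term = f"{premod} {head.surface}".lower() if (
            premod and f"{premod.lower()} {head.surface.lower()}"
            in lexicon.entries[cat]
        ) else head.surface
        start = head.start if term == head.surface else sentence.tokens[np.head - 1].start
        out.append(Mention(start, head.end, sentence.text_slice(start, head.end),
                           mtype, subtype=subtype))
    return out


def detect_linking_candidates(sentence, record, lexicon: TriggerLexicon) -> list:
    """Candidate linking entities (genes and cellular processes) in a sentence.

    Gene mentions come from the record-level detection clipped to the
    sentence; process candidates are NP heads found in the process dictionary
    or matching the morphological suffix rule.  Heads already classified as a
    miR/disease aspect in this sentence are excluded.
    """
    aspect_spans = {
        (m.start, m.end)
        for m in detect_candidate_aspects(sentence, lexicon)
    }
    out: list[LinkingEntity] = []
    for m in sentence.mentions:
        if m.mtype is MentionType.GENE:
            out.append(LinkingEntity(mention=m, kind="gene"))
    for np in sentence.noun_chunks():
        head = sentence.tokens[np.head]
        premod = sentence.tokens[np.head - 1].surface if np.head > np.start else None
        if (head.start, head.end) in aspect_spans or any(
            s <= head.start and head.end <= e for (s, e) in aspect_spans
        ):
            continue
        if any(m.start <= head.start and head.end <= m.end for m in sentence.mentions
               if m.mtype in (MentionType.MIR, MentionType.DISEASE, MentionType.GENE)):
            continue
        if lexicon.is_process(head.surface, premod) or lexicon.process_by_suffix(
            head.surface
        ):
            mention = Mention(head.start, head.end, head.surface,
                              MentionType.PROCESS, subtype="process")
            out.append(LinkingEntity(mention=mention, kind="process"))
    return out


# Entity classes -----------------------------------------------------------


@dataclass
class MiREntity:
    """A miR together with an (optional) aspect attached by noun modification."""

    mir: Mention
    aspect: Mention | None = None
    aspect_kind: str | None = None  # expression | mutation | methylation | other_state
    qualifier: str | None = None  # high / low / reduced ... as written

    @property
    def key(self) -> str:
        return normalize_mir(self.mir.surface)

    @property
    def aspect_surface(self) -> str | None:
        if self.aspect is None:
            return None
        q = f"{self.qualifier} " if self.qualifier else ""
        return f"{q}{self.aspect.surface}".lower()


@dataclass
class DiseaseEntity:
    """A disease together with an (optional) outcome/diagnostic/treatment aspect."""

    disease: Mention | None
    aspect: Mention | None = None
    aspect_kind: str | None = None  # outcome | diagnostic | treatment
    by_cooccurrence: bool = False  # aspect tied to the disease only by co-occurrence

    @property
    def key(self) -> str:
        if self.disease is not None:
            return self.disease.surface.lower()
        return (self.aspect.surface if self.aspect else "").lower()

    @property
    def aspect_surface(self) -> str | None:
        return self.aspect.surface.lower() if self.aspect else None


@dataclass
class LinkingEntity:
    """A gene or cellular process bridging a miR and a disease."""

    mention: Mention
    kind: str  # "gene" | "process"
    phrase: str | None = None  # noun-compound phrase for processes ("cell growth")

    @property
    def key(self) -> str:
        return (self.phrase or self.mention.surface).lower()
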