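"""End-to-end extraction pipeline over document records.

Order of operations per record (mirroring the system architecture): entity
detection -> sentence splitting and filtering -> chunking -> simplification ->
syntactic dependencies (original + simplified variants) -> semantic relations
-> association triplets -> informativeness scoring.  Per-record failures are
isolated: one malformed record never aborts a run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .corpus_io import DocumentRecord, Mention, MentionType
from .entities import (
    detect_candidate_aspects,
    detect_disease_mentions,
    detect_gene_mentions,
    detect_mir_mentions,
    resolve_overlaps,
)
from .lexicon import TriggerLexicon, load_default_lexicon
from .preprocess import (
    ChunkedSentence,
    attach_mentions,
    chunk,
    default_tagger,
    filter_sentences,
    split_sentences,
)
from .scoring import ScoredEvidence, score_sentence
from .semrel import (
    AssociationTriplet,
    SemanticRelation,
    assemble_triplets,
    categorize,
    compose_entities,
    relation_tuples,
    resolve_multiple_predicates,
)
from .simplify import detect_constructs, generate_simplified
from .syndep import extract_agent_theme, extract_noun_mod, extract_null_argument

logger = logging.getLogger(__name__)

__all__ = ["SentenceResult", "DocumentResult", "process_record", "process_text"]


@dataclass
class SentenceResult:
    sentence: ChunkedSentence
    relations: list[SemanticRelation] = field(default_factory=list)
    triplets: list[AssociationTriplet] = field(default_factory=list)
    scored: list[ScoredEvidence] = field(default_factory=list)

    @property
    def tuples(self):
        return relation_tuples(self.relations)


@dataclass
class DocumentResult:
    record: DocumentRecord
    skipped: bool = False  # no disease mention anywhere in the record
    sentences: list[SentenceResult] = field(default_factory=list)

    @property
    def scored(self) -> list[ScoredEvidence]:
        return [ev for s in self.sentences for ev in s.scored]

    @property
    def triplets(self) -> list[AssociationTriplet]:
        return [t for s in self.sentences for t in s.triplets]

    @property
    def tuples(self):
        out = set()
        for s in self.sentences:
            out |= s.tuples
        return out


def _detect_record_mentions(
    record: DocumentRecord, lexicon: TriggerLexicon
) -> list[Mention]:
    mentions = detect_mir_mentions(record.text)
    mentions += detect_disease_mentions(record, lexicon)
    mentions += detect_gene_mentions(record, lexicon)
    return resolve_overlaps(mentions)


def _variant_sentence(
    text: str,
    index: int,
    lexicon: TriggerLexicon,
    tagger,
    record: DocumentRecord,
) -> ChunkedSentence:
    """Build a standalone chunked sentence for a simplified variant.

    Mentions are re-detected on the generated text (sidecar mentions are
    recovered by surface matching), realizing the carried-through chunking.
    """
    pseudo = DocumentRecord(pmid=record.pmid, title=text, abstract="")
    for m in record.external_mentions:
        low = text.lower()
        start = low.find(m.surface.lower())
        if start >= 0:
            pseudo.external_mentions.append(
                Mention(start, start + len(m.surface), text[start:start + len(m.surface)],
                        m.mtype, norm_id=m.norm_id)
            )
    mentions = _detect_record_mentions(pseudo, lexicon)
    sent = ChunkedSentence(index=index, start=0, end=len(text), text=text)
    sent.mentions = mentions
    return chunk(sent, tagger)


def _extract_sentence(
    sentence: ChunkedSentence,
    record: DocumentRecord,
    lexicon: TriggerLexicon,
    tagger,
) -> SentenceResult:
    chunk(sentence, tagger)
    variants: list[tuple[ChunkedSentence, str]] = [(sentence, "original")]
    constructs = detect_constructs(sentence)
    for sim in generate_simplified(sentence, constructs):
        try:
            vs = _variant_sentence(sim.text, sentence.index, lexicon, tagger, record)
            variants.append((vs, "simplified:" + "+".join(sim.derivation)))
        except Exception:  # pragma: no cover - defensive
            logger.warning("failed to rebuild simplified sentence %r", sim.text)

    relations: list[SemanticRelation] = []
    seen_keys = set()
    all_deps = []
    for vs, prov in variants:
        noun_mods = extract_noun_mod(vs, lexicon)
        deps = extract_agent_theme(vs, lexicon, provenance=prov)
        deps += extract_null_argument(vs, deps, lexicon, provenance=prov)
        all_deps.extend(deps)
        rels = []
        for dep in deps:
            rel = categorize(dep, lexicon, noun_mods, vs)
            if rel is not None:
                rels.append(rel)
        for nm in noun_mods:
            rel = categorize(nm, lexicon, noun_mods, vs)
            if rel is not None:
                rels.append(rel)
        rels = resolve_multiple_predicates(rels, lexicon, noun_mods, vs)
        for rel in rels:
            k = rel.key()
            if k in seen_keys:
                continue
            seen_keys.add(k)
            relations.append(rel)

    compose_entities(relations, sentence, all_deps, lexicon)
    triplets = assemble_triplets(relations, sentence, record)
    aspect_candidates = detect_candidate_aspects(sentence, lexicon)
    scored = [
        score_sentence(t, sentence, lexicon, relations, aspect_candidates)
        for t in triplets
    ]
    return SentenceResult(sentence, relations, triplets, scored)


def process_record(
    record: DocumentRecord,
    lexicon: TriggerLexicon | None = None,
    tagger=None,
    require_disease: bool = True,
) -> DocumentResult:
    """Run the full pipeline on one record.

    ``require_disease=False`` disables the abstract-level disease filter;
    useful for analysing bare dependency/relation examples that have no
    disease context.
    """
    lexicon = lexicon or load_default_lexicon()
    tagger = tagger or default_tagger()
    result = DocumentResult(record=record)

    mentions = _detect_record_mentions(record, lexicon)
    if require_disease and not any(
        m.mtype is MentionType.DISEASE for m in mentions
    ):
        result.skipped = True
        logger.info("PMID %s: no disease mention; record skipped", record.pmid)
        return result

    sentences = split_sentences(record)
    attach_mentions(sentences, mentions)
    for sentence in filter_sentences(sentences):
        try:
            result.sentences.append(
                _extract_sentence(sentence, record, lexicon, tagger)
            )
        except Exception:
            logger.exception(
                "PMID %s sentence %d: extraction failed; sentence skipped",
                record.pmid, sentence.index,
            )
    return result


def process_text(
    text: str,
    pmid: str = "NA",
    lexicon: TriggerLexicon | None = None,
    tagger=None,
    require_disease: bool = True,
) -> DocumentResult:
    """Convenience wrapper: run the pipeline on one sentence/abstract string."""
    record = DocumentRecord(pmid=pmid, title=text, abstract="")
    return process_record(record, lexicon=lexicon, tagger=tagger,
                          require_disease=require_disease)
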