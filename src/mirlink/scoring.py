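"""Sentence informativeness scoring on a 1-3 scale.

Evidence sentences differ sharply in how much a reader learns about a
miR-disease association: a sentence that *explains* the association (through
a target gene or a chain of events) is worth more than one that merely states
an expression difference.  The rules:

**3 -- highly informative**: the sentence explains the connection, signaled
by (a) a null-argument dependency ("functions as a tumor suppressor *by
targeting CtBP1*..."), (b) at least two semantic relations forming an event
sequence marked by contribute/result/cause/support connectives, or (c)
target-gene information together with another relation.

**2 -- informative**: both diagnostic and treatment disease aspects, a
regulation of a linking entity (gene or process), or a treatment aspect in
theme position.

**1 -- somewhat informative**: an altered-expression relation, an
involvement relation, a diagnostic aspect -- or anything that matched no
higher rule.

Adjustments (each applied at most once, then clamped to [1, 3]): +1 when an
outcome aspect is present; -1 when a diagnostic/treatment aspect occurs only
by co-occurrence (outside every relation); -1 for hedging (might, could,
suggest, propose and variants).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .corpus_io import MentionType
from .entities import DiseaseEntity, LinkingEntity, MiREntity
from .lexicon import TriggerLexicon
from .preprocess import ChunkedSentence
from .semrel import AssociationTriplet, SemanticRelation

__all__ = ["ScoredEvidence", "score_sentence", "rank_sentences"]


@dataclass
class ScoredEvidence:
    triplet: AssociationTriplet
    base_score: int
    adjustments: list[tuple[str, int]] = field(default_factory=list)
    final_score: int = 0
    rule_trace: list[str] = field(default_factory=list)


def _aspect_kinds_in_relations(relations) -> set[str]:
    kinds = set()
    for r in relations:
        for e in r.entities:
            if isinstance(e, (MiREntity, DiseaseEntity)) and e.aspect_kind:
                kinds.add(e.aspect_kind)
    return kinds


def _distinct(relations: list[SemanticRelation]) -> list[SemanticRelation]:
    seen, out = set(), []
    for r in relations:
        if r.category == "state":
            continue
        k = r.key()
        if k not in seen:
            seen.add(k)
            out.append(r)
    return out


def score_sentence(
    triplet: AssociationTriplet,
    sentence: ChunkedSentence,
    lexicon: TriggerLexicon,
    relations: list[SemanticRelation] | None = None,
    aspect_candidates=None,
) -> ScoredEvidence:
    """Score one evidence sentence (see module docstring for the rubric).

    ``relations`` defaults to the triplet's own chain but should be the full
    sentence-level relation set when available -- the event-sequence and
    co-occurrence rules are sentence-level observations.
    """
    rels = _distinct(relations if relations is not None else triplet.relations)
    trace: list[str] = []
    tokens_low = [t.surface.lower() for t in sentence.tokens]

    null_arg = any(
        getattr(r.source_dep, "null_argument", False) for r in rels
    )
    connective = any(t in lexicon.connectives for t in tokens_low)
    target_gene = any(r.trigger.startswith("target") for r in rels)
    kinds = _aspect_kinds_in_relations(rels)
    reg_of_linking = any(
        r.category == "regulation"
        and isinstance(r.theme_entity, LinkingEntity)
        and r.theme_entity.kind in ("gene", "process")
        for r in rels
    )
    treat_theme = any(
        isinstance(r.theme_entity, DiseaseEntity)
        and r.theme_entity.aspect_kind == "treatment"
        for r in rels
    )
    altered_expression = any(
        (isinstance(e, MiREntity) and e.aspect_kind in
         ("expression", "mutation", "methylation", "other_state"))
        or r.category == "found_in"
        for r in rels
        for e in r.entities
    )
    involvement = any(r.category == "involvement" for r in rels)

    if null_arg:
        base = 3
        trace.append("explanatory:null_argument")
    elif len(rels) >= 2 and connective:
        base = 3
        trace.append("explanatory:event_sequence")
    elif target_gene and len(rels) >= 2:
        base = 3
        trace.append("explanatory:target_gene_plus_relation")
    elif ("diagnostic" in kinds and "treatment" in kinds):
        base = 2
        trace.append("informative:diagnostic_and_treatment")
    elif reg_of_linking:
        base = 2
        trace.append("informative:linking_entity_regulation")
    elif treat_theme:
        base = 2
        trace.append("informative:treatment_theme")
    else:
        base = 1
        if altered_expression:
            trace.append("somewhat:altered_expression")
        elif involvement:
            trace.append("somewhat:involvement")
        elif "diagnostic" in kinds:
            trace.append("somewhat:diagnostic_aspect")
        else:
            trace.append("somewhat:default")

    adjustments: list[tuple[str, int]] = []

    outcome_present = "outcome" in kinds or any(
        m.mtype is MentionType.DISEASE_ASPECT and m.subtype == "outcome"
        for m in (aspect_candidates or [])
    )
    if outcome_present:
        adjustments.append(("outcome_upgrade", +1))

    # diagnostic/treatment aspect present only by co-occurrence
    used_aspects = {
        (e.aspect.start, e.aspect.end)
        for r in (relations or [])
        for e in r.entities
        if isinstance(e, (MiREntity, DiseaseEntity)) and e.aspect is not None
    }
    cooc = any(
        m.subtype in ("diagnostic", "treatment")
        and (m.start, m.end) not in used_aspects
        for m in (aspect_candidates or [])
    )
    if cooc:
        adjustments.append(("cooccurrence_aspect_downgrade", -1))

    if any(t in lexicon.doubt for t in tokens_low):
        adjustments.append(("hedging_downgrade", -1))

    final = max(1, min(3, base + sum(d for _, d in adjustments)))
    trace.extend(name for name, _ in adjustments)
    return ScoredEvidence(
        triplet=triplet,
        base_score=base,
        adjustments=adjustments,
        final_score=final,
        rule_trace=trace,
    )


def rank_sentences(scored: list[ScoredEvidence]) -> list[ScoredEvidence]:
    """Stable sort: score descending, ties by (pmid, sentence_index)."""
    return sorted(
        scored,
        key=lambda ev: (
            -ev.final_score,
            str(ev.triplet.pmid),
            ev.triplet.sentence_index,
        ),
    )
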