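"""Semantic relation assignment and miR-disease association assembly.

A dependency becomes a semantic relation when its predicate head (after
stripping modal/auxiliary modifiers -- the head of the final verb group)
matches one of six trigger categories: involvement, regulation, association,
is-a, found-in and state.  The relation's arguments are then resolved to
typed entities:

* miR entities -- a miR alone or with an abundance/state aspect attached by
  noun modification ("downregulation of mir-26a", "high miR-199a expression");
* disease entities -- a disease alone or through an outcome / diagnostic /
  treatment aspect ("tumor metastasis in osteosarcoma", "biomarker for ...
  colorectal cancer"); an aspect head with no local disease argument composes
  with a co-occurring disease mention in the same sentence;
* linking entities -- genes and cellular processes that bridge the miR and
  the disease; the linking-entity -> disease connection is frequently left
  implicit, realized here as same-sentence co-occurrence.

When several triggers stack between one agent and one ultimate theme
("involved in the *regulation of* apoptosis"), only the more specific
relation is kept: regulation outranks involvement and is-a.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

from .corpus_io import Mention, MentionType
from .entities import DiseaseEntity, LinkingEntity, MiREntity, normalize_mir
from .lexicon import FOUND_IN_IMPLIED_ASPECT, TriggerLexicon
from .preprocess import ChunkedSentence, NOUN_TAGS
from .syndep import AgentThemeDep, NPView, NounModDep

__all__ = [
    "SemanticRelation",
    "AssociationTriplet",
    "resolve_np",
    "categorize",
    "resolve_multiple_predicates",
    "compose_entities",
    "assemble_triplets",
    "relation_tuples",
]

Entity = MiREntity | DiseaseEntity | LinkingEntity

_ASPECT_KIND = {
    "MIR_ASPECT_ABUNDANCE": "expression",
    "DISEASE_OUTCOME": "outcome",
    "DISEASE_DIAGNOSTIC": "diagnostic",
    "DISEASE_TREATMENT": "treatment",
}

_STATE_KIND = {
    "mutation": "mutation", "mutations": "mutation", "variant": "mutation",
    "variants": "mutation", "polymorphism": "mutation",
    "polymorphisms": "mutation", "methylation": "methylation",
    "hypermethylation": "methylation", "hypomethylation": "methylation",
}


@dataclass
class SemanticRelation:
    category: str  # involvement | regulation | association | is_a | found_in | state
    agent_entity: Entity | None
    theme_entity: Entity | None
    trigger: str
    source_dep: object = None
    provenance: str = "original"
    hedged: bool = False
    pending_theme: NPView | None = None  # nominal chain awaiting resolution

    @property
    def entities(self) -> list[Entity]:
        return [e for e in (self.agent_entity, self.theme_entity) if e is not None]

    def mir_entity(self) -> MiREntity | None:
        for e in self.entities:
            if isinstance(e, MiREntity):
                return e
        return None

    def key(self) -> tuple:
        def ekey(e):
            return None if e is None else (type(e).__name__, e.key)

        return (ekey(self.agent_entity), self.category, ekey(self.theme_entity))


@dataclass
class AssociationTriplet:
    pmid: str
    mir: MiREntity
    disease: DiseaseEntity | None
    linking: list[LinkingEntity]
    relations: list[SemanticRelation]
    sentence_index: int
    evidence_sentence: str


# --- NP -> entity resolution -------------------------------------------------


def _noun_run(np: NPView) -> str:
    """Contiguous noun tokens ending at the head ("cell growth", "transition")."""
    toks = np.sentence.tokens
    i = np.head
    while i - 1 >= np.base_start and toks[i - 1].pos in NOUN_TAGS:
        i -= 1
    return " ".join(t.surface for t in toks[i : np.head + 1]).lower()


def _noun_mod_for(np: NPView, noun_mods: list[NounModDep]) -> NounModDep | None:
    for nm in noun_mods:
        if nm.head == np.head:
            return nm
    return None


def resolve_np(
    np: NPView | None,
    lexicon: TriggerLexicon,
    noun_mods: list[NounModDep],
    sentence: ChunkedSentence,
    position: str = "theme",
) -> Entity | None:
    """Resolve a maximal NP to a miR / disease / linking entity, or None.

    Resolution is head-driven: the base-NP head decides the entity type.  An
    aspect-trigger head composes with its noun-modification modifier; an
    outcome/diagnostic/treatment head with no modifier composes with a
    co-occurring disease mention.  Morphological (-sion/-tion/...) process
    readings are admitted in theme position only -- an agent must be an
    explicitly recognized entity.
    """
    if np is None:
        return None
    head_tok = np.head_token
    # a CD head ("suppressor 1") defers to the preceding noun
    if head_tok.pos == "CD" and np.head - 1 >= np.base_start:
        np = dc_replace_np(np, np.head - 1)
        head_tok = np.head_token

    m = np.head_in_mention(MentionType.MIR)
    if m is not None:
        return _mir_entity(m, np, noun_mods)
    m = np.head_in_mention(MentionType.DISEASE)
    if m is not None:
        return DiseaseEntity(disease=m)
    m = np.head_in_mention(MentionType.GENE)
    if m is not None:
        return LinkingEntity(mention=m, kind="gene")

    nm = _noun_mod_for(np, noun_mods)
    premod = (
        np.sentence.tokens[np.head - 1].surface if np.head > np.base_start else None
    )
    cat = lexicon.aspect_category(head_tok.surface, premod)
    if cat is not None:
        head_mention = Mention(head_tok.start, head_tok.end, head_tok.surface,
                               MentionType.MIR_ASPECT if cat.startswith("MIR")
                               else MentionType.DISEASE_ASPECT)
        if nm is not None and nm.modifier.mtype is MentionType.MIR:
            return MiREntity(mir=nm.modifier, aspect=head_mention,
                             aspect_kind=_mir_aspect_kind(cat, head_tok.surface),
                             qualifier=nm.qualifier)
        if nm is not None and nm.modifier.mtype is MentionType.DISEASE:
            return DiseaseEntity(disease=nm.modifier, aspect=head_mention,
                                 aspect_kind=_ASPECT_KIND.get(cat))
        if nm is not None and nm.modifier.mtype is MentionType.GENE:
            return LinkingEntity(mention=nm.modifier, kind="gene")
        if cat.startswith("DISEASE"):
            disease = next(
                (m for m in sentence.mentions if m.mtype is MentionType.DISEASE),
                None,
            )
            return DiseaseEntity(disease=disease, aspect=head_mention,
                                 aspect_kind=_ASPECT_KIND.get(cat),
                                 by_cooccurrence=True)
        return None  # unattached miR aspect

    if lexicon.is_role_noun(head_tok.surface, premod):
        return LinkingEntity(
            mention=Mention(head_tok.start, head_tok.end, head_tok.surface,
                            MentionType.PROCESS, subtype="role"),
            kind="role", phrase=_noun_run(np))

    if lexicon.is_process(head_tok.surface, premod) or (
        position == "theme" and lexicon.process_by_suffix(head_tok.surface)
    ):
        return LinkingEntity(
            mention=Mention(head_tok.start, head_tok.end, head_tok.surface,
                            MentionType.PROCESS, subtype="process"),
            kind="process", phrase=_noun_run(np))
    return None


def dc_replace_np(np: NPView, new_head: int) -> NPView:
    return NPView(np.sentence, np.start, np.end, np.base_start, np.base_end, new_head)


def _mir_aspect_kind(cat: str, head_surface: str) -> str:
    if cat == "MIR_ASPECT_ABUNDANCE":
        return "expression"
    return _STATE_KIND.get(head_surface.lower(), "other_state")


def _mir_entity(m: Mention, np: NPView, noun_mods: list[NounModDep]) -> MiREntity:
    """A bare miR NP; an aspect whose modifier is this miR does not attach
    here (the aspect head is then the NP head and resolves above)."""
    return MiREntity(mir=m)


# --- categorization ----------------------------------------------------------


def categorize(
    dep: AgentThemeDep | NounModDep,
    lexicon: TriggerLexicon,
    noun_mods: list[NounModDep] | None = None,
    sentence: ChunkedSentence | None = None,
) -> SemanticRelation | None:
    """Assign a semantic category to a dependency, or None.

    Negated dependencies are discarded.  is-a relations are gated on the
    theme being a diagnostic/treatment aspect noun or a role noun ("tumor
    suppressor"), so bare copulas do not flood false positives.  A theme NP
    headed by a regulation nominalization with an of-PP is kept *pending* for
    :func:`resolve_multiple_predicates`.
    """
    noun_mods = noun_mods or []
    if isinstance(dep, NounModDep):
        return _state_relation(dep, lexicon, sentence)

    pred = dep.predicate
    if pred.negated or dep.agent is None:
        return None
    sent = sentence or (dep.agent.sentence if dep.agent else None)

    category = None
    trigger = pred.multiword_trigger
    if trigger is not None:
        if trigger == "play a role in":
            category = "involvement"
        else:
            adj, prep = trigger.split()
            category = lexicon.adjective_predicates.get((adj, prep))
    else:
        category = lexicon.relation_category(pred.lemma, pred.prep)
        trigger = pred.lemma if pred.prep is None else f"{pred.lemma} {pred.prep}"
    if category is None:
        return None

    agent = resolve_np(dep.agent, lexicon, noun_mods, sent, position="agent")
    if agent is None:
        return None
    theme = resolve_np(dep.theme, lexicon, noun_mods, sent, position="theme")

    pending = None
    if theme is None:
        pending = _pending_nominal(dep.theme, lexicon)
        if pending is None:
            return None
    elif isinstance(theme, LinkingEntity) and theme.kind in ("role", "process"):
        # "a regulator of X": the theme head may itself be a specific trigger
        if _pending_nominal(dep.theme, lexicon) is not None and category in (
            "involvement", "is_a",
        ):
            pending = dep.theme

    if category == "is_a" and pending is None:
        ok = (
            isinstance(theme, DiseaseEntity)
            and theme.aspect_kind in ("diagnostic", "treatment")
        ) or (isinstance(theme, LinkingEntity) and theme.kind == "role")
        if not ok:
            return None

    if not _has_anchor_entity(agent, theme):
        return None

    if category == "found_in":
        kind = lexicon.found_in_kind(pred.lemma, pred.prep)
        if kind == "aspect" and isinstance(agent, MiREntity) and agent.aspect is None:
            agent = _implied_aspect(agent, pred, sent, lexicon)

    hedged = bool(sent) and any(
        t.surface.lower() in lexicon.doubt for t in sent.tokens
    )
    return SemanticRelation(
        category=category,
        agent_entity=agent,
        theme_entity=None if pending is not None else theme,
        trigger=trigger,
        source_dep=dep,
        provenance=dep.provenance,
        hedged=hedged,
        pending_theme=pending if pending is not None else None,
    )


def _pending_nominal(theme_np: NPView | None, lexicon: TriggerLexicon):
    """Theme NP headed by a regulation nominalization with an of-PP."""
    if theme_np is None:
        return None
    head = theme_np.head_token.surface.lower()
    lemma = lexicon.nominal_lemma.get(head)
    if lemma is None:
        return None
    if lexicon.relation_category(lemma) != "regulation":
        return None
    if theme_np.of_pp() is None:
        return None
    return theme_np


def _has_anchor_entity(*entities) -> bool:
    return any(isinstance(e, (MiREntity, DiseaseEntity)) for e in entities)


def _implied_aspect(
    agent: MiREntity, pred, sentence, lexicon: TriggerLexicon
) -> MiREntity:
    implied = FOUND_IN_IMPLIED_ASPECT.get(pred.lemma)
    if implied is None:
        return agent
    kind, qualifier = implied
    tok = sentence.tokens[pred.head]
    # synthetic aspect mention: the surface names the inferred aspect, not a
    # text slice ("overexpressed in" implies expression:high)
    aspect = Mention(tok.start, tok.end, kind, MentionType.MIR_ASPECT,
                     subtype="state" if kind == "mutation" else "abundance")
    return MiREntity(mir=agent.mir, aspect=aspect,
                     aspect_kind=kind, qualifier=qualifier)


def _state_relation(
    dep: NounModDep, lexicon: TriggerLexicon, sentence
) -> SemanticRelation | None:
    head_mention = Mention(
        0, 1, dep.head_surface, MentionType.MIR_ASPECT
        if dep.category.startswith("MIR") else MentionType.DISEASE_ASPECT,
    ) if sentence is None else Mention(
        sentence.tokens[dep.head].start, sentence.tokens[dep.head].end,
        dep.head_surface,
        MentionType.MIR_ASPECT if dep.category.startswith("MIR")
        else MentionType.DISEASE_ASPECT,
    )
    if dep.modifier.mtype is MentionType.MIR:
        ent = MiREntity(mir=dep.modifier, aspect=head_mention,
                        aspect_kind=_mir_aspect_kind(dep.category, dep.head_surface),
                        qualifier=dep.qualifier)
    elif dep.modifier.mtype is MentionType.DISEASE:
        ent = DiseaseEntity(disease=dep.modifier, aspect=head_mention,
                            aspect_kind=_ASPECT_KIND.get(dep.category))
    else:
        return None
    return SemanticRelation(category="state", agent_entity=ent, theme_entity=None,
                            trigger=dep.head_surface.lower(), source_dep=dep)


# --- multiple predicate triggers ---------------------------------------------

SPECIFICITY = {"regulation": 3, "involvement": 2, "is_a": 2, "association": 2,
               "found_in": 2, "state": 1}


def resolve_multiple_predicates(
    relations: list[SemanticRelation],
    lexicon: TriggerLexicon,
    noun_mods: list[NounModDep] | None = None,
    sentence: ChunkedSentence | None = None,
) -> list[SemanticRelation]:
    """Keep only the more specific relation of a stacked trigger chain.

    "miR-9 is involved in the regulation of apoptosis" first yields
    [miR-9, involved in, regulation-of-apoptosis]; the inner regulation
    trigger is more specific, so the output is [miR-9, regulates, apoptosis].
    Never increases the relation count and never drops a regulation relation.
    """
    noun_mods = noun_mods or []
    out: list[SemanticRelation] = []
    for rel in relations:
        if rel.pending_theme is None:
            out.append(rel)
            continue
        np = rel.pending_theme
        head = np.head_token
        nominal_lemma = lexicon.nominal_lemma.get(head.surface.lower())
        inner_theme = resolve_np(np.of_pp(), lexicon, noun_mods,
                                 sentence or np.sentence, position="theme")
        if inner_theme is None or nominal_lemma is None:
            continue  # unresolvable chain: drop the general relation
        out.append(
            SemanticRelation(
                category="regulation",
                agent_entity=rel.agent_entity,
                theme_entity=inner_theme,
                trigger=head.surface.lower(),
                source_dep=rel.source_dep,
                provenance=rel.provenance,
                hedged=rel.hedged,
            )
        )
    return out


# --- entity composition and triplets -----------------------------------------


def compose_entities(
    relations: list[SemanticRelation],
    sentence: ChunkedSentence,
    deps: list[AgentThemeDep] | None = None,
    lexicon: TriggerLexicon | None = None,
) -> tuple[list[MiREntity], list[DiseaseEntity]]:
    """Collect the composed miR and disease entities of a sentence.

    Aspects attach through state (noun-modification) relations and through
    found-in aspect-class predicates; additionally an agentless passive of an
    expression verb ("miR-23b is epigenetically down-regulated") synthesizes
    an expression aspect for its subject miR.
    """
    mirs: dict[str, MiREntity] = {}
    diseases: dict[str, DiseaseEntity] = {}

    def add(e):
        if isinstance(e, MiREntity):
            prev = mirs.get(e.key)
            if prev is None or (prev.aspect is None and e.aspect is not None):
                mirs[e.key] = e
        elif isinstance(e, DiseaseEntity):
            prev = diseases.get(e.key)
            if prev is None or (prev.aspect is None and e.aspect is not None):
                diseases[e.key] = e

    for rel in relations:
        for e in rel.entities:
            add(e)

    if deps and lexicon:
        for dep in deps:
            pred = dep.predicate
            if (
                pred.voice == "passive"
                and dep.theme is None
                and dep.agent is not None
                and pred.lemma in FOUND_IN_IMPLIED_ASPECT
            ):
                mir = dep.agent.head_in_mention(MentionType.MIR)
                if mir is not None:
                    add(_implied_aspect(MiREntity(mir=mir), pred,
                                        dep.agent.sentence, lexicon))
    return list(mirs.values()), list(diseases.values())


def assemble_triplets(
    relations: list[SemanticRelation],
    sentence: ChunkedSentence,
    record,
) -> list[AssociationTriplet]:
    """miR-disease association triplets for one sentence.

    A triplet joins a miR entity with a disease entity connected either
    directly (a relation has both) or implicitly (the miR relates to a
    linking entity and a disease mention co-occurs in the sentence).  The
    connecting relation chain and the linking entities are recorded.
    """
    non_state = [r for r in relations if r.category != "state"]
    mirs: dict[str, MiREntity] = {}
    for r in non_state:
        m = r.mir_entity()
        if m is not None and (m.key not in mirs or mirs[m.key].aspect is None):
            mirs[m.key] = m

    sentence_disease = next(
        (m for m in sentence.mentions if m.mtype is MentionType.DISEASE), None
    )
    triplets = []
    for key, mir in mirs.items():
        chain = [
            r
            for r in non_state
            if r.mir_entity() is not None and r.mir_entity().key == key
        ]
        direct_disease = None
        linking: dict[str, LinkingEntity] = {}
        for r in chain:
            for e in r.entities:
                if isinstance(e, DiseaseEntity) and direct_disease is None:
                    direct_disease = e
                if isinstance(e, LinkingEntity) and e.kind in ("gene", "process"):
                    linking.setdefault(e.key, e)
        disease = direct_disease
        if disease is None and sentence_disease is not None:
            disease = DiseaseEntity(disease=sentence_disease, by_cooccurrence=True)
        if disease is None:
            continue  # no disease in the sentence: no association
        triplets.append(
            AssociationTriplet(
                pmid=record.pmid,
                mir=mir,
                disease=disease,
                linking=list(linking.values()),
                relations=chain,
                sentence_index=sentence.index,
                evidence_sentence=sentence.text,
            )
        )
    return triplets


def relation_tuples(
    relations: list[SemanticRelation],
) -> set[tuple[str, str, str]]:
    """Normalized (miR, category, counterpart) tuples for evaluation.

    State relations are entity composition, not associations, and are
    excluded; the miR side is normalized (``MicroRNA-9`` -> ``mir-9``).
    """
    out = set()
    for r in relations:
        if r.category == "state":
            continue
        mir = r.mir_entity()
        if mir is None:
            continue
        other = next(
            (e for e in r.entities if e is not mir), None
        )
        if other is None:
            continue
        out.add((mir.key, r.category, other.key))
    return out
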