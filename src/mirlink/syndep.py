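"""Lexico-syntactic dependency extraction over chunked sentences.

Two dependency families feed semantic-relation assignment:

* **agent-theme of predicate** -- subject/object of a (possibly multi-group)
  verb predicate, voice-normalized so "apoptosis is regulated by miR-9" and
  "miR-9 regulates apoptosis" yield the same (agent, predicate, theme);
  nominalized predicates ("miR-9 regulation of cell proliferation") and
  multi-word predicates ("play a role in", "is crucial for") are covered;
* **noun modification** -- a miR/disease/gene modifying an aspect head noun,
  as a premodifier ("mir-21 overexpression") or through an of/in-PP
  ("metastasis of gastric cancer").

Null-argument clauses -- an omitted agent inherited from an earlier clause,
signaled by "to"+verb, "via"/"through"/"by"+gerund or +nominalization -- are
extracted by :func:`extract_null_argument` using the agents of previously
extracted dependencies.  Arguments are *maximal* noun phrases (base NP plus
attached PPs), since agents/themes routinely carry their prepositional
modifiers ("expression of mir-9", "proliferation of U87 cells").
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .corpus_io import Mention, MentionType
from .lexicon import TriggerLexicon
from .preprocess import (
    BE_FORMS,
    CONNECTIVE_PREPS,
    ChunkedSentence,
    NOUN_TAGS,
    VERB_TAGS,
)

__all__ = [
    "NPView",
    "PredicateSpan",
    "AgentThemeDep",
    "NounModDep",
    "maximal_np",
    "extract_agent_theme",
    "extract_null_argument",
    "extract_noun_mod",
]


@dataclass
class NPView:
    """A maximal noun phrase: base NP plus its attached PP chain."""

    sentence: ChunkedSentence
    start: int  # token index, inclusive
    end: int  # token index, exclusive
    base_start: int
    base_end: int
    head: int  # token index of the base-NP head

    @property
    def surface(self) -> str:
        toks = self.sentence.tokens[self.start : self.end]
        return " ".join(t.surface for t in toks)

    @property
    def head_token(self):
        return self.sentence.tokens[self.head]

    def mentions(self, mtypes: tuple[MentionType, ...] | None = None) -> list[Mention]:
        out = self.sentence.mentions_in_span(self.start, self.end)
        if mtypes:
            out = [m for m in out if m.mtype in mtypes]
        return out

    def base_mentions(self, mtypes=None) -> list[Mention]:
        out = self.sentence.mentions_in_span(self.base_start, self.base_end)
        if mtypes:
            out = [m for m in out if m.mtype in mtypes]
        return out

    def head_in_mention(self, mtype: MentionType) -> Mention | None:
        ht = self.head_token
        for m in self.sentence.mentions:
            if m.mtype is mtype and m.start <= ht.start and ht.end <= m.end:
                return m
        return None

    def attached_pps(self) -> list[tuple[str, "NPView"]]:
        """(preposition, NP) pairs for PPs attached to this maximal NP."""
        s = self.sentence
        out = []
        for ci, c in enumerate(s.chunks):
            if c.ctype == "PP" and self.base_end <= c.start and c.end <= self.end:
                out.append((c.prep, _pp_np(s, ci)))
        return out

    def of_pp(self, preps=("of",)) -> "NPView | None":
        for prep, np in self.attached_pps():
            if prep in preps:
                return np
        return None


def _pp_np(sentence: ChunkedSentence, ci: int) -> NPView:
    """NPView over the NP inside PP chunk ``ci`` plus its own attached PPs."""
    c = sentence.chunks[ci]
    end = c.end
    for cj in range(ci + 1, len(sentence.chunks)):
        nxt = sentence.chunks[cj]
        if nxt.ctype == "PP" and nxt.attached_to is not None and nxt.start == end:
            end = nxt.end
        else:
            break
    return NPView(sentence, c.start + 1, end, c.start + 1, c.end, c.head)


def maximal_np(sentence: ChunkedSentence, ci: int) -> NPView:
    """Maximal NP rooted at NP chunk ``ci``: attached PPs and a trailing
    parenthetical are absorbed."""
    chunks = sentence.chunks
    base = chunks[ci]
    end_chunk = ci
    end = base.end
    j = ci + 1
    while j < len(chunks):
        c = chunks[j]
        if c.ctype == "PP" and c.attached_to is not None and c.start == end:
            end = c.end
            end_chunk = j
            j += 1
        elif (
            c.ctype == "O"
            and sentence.tokens[c.start].surface == "("
            and j + 2 < len(chunks)
            and chunks[j + 1].ctype == "NP"
            and chunks[j + 2].ctype == "O"
            and sentence.tokens[chunks[j + 2].start].surface == ")"
        ):
            end = chunks[j + 2].end
            j += 3
        else:
            break
    return NPView(sentence, base.start, end, base.start, base.end, base.head)


@dataclass
class PredicateSpan:
    """The predicate of an agent-theme dependency (1-2 verb groups or a noun)."""

    head: int  # token index of the head verb / nominal
    lemma: str
    voice: str = "active"  # active | passive
    is_nominalized: bool = False
    multiword_trigger: str | None = None
    prep: str | None = None  # preposition introducing the theme, if any
    negated: bool = False
    vg_start: int = -1
    vg_end: int = -1

    @property
    def surface(self) -> str:
        return self.lemma


@dataclass
class AgentThemeDep:
    agent: NPView | None
    predicate: PredicateSpan
    theme: NPView | None
    null_argument: bool = False
    connective: str | None = None  # to+V | via+NOM | through+NOM | by+Ving ...
    conjoined: bool = False  # agent shared across coordinated predicates
    provenance: str = "original"


@dataclass
class NounModDep:
    head: int  # token index of the aspect head noun
    head_surface: str
    category: str  # lexicon aspect category
    modifier: Mention
    form: str  # premodifier | prepositional_of
    qualifier: str | None = None  # high/low/reduced/poor ... premodifier
    np_start: int = -1
    np_end: int = -1


_ENTITY_TYPES = (MentionType.MIR, MentionType.DISEASE, MentionType.GENE)


def _vg_tokens(sentence: ChunkedSentence, ci: int):
    c = sentence.chunks[ci]
    return sentence.tokens[c.start : c.end]


def _vg_is_passive(sentence: ChunkedSentence, ci: int) -> bool:
    toks = _vg_tokens(sentence, ci)
    head = sentence.tokens[sentence.chunks[ci].head]
    if head.pos != "VBN":
        return False
    return any(t.surface.lower() in BE_FORMS for t in toks)


def _build_predicate(
    sentence: ChunkedSentence, vg_indices: list[int], lexicon: TriggerLexicon
) -> PredicateSpan:
    last = vg_indices[-1]
    head_i = sentence.chunks[last].head
    head = sentence.tokens[head_i]
    lemma = lexicon.lemma_of(head.surface)
    voice = "passive" if _vg_is_passive(sentence, last) else "active"
    negated = any(
        t.surface.lower() in ("not", "never")
        for ci in vg_indices
        for t in _vg_tokens(sentence, ci)
    ) or _negated_left(sentence, vg_indices[0])
    return PredicateSpan(
        head=head_i,
        lemma=lemma,
        voice=voice,
        negated=negated,
        vg_start=sentence.chunks[vg_indices[0]].start,
        vg_end=sentence.chunks[last].end,
    )


def _negated_left(sentence: ChunkedSentence, ci: int) -> bool:
    start = sentence.chunks[ci].start
    if start > 0 and sentence.tokens[start - 1].surface.lower() in ("not", "never"):
        return True
    return False


def _find_theme(
    sentence: ChunkedSentence, after: int, pred: PredicateSpan, lexicon: TriggerLexicon
) -> tuple[NPView | None, int]:
    """Theme NP following the predicate; fills pred.prep/multiword.

    ``after`` is the chunk index right after the last verb group.  Returns
    (theme, chunk index after the consumed material).
    """
    chunks = sentence.chunks
    toks = sentence.tokens
    k = after
    if k >= len(chunks):
        return None, k

    # multi-word: play (a) role in X
    if pred.lemma == "play" and chunks[k].ctype == "NP":
        head = toks[chunks[k].head].surface.lower()
        if head == "role" and k + 1 < len(chunks) and chunks[k + 1].ctype == "PP" \
                and chunks[k + 1].prep == "in":
            pred.multiword_trigger = "play a role in"
            pred.prep = "in"
            return _pp_np(sentence, k + 1), k + 2

    # adjectival predicate: be crucial/important/... for X
    if pred.lemma == "be" and chunks[k].ctype == "O":
        adj = toks[chunks[k].start].surface.lower()
        if k + 1 < len(chunks) and chunks[k + 1].ctype == "PP":
            prep = chunks[k + 1].prep
            if (adj, prep) in lexicon.adjective_predicates:
                pred.multiword_trigger = f"{adj} {prep}"
                pred.prep = prep
                return _pp_np(sentence, k + 1), k + 2

    if chunks[k].ctype == "NP":
        return maximal_np(sentence, k), k + 1
    if chunks[k].ctype == "PP":
        pred.prep = chunks[k].prep
        return _pp_np(sentence, k), k + 1
    return None, k


def _subject_for(
    sentence: ChunkedSentence, ci: int
) -> tuple[NPView | None, bool]:
    """Subject NP of the VG at chunk ``ci``; (None, True) when the predicate
    is coordinated to an earlier clause (a comma/CC separates it)."""
    chunks = sentence.chunks
    j = ci - 1
    conjoined = False
    while j >= 0:
        c = chunks[j]
        if c.ctype == "O":
            tok = sentence.tokens[c.start]
            if tok.surface == "," or tok.pos == "CC":
                return None, True
            if tok.pos == "RB":
                j -= 1
                continue
            if tok.surface == ")":
                # skip a parenthetical group back to its anchor
                j -= 1
                depth = 1
                while j >= 0 and depth:
                    if chunks[j].ctype == "O":
                        s = sentence.tokens[chunks[j].start].surface
                        depth += s == ")"
                        depth -= s == "("
                    j -= 1
                continue
            return None, False
        if c.ctype in ("NP", "PP"):
            # walk back through an attached PP chain to the base NP
            while c.ctype == "PP":
                if c.attached_to is None:
                    return None, False
                j = c.attached_to
                c = chunks[j]
            return maximal_np(sentence, j), False
        return None, False
    return None, conjoined


def extract_agent_theme(
    sentence: ChunkedSentence, lexicon: TriggerLexicon, provenance: str = "original"
) -> list[AgentThemeDep]:
    """Agent-theme dependencies from verbal and nominalized predicates.

    The predicate head is the head of the *final* verb group of a run of
    consecutive groups ("is known" + "to directly regulate" -> regulate); a
    passive by-PP swaps agent and theme; coordinated predicates with an
    elided subject inherit the nearest preceding explicit agent.
    """
    chunks = sentence.chunks
    deps: list[AgentThemeDep] = []
    consumed: set[int] = set()
    last_agent: NPView | None = None

    for ci, c in enumerate(chunks):
        if c.ctype != "VG" or ci in consumed:
            continue
        first_tok = sentence.tokens[c.start]
        prev_surface = (
            sentence.tokens[c.start - 1].surface.lower() if c.start > 0 else ""
        )
        # null-argument clauses are extracted separately
        if prev_surface in CONNECTIVE_PREPS:
            continue
        if first_tok.pos == "TO" and ci > 0 and chunks[ci - 1].ctype in ("NP", "PP"):
            continue

        group = [ci]
        j = ci + 1
        while j < len(chunks) and chunks[j].ctype == "VG":
            group.append(j)
            consumed.add(j)
            j += 1
        pred = _build_predicate(sentence, group, lexicon)
        subject, conjoined = _subject_for(sentence, ci)
        theme, _ = _find_theme(sentence, j, pred, lexicon)

        agent: NPView | None = subject
        dep_conjoined = False
        if subject is None and conjoined and last_agent is not None:
            agent = last_agent
            dep_conjoined = True

        if pred.voice == "passive":
            if theme is not None and pred.prep == "by":
                agent, theme = theme, subject  # voice normalization
                pred.prep = None
            else:
                # subject is semantically the entity the predicate is about:
                # keep it as agent for prepositional themes ("is associated
                # with X", "was found in Y"); no theme -> state-like
                agent = subject if not dep_conjoined else agent

        deps.append(
            AgentThemeDep(agent, pred, theme, conjoined=dep_conjoined,
                          provenance=provenance)
        )
        if subject is not None:
            last_agent = subject

    deps.extend(_nominalization_deps(sentence, lexicon, provenance))
    return deps


def _nominalization_deps(
    sentence: ChunkedSentence, lexicon: TriggerLexicon, provenance: str
) -> list[AgentThemeDep]:
    """NP-internal predicates: "miR-9 regulation of cell proliferation".

    Requires both arguments: a mention-bearing premodifier (agent) and an
    attached of-PP (theme); a lone modifier is noun modification (state), not
    an agent-theme dependency.
    """
    out = []
    for ci, c in enumerate(sentence.chunks):
        if c.ctype != "NP":
            continue
        head = sentence.tokens[c.head]
        lemma = lexicon.nominal_lemma.get(head.surface.lower())
        if lemma is None:
            continue
        np = maximal_np(sentence, ci)
        theme = np.of_pp()
        if theme is None:
            continue
        premods = [
            m
            for m in sentence.mentions_in_span(c.start, c.head)
            if m.mtype in _ENTITY_TYPES
        ]
        if not premods:
            continue
        agent_mention = premods[-1]
        a_start, a_end = _mention_token_span(sentence, agent_mention)
        agent = NPView(sentence, a_start, a_end, a_start, a_end, a_end - 1)
        pred = PredicateSpan(head=c.head, lemma=lemma, is_nominalized=True)
        out.append(AgentThemeDep(agent, pred, theme, provenance=provenance))
    return out


def _mention_token_span(sentence: ChunkedSentence, m: Mention) -> tuple[int, int]:
    idx = [
        i
        for i, t in enumerate(sentence.tokens)
        if t.start >= m.start and t.end <= m.end
    ]
    if not idx:  # mention straddles token boundaries; best effort
        idx = [
            i
            for i, t in enumerate(sentence.tokens)
            if t.start < m.end and m.start < t.end
        ]
    return idx[0], idx[-1] + 1


def extract_null_argument(
    sentence: ChunkedSentence,
    deps: list[AgentThemeDep],
    lexicon: TriggerLexicon,
    provenance: str = "original",
) -> list[AgentThemeDep]:
    """Dependencies whose agent is inherited across a null-argument connective.

    Connectives: "to" + verb after a theme; "by"/"via"/"through" + gerund;
    "by"/"via"/"through" + nominalization (with of-PP theme).  The inherited
    agent is that of the nearest preceding dependency with an explicit agent;
    with no prior agent the clause yields nothing.
    """
    chunks = sentence.chunks
    out: list[AgentThemeDep] = []

    def inherited_agent(before_tok: int) -> NPView | None:
        cands = [
            d
            for d in deps + out
            if d.agent is not None and d.predicate.head < before_tok
        ]
        if not cands:
            return None
        return max(cands, key=lambda d: d.predicate.head).agent

    for ci, c in enumerate(chunks):
        if c.ctype == "VG":
            first_tok = sentence.tokens[c.start]
            prev = sentence.tokens[c.start - 1] if c.start > 0 else None
            prev_surface = prev.surface.lower() if prev else ""
            connective = None
            if prev_surface in CONNECTIVE_PREPS and first_tok.pos == "VBG":
                connective = f"{prev_surface}+Ving"
            elif (
                first_tok.pos == "TO"
                and ci > 0
                and chunks[ci - 1].ctype in ("NP", "PP")
            ):
                connective = "to+V"
            if connective is None:
                continue
            agent = inherited_agent(c.start)
            if agent is None:
                continue
            pred = _build_predicate(sentence, [ci], lexicon)
            theme, _ = _find_theme(sentence, ci + 1, pred, lexicon)
            out.append(
                AgentThemeDep(agent, pred, theme, null_argument=True,
                              connective=connective, provenance=provenance)
            )
        elif c.ctype == "PP" and c.prep in CONNECTIVE_PREPS:
            head = sentence.tokens[c.head]
            lemma = lexicon.nominal_lemma.get(head.surface.lower())
            if lemma is None:
                continue
            np = _pp_np(sentence, ci)
            theme = np.of_pp()
            if theme is None:
                continue
            agent = inherited_agent(c.start)
            if agent is None:
                continue
            pred = PredicateSpan(head=c.head, lemma=lemma, is_nominalized=True)
            out.append(
                AgentThemeDep(agent, pred, theme, null_argument=True,
                              connective=f"{c.prep}+NOM", provenance=provenance)
            )
    return out


_QUALIFIERS = {"high", "low", "reduced", "increased", "decreased", "elevated",
               "poor", "shorter", "higher", "lower", "aberrant", "altered"}


def extract_noun_mod(
    sentence: ChunkedSentence, lexicon: TriggerLexicon
) -> list[NounModDep]:
    """Noun-modification dependencies: entity modifier + aspect head noun.

    The head must be an aspect trigger; the modifier a miR/disease/gene
    mention, either premodifying inside the base NP or inside an attached
    of/in-PP (for/with are also searched for diagnostic and treatment heads,
    whose disease argument often arrives as "biomarker *for* X").
    """
    out: list[NounModDep] = []
    for ci, c in enumerate(sentence.chunks):
        if c.ctype not in ("NP", "PP"):
            continue
        if c.ctype == "PP":
            np = _pp_np(sentence, ci)
        else:
            np = maximal_np(sentence, ci)
        head = sentence.tokens[np.head]
        premod_tok = (
            sentence.tokens[np.head - 1].surface if np.head > np.base_start else None
        )
        cat = lexicon.aspect_category(head.surface, premod_tok)
        if cat is None:
            continue
        # a miR aspect is modified by a miR (or a gene: "Camsap1 expression");
        # a disease aspect by a disease
        allowed = (
            (MentionType.MIR, MentionType.GENE)
            if cat.startswith("MIR")
            else (MentionType.DISEASE,)
        )
        qualifier = next(
            (
                t.surface.lower()
                for t in sentence.tokens[np.base_start : np.head]
                if t.surface.lower() in _QUALIFIERS
            ),
            None,
        )
        # premodifier form
        premods = [
            m
            for m in sentence.mentions_in_span(np.base_start, np.head)
            if m.mtype in allowed and m.end <= head.start
        ]
        if premods:
            out.append(NounModDep(np.head, head.surface, cat, premods[-1],
                                  "premodifier", qualifier, np.start, np.end))
            continue
        # prepositional form
        preps = ("of", "in")
        if cat in ("DISEASE_DIAGNOSTIC", "DISEASE_TREATMENT"):
            preps = ("of", "in", "for", "with")
        for prep, pp_np in np.attached_pps():
            if prep not in preps:
                continue
            cands = [m for m in pp_np.mentions(allowed)]
            if cands:
                out.append(NounModDep(np.head, head.surface, cat, cands[0],
                                      "prepositional_of", qualifier,
                                      np.start, np.end))
                break
    return out
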