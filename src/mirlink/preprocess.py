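"""Sentence splitting, tokenization, POS tagging and NP/VG/PP chunking.

The downstream dependency patterns operate on *chunks*: non-recursive noun
phrases (NP), verb groups (VG) and prepositional phrases (PP) produced by a
greedy finite-state grammar over Penn-Treebank POS tags.  POS tagging is a
pluggable contract -- any callable mapping a list of token surfaces to a list
of Penn tags may be injected -- and the default is :class:`RuleTagger`, a
deterministic lexicon+suffix tagger whose verb vocabulary is generated from
the trigger lexicon.  This keeps the whole pipeline reproducible offline and
independent of any statistical tagger.

Chunk grammar (one left-to-right pass):

* ``NP``:  (PDT)? (DT|PRP$)? (JJ|VBN|VBG|NN|NNS|NNP|CD)* ending at a noun;
  participle premodifiers are admitted only when context says they modify
  (see the tagger repair rules); a CC between premodifiers is kept inside
  the NP when a noun still follows ("proven or predicted target genes").
* ``VG``:  (MD|TO)? (RB)* verb+, with "able/unable/likely + to" bridging so
  "was able to inhibit" is one group; "is known" / "to directly regulate"
  remain two consecutive groups (merged later when finding the predicate).
* ``PP``:  IN + NP; a PP headed by of/in/for/with/... immediately following
  an NP attaches to it (right association); by/via/through never attach --
  they signal passive agents and null-argument clauses.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Sequence

from .corpus_io import DocumentRecord, Mention, MentionType
from .lexicon import TriggerLexicon, load_default_lexicon

__all__ = [
    "Token",
    "Chunk",
    "ChunkedSentence",
    "split_sentences",
    "filter_sentences",
    "tokenize",
    "RuleTagger",
    "default_tagger",
    "chunk",
]

NOUN_TAGS = {"NN", "NNS", "NNP"}
VERB_TAGS = {"VB", "VBD", "VBZ", "VBP", "VBN", "VBG"}
NP_PREMOD_TAGS = {"JJ", "JJR", "JJS", "VBN", "VBG", "NN", "NNS", "NNP", "CD"}
ATTACH_PREPS = {"of", "in", "for", "with", "on", "at", "within", "among",
                "between", "against", "from", "to"}
CONNECTIVE_PREPS = {"by", "via", "through"}
BE_FORMS = {"be", "is", "are", "was", "were", "been", "being", "am"}
HAVE_FORMS = {"have", "has", "had", "having"}


@dataclass(frozen=True)
class Token:
    surface: str
    pos: str
    start: int
    end: int


@dataclass
class Chunk:
    """A contiguous token group; ``head`` is a token index into the sentence."""

    ctype: str  # NP | VG | PP | O
    start: int  # token index, inclusive
    end: int  # token index, exclusive
    head: int
    attached_to: int | None = None  # chunk index this PP modifies
    prep: str | None = None  # preposition surface for PP


@dataclass
class ChunkedSentence:
    """A sentence with tokens, chunks and the mentions clipped to it.

    Offsets (``start``/``end`` and all token/mention offsets) refer to the
    *document* text the sentence was cut from, so mentions detected at the
    document level can be carried through unchanged.
    """

    index: int
    start: int
    end: int
    text: str
    tokens: list[Token] = field(default_factory=list)
    chunks: list[Chunk] = field(default_factory=list)
    mentions: list[Mention] = field(default_factory=list)

    def text_slice(self, start: int, end: int) -> str:
        return self.text[start - self.start : end - self.start]

    def noun_chunks(self) -> list[Chunk]:
        """NP chunks, plus PP chunks (whose embedded NP carries the head) --
        candidate detection must see nouns inside prepositional phrases."""
        return [c for c in self.chunks if c.ctype in ("NP", "PP")]

    def token_text(self, ti: int) -> str:
        return self.tokens[ti].surface

    def mentions_in_span(self, start_tok: int, end_tok: int) -> list[Mention]:
        if end_tok <= start_tok:
            return []
        s = self.tokens[start_tok].start
        e = self.tokens[end_tok - 1].end
        return [m for m in self.mentions if m.start >= s and m.end <= e]


# --- sentence splitting ----------------------------------------------------

_ABBREVS = {"et", "al", "fig", "figs", "e.g", "i.e", "vs", "approx", "ca",
            "no", "spp", "inc", "resp", "cf"}

_BOUNDARY_RE = re.compile(r"[.!?]+(?=\s)")


def _split_text(text: str, base: int) -> list[tuple[int, int]]:
    """Sentence spans (document offsets) within ``text`` starting at ``base``."""
    spans = []
    last = 0
    for m in _BOUNDARY_RE.finditer(text):
        prev = text[:m.start()].rstrip()
        word = prev.split()[-1].lower() if prev.split() else ""
        word = word.rstrip(".")
        if word in _ABBREVS or (len(word) == 1 and word.isalpha()):
            continue  # abbreviation or initial: not a boundary
        spans.append((last, m.end()))
        last = m.end()
    if text[last:].strip():
        spans.append((last, len(text)))
    out = []
    for s, e in spans:
        seg = text[s:e]
        lead = len(seg) - len(seg.lstrip())
        trail = len(seg) - len(seg.rstrip())
        if seg.strip():
            out.append((base + s + lead, base + e - trail))
    return out


def split_sentences(record: DocumentRecord) -> list[ChunkedSentence]:
    """Split a record into sentences; the title is always sentence 0."""
    text = record.text
    spans: list[tuple[int, int]] = []
    if record.title.strip():
        spans.append((0, len(record.title)))
    if record.abstract.strip():
        spans.extend(_split_text(record.abstract, len(record.title) + 1))
    return [
        ChunkedSentence(index=i, start=s, end=e, text=text[s:e])
        for i, (s, e) in enumerate(spans)
    ]


def attach_mentions(
    sentences: list[ChunkedSentence], mentions: Sequence[Mention]
) -> None:
    """Clip document-level mentions to the sentence that contains them."""
    for sent in sentences:
        sent.mentions = [
            m for m in mentions if m.start >= sent.start and m.end <= sent.end
        ]


def filter_sentences(sentences: list[ChunkedSentence]) -> list[ChunkedSentence]:
    """Keep only sentences containing at least one miR or disease mention."""
    return [
        s
        for s in sentences
        if any(m.mtype in (MentionType.MIR, MentionType.DISEASE) for m in s.mentions)
    ]


# --- tokenization ----------------------------------------------------------

_TOKEN_RE = re.compile(
    r"\d+\.\d+"  # decimals
    r"|[A-Za-z0-9](?:[A-Za-z0-9'/’-]*[A-Za-z0-9])?"  # words (internal -/')
    r"|[^\sA-Za-z0-9]"  # everything else, one symbol at a time
)


def tokenize(
    text: str, base: int = 0, protected: Sequence[tuple[int, int]] = ()
) -> list[tuple[str, int, int]]:
    """Tokenize ``text``; offsets are shifted by ``base``.

    Words keep internal hyphens and slashes, so miR names, gene symbols and
    hyphenated adjectives stay single tokens.  ``protected`` spans (document
    offsets, e.g. space-containing miR mentions) are merged into one token.
    """
    raw = [(m.group(0), base + m.start(), base + m.end())
           for m in _TOKEN_RE.finditer(text)]
    if not protected:
        return raw
    out: list[tuple[str, int, int]] = []
    i = 0
    while i < len(raw):
        span = next(
            (p for p in protected if p[0] <= raw[i][1] and raw[i][2] <= p[1]), None
        )
        if span is None:
            out.append(raw[i])
            i += 1
            continue
        j = i
        while j < len(raw) and raw[j][2] <= span[1]:
            j += 1
        s, e = raw[i][1], raw[j - 1][2]
        out.append((text[s - base : e - base], s, e))
        i = j
    return out


# --- POS tagging -----------------------------------------------------------

_CLOSED = {
    "the": "DT", "a": "DT", "an": "DT", "this": "DT", "these": "DT",
    "those": "DT", "either": "DT", "neither": "DT", "some": "DT", "any": "DT",
    "no": "DT",
    "all": "PDT", "both": "PDT", "each": "PDT",
    "which": "WDT", "that": "WDT", "who": "WDT", "whom": "WDT",
    "and": "CC", "or": "CC", "but": "CC", "nor": "CC",
    "to": "TO",
    "not": "RB", "never": "RB", "also": "RB", "only": "RB", "very": "RB",
    "we": "PRP", "it": "PRP", "they": "PRP", "he": "PRP", "she": "PRP",
    "i": "PRP", "you": "PRP",
    "its": "PRP$", "their": "PRP$", "our": "PRP$", "his": "PRP$",
    "her": "PRP$", "my": "PRP$", "your": "PRP$",
    "may": "MD", "might": "MD", "can": "MD", "could": "MD", "will": "MD",
    "would": "MD", "shall": "MD", "should": "MD", "must": "MD",
    "is": "VBZ", "are": "VBP", "was": "VBD", "were": "VBD", "be": "VB",
    "been": "VBN", "being": "VBG", "am": "VBP",
    "has": "VBZ", "have": "VBP", "had": "VBD",
    "does": "VBZ", "do": "VBP", "did": "VBD",
    "proven": "VBN", "shown": "VBN", "known": "VBN", "given": "VBN",
    "high": "JJ", "low": "JJ", "poor": "JJ", "shorter": "JJR", "higher": "JJR",
    "lower": "JJR", "early": "JJ", "likely": "JJ", "able": "JJ",
    "unable": "JJ", "novel": "JJ", "new": "JJ", "several": "JJ", "such": "JJ",
    "other": "JJ", "further": "JJ", "first": "JJ",
    "one": "CD", "two": "CD", "three": "CD", "four": "CD", "five": "CD",
    "six": "CD", "seven": "CD", "eight": "CD", "nine": "CD", "ten": "CD",
}

_PREPOSITIONS = {
    "of", "in", "for", "with", "by", "via", "through", "on", "at", "from",
    "as", "into", "within", "during", "after", "before", "between", "against",
    "among", "upon", "toward", "towards", "per", "without", "under", "over",
    "across", "than",
}

# common biomedical nouns the suffix rules would mistag
_NOUNS = {
    "cell", "cells", "gene", "genes", "patient", "patients", "tissue",
    "tissues", "sample", "samples", "role", "tumor", "tumour", "tumors",
    "protein", "proteins", "cancer", "cancers", "carcinoma", "abstract",
    "study", "studies", "sentence", "level", "levels", "mirnas", "mirna",
    "mir", "microrna", "micrornas", "data", "effect", "effects", "pathway",
    "pathways", "type", "types", "plasma", "serum", "line", "lines",
}

_JJ_SUFFIXES = ("ous", "ive", "ic", "al", "ary", "able", "ible", "less",
                "ful", "ant", "ent", "like", "free")


class RuleTagger:
    """Deterministic Penn-tagset tagger: lexicon first, then suffix rules.

    The verb vocabulary is generated from the trigger lexicon, so every
    predicate the patterns care about is guaranteed a verb tag; unknown
    words fall back to noun/adjective/adverb suffix heuristics.  Two repair
    passes disambiguate noun/verb homographs ("a therapeutic target") and
    -ed forms (past tense vs participle premodifier vs reduced relative).
    """

    def __init__(self, lexicon: TriggerLexicon | None = None):
        self.lex = lexicon or load_default_lexicon()
        # nouns known from the lexicons
        self.nouns: set[str] = set(_NOUNS)
        for cat, terms in self.lex.entries.items():
            for t in terms:
                self.nouns.update(t.split())
        for t in self.lex.role_nouns:
            self.nouns.update(t.split())
        self.nouns.update(self.lex.nominal_lemma.keys())
        # two-word lexicon terms: the second word is nominal after the first
        self.noun_bigrams: set[tuple[str, str]] = set()
        for terms in list(self.lex.entries.values()) + [self.lex.role_nouns]:
            for t in terms:
                words = t.split()
                if len(words) == 2:
                    self.noun_bigrams.add((words[0], words[1]))
        for d in self.lex.diseases:
            for w in d.split():
                if not w.endswith(_JJ_SUFFIXES):
                    self.nouns.add(w)
        self.verb_lemma = dict(self.lex.verb_lemma)

    # -- initial per-token tag ---------------------------------------------

    def _initial(self, word: str) -> str:
        low = word.lower()
        if not any(ch.isalnum() for ch in word):
            return word  # punctuation tags itself: "," "." "(" ")"
        if low in _CLOSED:
            return _CLOSED[low]
        if low in _PREPOSITIONS:
            return "IN"
        if re.fullmatch(r"\d+(\.\d+)?", word):
            return "CD"
        if low in self.verb_lemma:
            if low.endswith("ing"):
                return "VBG"
            if low.endswith("ed") or low in ("found", "knew", "did", "shown"):
                return "ED"  # ambiguous VBD/VBN, resolved in repair
            lemma = self.verb_lemma[low]
            if low != lemma and (low.endswith("s") or low.endswith("es")):
                return "VBZ"
            return "VB"
        if "-" in low and len(low) > 3:
            seg = low.rsplit("-", 1)[-1]
            if seg in self.verb_lemma and (seg.endswith("ed") or seg.endswith("ing")):
                return "ED" if seg.endswith("ed") else "VBG"
            if low.endswith(("ed", "ing")) or seg.endswith(_JJ_SUFFIXES):
                return "JJ"
        if low in self.nouns:
            return "NNS" if low.endswith("s") and not low.endswith(("ss", "sis", "us", "is")) else "NN"
        if low.endswith("ly"):
            return "RB"
        if any(ch.isdigit() for ch in word):
            return "NN"
        if low.endswith("ing"):
            return "VBG"
        if low.endswith("ed"):
            return "ED"
        if low.endswith(_JJ_SUFFIXES):
            return "JJ"
        if low.endswith("s") and not low.endswith(("ss", "sis", "us", "is")):
            stem = low[:-1]
            if stem in self.nouns or not stem.endswith(_JJ_SUFFIXES):
                return "NNS"
        return "NN"

    # -- repairs -------------------------------------------------------------

    _NOUNISH = {"NN", "NNS", "NNP", "CD", "JJ", "JJR", "JJS", "VBG", "ED", "VBN"}
    _PREMOD_LEFT = {"DT", "PDT", "JJ", "JJR", "CC", ",", "IN", "PRP$", "CD",
                    "VBN", "ED"}

    def __call__(self, words: Sequence[str]) -> list[str]:
        tags = [self._initial(w) for w in words]
        n = len(words)

        def prev_skipping_rb(i: int) -> int | None:
            j = i - 1
            while j >= 0 and tags[j] == "RB":
                j -= 1
            return j if j >= 0 else None

        # pass A: noun/verb homographs -- a verb-tagged token after a clear
        # NP-internal left context is a noun ("a therapeutic target").
        for i, w in enumerate(words):
            if tags[i] in ("VB", "VBZ") and w.lower() not in BE_FORMS | HAVE_FORMS:
                j = prev_skipping_rb(i)
                if j is None:
                    continue
                low = w.lower()
                known_noun = low in self.nouns or low.rstrip("s") in self.nouns
                # after DT/JJ/PRP$ a homograph is (almost) always nominal;
                # after a participle premodifier only known nouns flip
                bigram = (
                    i > 0 and (words[i - 1].lower(), low) in self.noun_bigrams
                )
                if tags[j] in ("DT", "PDT", "JJ", "JJR", "PRP$") or bigram or (
                    tags[j] in ("ED", "VBN") and known_noun
                ):
                    tags[i] = "NNS" if low.endswith("s") else "NN"

        # pass B: resolve ambiguous -ed forms
        for i, w in enumerate(words):
            if tags[i] != "ED":
                continue
            low = w.lower()
            j = prev_skipping_rb(i)
            prev_low = words[j].lower() if j is not None else ""
            nxt = tags[i + 1] if i + 1 < n else None
            if prev_low in BE_FORMS or prev_low in HAVE_FORMS:
                tags[i] = "VBN"  # passive / perfect
            elif nxt in self._NOUNISH and (
                j is None or tags[j] in self._PREMOD_LEFT
            ):
                tags[i] = "VBN"  # participial premodifier
            elif (
                i + 1 < n
                and words[i + 1].lower() in _PREPOSITIONS | {"to"}
                and (self.verb_lemma.get(low, low), words[i + 1].lower())
                in self.lex.relation_triggers
            ):
                tags[i] = "VBN"  # reduced relative ("genes involved in ...")
            else:
                tags[i] = "VBD"

        # "to" before a non-verb is a preposition ("linked to cancer")
        for i, w in enumerate(words):
            if tags[i] == "TO":
                k = i + 1
                while k < n and tags[k] == "RB":
                    k += 1
                if k >= n or tags[k] not in VERB_TAGS | {"VB"}:
                    tags[i] = "IN"
        return tags


_DEFAULT_TAGGER: RuleTagger | None = None


def default_tagger(lexicon: TriggerLexicon | None = None) -> RuleTagger:
    global _DEFAULT_TAGGER
    if lexicon is not None:
        return RuleTagger(lexicon)
    if _DEFAULT_TAGGER is None:
        _DEFAULT_TAGGER = RuleTagger()
    return _DEFAULT_TAGGER


# --- chunking --------------------------------------------------------------


def _np_end(tags: list[str], words: list[str], i: int) -> int | None:
    """Greedy base-NP scan starting at token i; returns end index or None."""
    n = len(tags)
    j = i
    if j < n and tags[j] == "PDT":
        j += 1
    if j < n and tags[j] in ("DT", "PRP$"):
        j += 1
    last_noun = None
    while j < n:
        t = tags[j]
        if t in ("NN", "NNS", "NNP", "CD"):
            last_noun = j
            j += 1
        elif t in ("JJ", "JJR", "JJS", "VBN", "VBG"):
            j += 1
        elif t == "CC" and last_noun is None:
            # keep CC inside the NP only for *premodifier* coordination
            # ("proven or predicted target genes"): no head noun seen yet,
            # the conjunct starts with a premodifier, and a noun follows
            k = j + 1
            ok = False
            while k < n:
                if tags[k] in ("NN", "NNS", "NNP", "CD"):
                    ok = tags[j + 1] in ("JJ", "JJR", "VBN", "VBG")
                    break
                if tags[k] not in ("JJ", "JJR", "VBN", "VBG", "RB"):
                    break
                k += 1
            if ok:
                j += 1
            else:
                break
        else:
            break
    if last_noun is None:
        return None
    return last_noun + 1


def _np_head(tags: list[str], start: int, end: int) -> int:
    for j in range(end - 1, start - 1, -1):
        if tags[j] in NOUN_TAGS:
            return j
    for j in range(end - 1, start - 1, -1):
        if tags[j] == "CD":
            return j
    return end - 1


def chunk(
    sentence: ChunkedSentence,
    tagger: Callable[[Sequence[str]], list[str]] | None = None,
    lexicon: TriggerLexicon | None = None,
) -> ChunkedSentence:
    """Tokenize, tag and chunk a sentence in place (idempotent).

    The tagger is any callable satisfying the POS-tagging contract; when
    omitted the bundled :class:`RuleTagger` is used.
    """
    tagger = tagger or default_tagger(lexicon)
    protected = [
        (m.start, m.end) for m in sentence.mentions if m.mtype is MentionType.MIR
    ]
    raw = tokenize(sentence.text, sentence.start, protected)
    words = [w for w, _, _ in raw]
    tags = list(tagger(words))

    # tokens covered by a miR mention are nouns regardless of surface shape
    for k, (w, s, e) in enumerate(raw):
        if any(ms <= s and e <= me for ms, me in protected):
            tags[k] = "NN"

    sentence.tokens = [Token(w, t, s, e) for (w, s, e), t in zip(raw, tags)]
    sentence.chunks = _chunk_tags(words, tags)
    return sentence


def _vg_scan(words: list[str], tags: list[str], i: int) -> int | None:
    """Scan a verb group starting at i; returns end index or None."""
    n = len(tags)
    j = i
    if j < n and tags[j] == "MD":
        j += 1
    elif j < n and tags[j] == "TO":
        j += 1
    saw_verb = False
    while j < n:
        t = tags[j]
        if t == "RB" and j + 1 < n and (
            tags[j + 1] in VERB_TAGS or tags[j + 1] in ("RB",)
        ):
            j += 1
        elif t in VERB_TAGS:
            saw_verb = True
            j += 1
        elif (
            saw_verb
            and t == "JJ"
            and words[j].lower() in ("able", "unable", "likely")
            and j + 1 < n
            and tags[j + 1] == "TO"
        ):
            j += 2  # bridge "able to" and continue with the verb
        else:
            break
    if not saw_verb or j == i:
        return None
    return j


def _vg_head(words: list[str], tags: list[str], start: int, end: int) -> int:
    for j in range(end - 1, start - 1, -1):
        if tags[j] in VERB_TAGS:
            return j
    return end - 1


def _chunk_tags(words: list[str], tags: list[str]) -> list[Chunk]:
    n = len(words)
    chunks: list[Chunk] = []
    has_nonfinite_vg = False  # an earlier to-infinitive or gerund VG
    i = 0

    def prev_nonspace(k: int) -> str:
        return words[k - 1].lower() if k > 0 else ""

    while i < n:
        t = tags[i]
        low = words[i].lower()

        # --- verb group?
        start_vg = False
        if t == "MD":
            start_vg = True
        elif t == "TO":
            k = i + 1
            while k < n and tags[k] == "RB":
                k += 1
            start_vg = k < n and tags[k] in VERB_TAGS
        elif t in ("VB", "VBZ", "VBP", "VBD"):
            start_vg = True
        elif t == "VBN":
            nxt = tags[i + 1] if i + 1 < n else None
            start_vg = nxt not in ("JJ", "NN", "NNS", "NNP", "CD", "VBG", "VBN")
        elif t == "VBG":
            prev = prev_nonspace(i)
            nxt = tags[i + 1] if i + 1 < n else None
            if prev in CONNECTIVE_PREPS:
                start_vg = True  # gerund clause: "by targeting ..."
            elif prev in (",", "and", "or") and has_nonfinite_vg:
                start_vg = True  # conjoined gerund: "... and inducing ..."
            elif nxt in ("JJ", "NN", "NNS", "NNP", "CD", "VBN"):
                start_vg = False  # premodifier: "circulating mir-150 levels"
            else:
                start_vg = True
        if start_vg:
            end = _vg_scan(words, tags, i)
            if end is not None:
                head = _vg_head(words, tags, i, end)
                chunks.append(Chunk("VG", i, end, head))
                if tags[i] in ("TO", "VBG") or tags[head] == "VBG":
                    has_nonfinite_vg = True
                i = end
                continue

        # --- prepositional phrase / noun phrase?
        if t == "IN":
            end = _np_end(tags, words, i + 1)
            if end is not None and not (
                low in CONNECTIVE_PREPS and tags[i + 1] == "VBG"
            ):
                head = _np_head(tags, i + 1, end)
                pp = Chunk("PP", i, end, head, prep=low)
                if (
                    chunks
                    and low in ATTACH_PREPS
                    and chunks[-1].ctype in ("NP", "PP")
                    and chunks[-1].end == i
                ):
                    pp.attached_to = len(chunks) - 1
                chunks.append(pp)
                i = end
                continue
            chunks.append(Chunk("O", i, i + 1, i))
            i += 1
            continue

        if t in NP_PREMOD_TAGS or t in ("DT", "PDT", "PRP$"):
            end = _np_end(tags, words, i)
            if end is not None:
                chunks.append(Chunk("NP", i, end, _np_head(tags, i, end)))
                i = end
                continue

        if t == "PRP":
            chunks.append(Chunk("NP", i, i + 1, i))
            i += 1
            continue

        chunks.append(Chunk("O", i, i + 1, i))
        i += 1
    return chunks
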