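"""Sentence simplification: detect complex constructs, emit simple clauses.

Abstracts state miR-disease relations inside appositives, coordinated lists,
relative and reduced relative clauses and parentheticals; the dependency
patterns downstream are deliberately local and would miss them.  This module
detects five construct kinds on a chunked sentence and rewrites each into
simple declarative sentences:

* list/pair conjunctions -- each member substituted for the whole
  coordination;
* appositives ("four miRNAs, miR-21, ..., and miR-196a") -- the counted
  anchor is identified so list members can stand in for it;
* relative clauses -- the pronoun is replaced by its anchor NP;
* reduced relative clauses -- a number-agreeing copula is inserted
  ("miR-21 *is* implicated in ...");
* parentheticals -- dropped, and substituted for their anchor.

Generated sentences are plain text with a derivation trace; the pipeline
re-chunks them and re-detects mentions, which realizes the carried-through
chunking deterministically.  The original sentence is always processed too.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .preprocess import ChunkedSentence, NOUN_TAGS

__all__ = [
    "SimplificationConstruct",
    "SimplifiedSentence",
    "detect_constructs",
    "generate_simplified",
]

_NUMBER_WORDS = {"one": 1, "two": 2, "three": 3, "four": 4, "five": 5,
                 "six": 6, "seven": 7, "eight": 8, "nine": 9, "ten": 10}


@dataclass
class SimplificationConstruct:
    kind: str  # conjunction_list | conjunction_pair | appositive |
    #            relative_clause | reduced_relative_clause | parenthetical
    span: tuple[int, int]  # token range (half open)
    members: list[tuple[int, int]] = field(default_factory=list)
    anchor: tuple[int, int] | None = None


@dataclass
class SimplifiedSentence:
    """A generated simple sentence (text + surfaces + derivation trace)."""

    text: str
    tokens: list[str]
    source_index: int
    derivation: list[str] = field(default_factory=list)


def _detokenize(tokens: list[str]) -> str:
    text = " ".join(tokens)
    text = re.sub(r"\s+([.,;:!?%)\]])", r"\1", text)
    text = re.sub(r"([(\[])\s+", r"\1", text)
    return text


def _np_runs(sentence: ChunkedSentence) -> list[list[int]]:
    """Runs of NP chunks separated only by commas / coordinating conjunctions."""
    chunks = sentence.chunks
    runs: list[list[int]] = []
    i = 0
    while i < len(chunks):
        if chunks[i].ctype != "NP":
            i += 1
            continue
        run = [i]
        j = i + 1
        while j < len(chunks):
            sep = []
            while j < len(chunks) and chunks[j].ctype == "O" and (
                sentence.tokens[chunks[j].start].surface in (",",)
                or sentence.tokens[chunks[j].start].pos == "CC"
            ):
                sep.append(sentence.tokens[chunks[j].start].surface.lower())
                j += 1
            if sep and j < len(chunks) and chunks[j].ctype == "NP":
                run.append(j)
                j += 1
            else:
                break
        runs.append(run)
        i = run[-1] + 1
    return [r for r in runs if len(r) >= 2]


def _has_cc(sentence: ChunkedSentence, run: list[int]) -> bool:
    lo = sentence.chunks[run[0]].end
    hi = sentence.chunks[run[-1]].start
    return any(
        t.pos == "CC" for t in sentence.tokens[lo:hi]
    )


def detect_constructs(sentence: ChunkedSentence) -> list[SimplificationConstruct]:
    """Detect simplification constructs in a chunked sentence."""
    out: list[SimplificationConstruct] = []
    chunks = sentence.chunks
    tokens = sentence.tokens

    # --- NP coordination runs: lists, pairs, appositives
    for run in _np_runs(sentence):
        if not _has_cc(sentence, run):
            continue  # commas alone do not coordinate
        spans = [(chunks[ci].start, chunks[ci].end) for ci in run]
        first = chunks[run[0]]
        rest = spans[1:]
        count = None
        for ti in range(first.start, first.end):
            if tokens[ti].pos == "CD":
                count = _NUMBER_WORDS.get(
                    tokens[ti].surface.lower(),
                    int(tokens[ti].surface) if tokens[ti].surface.isdigit() else None,
                )
        plural_anchor = tokens[first.head].pos == "NNS"
        if len(rest) >= 2 and (count == len(rest) or (plural_anchor and count)):
            # counted appositive: "four miRNAs, miR-21, ..., and miR-196a"
            out.append(SimplificationConstruct(
                "appositive", (spans[0][0], spans[-1][1]),
                members=rest, anchor=spans[0]))
            out.append(SimplificationConstruct(
                "conjunction_list", (rest[0][0], rest[-1][1]), members=rest))
        elif len(spans) >= 3:
            out.append(SimplificationConstruct(
                "conjunction_list", (spans[0][0], spans[-1][1]), members=spans))
        else:
            out.append(SimplificationConstruct(
                "conjunction_pair", (spans[0][0], spans[-1][1]), members=spans))

    # --- premodifier pair coordination inside an NP ("proven or predicted")
    for c in chunks:
        if c.ctype not in ("NP", "PP"):
            continue
        for ti in range(c.start + 1, c.end - 1):
            if (
                tokens[ti].pos == "CC"
                and tokens[ti - 1].pos in ("JJ", "JJR", "VBN", "VBG")
                and tokens[ti + 1].pos in ("JJ", "JJR", "VBN", "VBG")
            ):
                out.append(SimplificationConstruct(
                    "conjunction_pair", (ti - 1, ti + 2),
                    members=[(ti - 1, ti), (ti + 1, ti + 2)]))

    # --- relative clauses: NP [,] which/that VG ...
    for k, c in enumerate(chunks):
        if c.ctype != "O" or tokens[c.start].pos != "WDT":
            continue
        if not (k + 1 < len(chunks) and chunks[k + 1].ctype == "VG"):
            continue
        anchor = _preceding_np(sentence, k)
        if anchor is not None:
            out.append(SimplificationConstruct(
                "relative_clause", (c.start, _clause_end(sentence, c.start)),
                anchor=anchor))

    # --- reduced relative clauses: NP [,] [all|both|each] VG(VBN-initial) ...
    for k, c in enumerate(chunks):
        if c.ctype != "VG" or tokens[c.start].pos != "VBN":
            continue
        anchor = _preceding_np(sentence, k)
        if anchor is not None:
            out.append(SimplificationConstruct(
                "reduced_relative_clause",
                (c.start, _clause_end(sentence, c.start)), anchor=anchor))

    # --- parentheticals: NP ( NP ) -- the anchor may sit inside a PP
    for k in range(len(chunks) - 3):
        a, b, c2, d = chunks[k : k + 4]
        if (
            a.ctype in ("NP", "PP")
            and b.ctype == "O" and tokens[b.start].surface == "("
            and c2.ctype == "NP"
            and d.ctype == "O" and tokens[d.start].surface == ")"
        ):
            anchor = (a.start + (1 if a.ctype == "PP" else 0), a.end)
            out.append(SimplificationConstruct(
                "parenthetical", (b.start, d.end),
                members=[(c2.start, c2.end)], anchor=anchor))
    return out


def _preceding_np(sentence: ChunkedSentence, k: int) -> tuple[int, int] | None:
    """Base-NP span directly before chunk k, skipping a comma and all/both/each."""
    chunks = sentence.chunks
    j = k - 1
    while j >= 0 and chunks[j].ctype == "O" and (
        sentence.tokens[chunks[j].start].surface == ","
        or sentence.tokens[chunks[j].start].surface.lower() in ("all", "both", "each")
    ):
        j -= 1
    if j < 0:
        return None
    if chunks[j].ctype == "NP":
        return (chunks[j].start, chunks[j].end)
    if chunks[j].ctype == "PP":  # anchor inside a PP: "... of miR200a that ..."
        return (chunks[j].start + 1, chunks[j].end)
    return None


def _clause_end(sentence: ChunkedSentence, start: int) -> int:
    """Clause runs to the end of the sentence, minus final punctuation."""
    end = len(sentence.tokens)
    while end > start and sentence.tokens[end - 1].pos in (".", ",", ";"):
        end -= 1
    return end


def _surfaces(sentence: ChunkedSentence, span: tuple[int, int]) -> list[str]:
    return [t.surface for t in sentence.tokens[span[0] : span[1]]]


def _copula(sentence: ChunkedSentence, span: tuple[int, int]) -> str:
    head_pos = None
    for t in reversed(sentence.tokens[span[0] : span[1]]):
        if t.pos in NOUN_TAGS:
            head_pos = t.pos
            break
    return "are" if head_pos == "NNS" else "is"


def generate_simplified(
    sentence: ChunkedSentence, constructs: list[SimplificationConstruct]
) -> list[SimplifiedSentence]:
    """Generate simple sentences for the detected constructs.

    For an anchored clause whose anchor heads a counted appositive list,
    exactly one member-substituted sentence per list member is produced.
    Constructs are expanded outside-in in a single pass: generated sentences
    are not re-simplified.  A construct-free sentence yields no variants (the
    caller always retains the original).
    """
    out: list[SimplifiedSentence] = []
    seen: set[str] = set()
    all_tokens = [t.surface for t in sentence.tokens]

    def emit(tokens: list[str], kinds: list[str]) -> None:
        tokens = [tok for tok in tokens if tok]
        if tokens and tokens[-1] not in (".", "!", "?"):
            tokens = tokens + ["."]
        text = _detokenize(tokens)
        if text not in seen and text != sentence.text:
            seen.add(text)
            out.append(SimplifiedSentence(text, tokens, sentence.index, kinds))

    appositives = [c for c in constructs if c.kind == "appositive"]

    def members_for_anchor(anchor: tuple[int, int]) -> list[tuple[int, int]]:
        for app in appositives:
            if app.anchor == anchor or (
                app.anchor and anchor[0] >= app.anchor[0] and anchor[1] <= app.span[1]
            ):
                return app.members
        return []

    for c in constructs:
        if c.kind == "reduced_relative_clause" and c.anchor:
            clause = _surfaces(sentence, c.span)
            members = members_for_anchor(c.anchor)
            if members:
                for m in members:
                    subj = _surfaces(sentence, m)
                    emit(subj + [_copula(sentence, m)] + clause,
                         ["appositive", "conjunction_list", c.kind])
            else:
                subj = _surfaces(sentence, c.anchor)
                emit(subj + [_copula(sentence, c.anchor)] + clause, [c.kind])
        elif c.kind == "relative_clause" and c.anchor:
            clause = _surfaces(sentence, (c.span[0] + 1, c.span[1]))  # drop pronoun
            subj = _surfaces(sentence, c.anchor)
            emit(subj + clause, [c.kind])
        elif c.kind in ("conjunction_list", "conjunction_pair"):
            lo, hi = c.span
            for m in c.members:
                emit(all_tokens[:lo] + _surfaces(sentence, m) + all_tokens[hi:],
                     [c.kind])
        elif c.kind == "appositive" and c.anchor:
            lo, hi = c.span
            for m in c.members:
                emit(all_tokens[:lo] + _surfaces(sentence, m) + all_tokens[hi:],
                     [c.kind])
        elif c.kind == "parenthetical":
            lo, hi = c.span
            emit(all_tokens[:lo] + all_tokens[hi:], [c.kind])  # drop
            if c.anchor:
                inner = _surfaces(sentence, c.members[0])
                emit(
                    all_tokens[: c.anchor[0]] + inner + all_tokens[hi:],
                    [c.kind],
                )
    return out
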