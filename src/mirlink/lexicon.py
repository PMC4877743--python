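"""Trigger lexicons and morphological variant expansion.

The extraction rules are driven entirely by small, editable term lists (one
lowercase term per line, ``#`` comments, category given by filename).  Six
aspect/process categories feed entity detection; five relation-trigger files
feed semantic-relation categorization; doubt and connective lists feed the
informativeness scoring.  Verbal triggers are stored as lemmas and expanded
to all inflections (3rd person, past, gerund) at load time, and an explicit
verb<->nominalization pair table covers nominal predicates ("regulation",
"inhibition") and agentive nouns ("regulator").
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

__all__ = [
    "TriggerLexicon",
    "load_default_lexicon",
    "load_lexicon",
    "verb_forms",
    "noun_plural",
    "LexiconAuditError",
    "ASPECT_CATEGORIES",
    "RELATION_CATEGORIES",
]

DATA_DIR = Path(__file__).parent / "data" / "lexicons"

ASPECT_CATEGORIES = (
    "MIR_ASPECT_ABUNDANCE",
    "MIR_ASPECT_STATE",
    "DISEASE_OUTCOME",
    "DISEASE_DIAGNOSTIC",
    "DISEASE_TREATMENT",
    "PROCESS_DICTIONARY",
)

_ASPECT_FILES = {
    "MIR_ASPECT_ABUNDANCE": "mir_aspect_abundance.txt",
    "MIR_ASPECT_STATE": "mir_aspect_state.txt",
    "DISEASE_OUTCOME": "disease_outcome.txt",
    "DISEASE_DIAGNOSTIC": "disease_diagnostic.txt",
    "DISEASE_TREATMENT": "disease_treatment.txt",
    "PROCESS_DICTIONARY": "processes.txt",
}

RELATION_CATEGORIES = (
    "involvement",
    "regulation",
    "association",
    "is_a",
    "found_in",
)

_RELATION_FILES = {
    "involvement": "rel_involvement.txt",
    "regulation": "rel_regulation.txt",
    "association": "rel_association.txt",
    "is_a": "rel_is_a.txt",
    "found_in_general": "rel_found_in_general.txt",
    "found_in_aspect": "rel_found_in_aspect.txt",
}

# miR aspect implied by a found-in aspect-class predicate ("overexpressed in").
FOUND_IN_IMPLIED_ASPECT = {
    "overexpress": ("expression", "high"),
    "express": ("expression", "high"),  # "highly expressed in"
    "upregulate": ("expression", "high"),
    "up-regulate": ("expression", "high"),
    "downregulate": ("expression", "low"),
    "down-regulate": ("expression", "low"),
    "underexpress": ("expression", "low"),
    "mutate": ("mutation", None),
}

_IRREGULAR_VERBS = {
    "be": {"be", "is", "are", "was", "were", "been", "being", "am"},
    "have": {"have", "has", "had", "having"},
    "do": {"do", "does", "did", "done", "doing"},
    "find": {"find", "finds", "found", "finding"},
    "know": {"know", "knows", "knew", "known", "knowing"},
    "show": {"show", "shows", "showed", "shown", "showing"},
}

_VOWELS = "aeiou"


def verb_forms(lemma: str) -> set[str]:
    """All inflected forms of a (possibly hyphenated) verb lemma.

    Regular morphology only, with e-drop, y->ies and single consonant doubling
    for short stems; irregular verbs come from a small fixed table.  The
    expansion always contains the lemma itself.
    """
    lemma = lemma.lower()
    if lemma in _IRREGULAR_VERBS:
        return set(_IRREGULAR_VERBS[lemma])
    prefix = ""
    stem = lemma
    if "-" in lemma:  # up-regulate -> inflect the final element
        prefix, stem = lemma.rsplit("-", 1)
        prefix += "-"
    forms = {stem}
    if stem.endswith(("s", "sh", "ch", "x", "z")):
        forms.add(stem + "es")
    elif stem.endswith("y") and len(stem) > 1 and stem[-2] not in _VOWELS:
        forms.add(stem[:-1] + "ies")
    else:
        forms.add(stem + "s")
    if stem.endswith("e"):
        forms.add(stem + "d")
        forms.add(stem[:-1] + "ing")
    elif stem.endswith("y") and stem[-2:] not in ("ay", "ey", "oy"):
        forms.add(stem[:-1] + "ied")
        forms.add(stem + "ing")
    else:
        # No final-consonant doubling: the biomedical trigger vocabulary
        # (target->targeted, develop->developed) never doubles.
        forms.add(stem + "ed")
        forms.add(stem + "ing")
    return {prefix + f for f in forms}


def noun_plural(term: str) -> set[str]:
    """A noun trigger together with its plural form(s)."""
    term = term.lower()
    out = {term}
    head = term.split()[-1]
    if head.endswith(("s", "sh", "ch", "x", "z")):
        out.add(term + "es" if " " not in term else term)
        out.add(re.sub(rf"{re.escape(head)}$", head + "es", term))
    elif head.endswith("y") and len(head) > 1 and head[-2] not in _VOWELS:
        out.add(re.sub(rf"{re.escape(head)}$", head[:-1] + "ies", term))
    elif head.endswith("is"):
        pass  # metastasis-like Greek nouns: leave singular only
    else:
        out.add(term + "s")
    return out


class LexiconAuditError(RuntimeError):
    """Raised at load time when relation trigger sets are not disjoint."""


@dataclass
class TriggerLexicon:
    """All term lists and derived lookup tables used by the pipeline.

    ``entries`` maps the six aspect/process categories to expanded term sets.
    ``relation_triggers`` maps ``(lemma, preposition-or-None)`` keys to a
    relation category (``found_in`` keys carry a ``found_in_class`` entry in
    :attr:`found_in_class`).  ``verb_lemma`` maps every known inflected verb
    form back to its lemma; ``nominal_lemma`` maps nominalizations and
    agentive nouns to the underlying verb lemma.
    """

    entries: dict[str, set[str]] = field(default_factory=dict)
    relation_triggers: dict[tuple[str, str | None], str] = field(default_factory=dict)
    found_in_class: dict[tuple[str, str | None], str] = field(default_factory=dict)
    multiword_predicates: list[tuple[tuple[str, ...], str | None, str]] = field(
        default_factory=list
    )
    adjective_predicates: dict[tuple[str, str], str] = field(default_factory=dict)
    role_nouns: set[str] = field(default_factory=set)
    doubt: set[str] = field(default_factory=set)
    connectives: set[str] = field(default_factory=set)
    diseases: list[str] = field(default_factory=list)
    genes: set[str] = field(default_factory=set)
    verb_lemma: dict[str, str] = field(default_factory=dict)
    nominal_lemma: dict[str, str] = field(default_factory=dict)
    verb_nominals: dict[str, set[str]] = field(default_factory=dict)

    # -- lookup helpers ----------------------------------------------------

    def aspect_category(self, head: str, premod: str | None = None) -> str | None:
        """Category of an aspect trigger head noun, or None.

        Singular/plural folding is applied; ``premod`` allows matching of
        two-word triggers such as "overall survival" or "clinical outcome".
        """
        head = head.lower()
        candidates = [head]
        if premod:
            candidates.insert(0, f"{premod.lower()} {head}")
        for cand in candidates:
            for cat in ASPECT_CATEGORIES[:-1]:  # processes handled separately
                if cand in self.entries[cat]:
                    return cat
        return None

    def is_process(self, head: str, premod: str | None = None) -> bool:
        head = head.lower()
        if premod and f"{premod.lower()} {head}" in self.entries["PROCESS_DICTIONARY"]:
            return True
        return head in self.entries["PROCESS_DICTIONARY"]

    def process_by_suffix(self, head: str) -> bool:
        """eGIFT-style morphological process test (-sion/-tion/-sis/-or/-er/-ment)."""
        head = head.lower()
        return len(head) > 4 and head.endswith(
            ("sion", "tion", "sis", "or", "er", "ment", "sions", "tions", "ments")
        )

    def lemma_of(self, word: str) -> str:
        """Lemma of a verb form or nominalization (identity if unknown)."""
        word = word.lower()
        if word in self.verb_lemma:
            return self.verb_lemma[word]
        if word in self.nominal_lemma:
            return self.nominal_lemma[word]
        return word

    def relation_category(self, lemma: str, prep: str | None = None) -> str | None:
        """Relation category for a predicate lemma (+ optional preposition).

        The (lemma, prep) key is tried first, then the bare lemma, so
        "increase" alone is regulation while ("increase", "in") is found_in.
        """
        cat = self.relation_triggers.get((lemma, prep))
        if cat is None and prep is not None:
            cat = self.relation_triggers.get((lemma, None))
        return "found_in" if cat in ("found_in_general", "found_in_aspect") else cat

    def found_in_kind(self, lemma: str, prep: str | None = None) -> str | None:
        cat = self.relation_triggers.get((lemma, prep))
        return {"found_in_general": "general", "found_in_aspect": "aspect"}.get(cat)

    def is_role_noun(self, head: str, premod: str | None = None) -> bool:
        head = head.lower()
        if premod and f"{premod.lower()} {head}" in self.role_nouns:
            return True
        return head in self.role_nouns


def _read_terms(path: Path) -> list[str]:
    terms = []
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.split("#", 1)[0].strip().lower()
        if line:
            terms.append(line)
    return terms


def _expand_nouns(terms: list[str]) -> set[str]:
    out: set[str] = set()
    for t in terms:
        out |= noun_plural(t)
    return out


def _audit(lex: TriggerLexicon) -> None:
    """Startup audit: every aspect category non-empty, disease/gene lists present.

    (Relation-trigger disjointness is enforced at insertion time; this is the
    final structural check before the lexicon is released to the pipeline.)
    """
    for cat in ASPECT_CATEGORIES:
        if not lex.entries.get(cat):
            raise LexiconAuditError(f"empty lexicon category {cat}")
    if not lex.diseases or not lex.genes:
        raise LexiconAuditError("bundled disease/gene lexicons must be non-empty")


def load_lexicon(directory: str | Path) -> TriggerLexicon:
    """Load a lexicon directory (see data/lexicons for the shipped layout)."""
    directory = Path(directory)
    lex = TriggerLexicon()

    for cat, fname in _ASPECT_FILES.items():
        lex.entries[cat] = _expand_nouns(_read_terms(directory / fname))
        if not lex.entries[cat]:
            raise LexiconAuditError(f"empty lexicon category {cat}")

    # verb <-> nominalization pairs
    for line in _read_terms(directory / "nominalizations.txt"):
        verb, _, nominals = line.partition(":")
        verb = verb.strip()
        noms = {n.strip() for n in nominals.split(",") if n.strip()}
        lex.verb_nominals[verb] = noms
        for nom in noms:
            for form in noun_plural(nom):
                lex.nominal_lemma.setdefault(form, verb)

    def register_verb(lemma: str) -> None:
        for form in verb_forms(lemma):
            lex.verb_lemma.setdefault(form, lemma)

    adjectives = {"necessary", "sufficient", "crucial", "important", "essential",
                  "dependent"}
    preps = {"in", "for", "with", "to", "on", "as", "by"}

    def add_trigger(key: tuple[str, str | None], cat: str) -> None:
        prior = lex.relation_triggers.get(key)
        if prior is not None and prior != cat:
            raise LexiconAuditError(
                f"relation trigger {key!r} claimed by both {prior} and {cat}"
            )
        lex.relation_triggers[key] = cat
    for cat, fname in _RELATION_FILES.items():
        for term in _read_terms(directory / fname):
            words = term.split()
            if term == "play a role in":
                lex.multiword_predicates.append((("play", "role"), "in", cat))
                register_verb("play")
            elif len(words) == 2 and words[1] in preps:
                if words[0] in adjectives:
                    # adjectival predicate: "is crucial for"
                    lex.adjective_predicates[(words[0], words[1])] = cat
                else:
                    register_verb(words[0])
                    add_trigger((words[0], words[1]), cat)
            elif len(words) == 1:
                register_verb(term)
                add_trigger((term, None), cat)
            elif len(words) == 3 and words[2] in preps:
                # adverb-qualified trigger: "highly express in"
                register_verb(words[1])
                add_trigger((words[1], words[2]), cat)
            else:
                raise LexiconAuditError(f"unparseable relation trigger {term!r}")

    lex.role_nouns = _expand_nouns(_read_terms(directory / "role_nouns.txt"))
    for term in _read_terms(directory / "doubt.txt"):
        lex.doubt |= verb_forms(term) if term not in ("might", "could") else {term}
    for term in _read_terms(directory / "connectives.txt"):
        lex.connectives |= verb_forms(term)
        lex.connectives |= lex.verb_nominals.get(term, set())
        register_verb(term)

    lex.diseases = sorted(_read_terms(directory / "diseases.txt"), key=len, reverse=True)
    lex.genes = set(_read_terms(directory / "genes.txt"))

    # auxiliary / support verbs the chunker must know
    for aux in ("be", "have", "do", "know", "show", "find", "use", "profile",
                "identify", "observe", "confirm", "consider", "analyze", "express",
                "play", "act", "function", "serve", "suggest", "propose"):
        register_verb(aux)

    _audit(lex)
    return lex


@lru_cache(maxsize=4)
def _cached_load(directory: str) -> TriggerLexicon:
    return load_lexicon(directory)


def load_default_lexicon(directory: str | Path | None = None) -> TriggerLexicon:
    """Load (and cache) the bundled lexicon, or one from ``directory``."""
    return _cached_load(str(directory or DATA_DIR))
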