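import pytest

from mirlink.corpus_io import MentionType
from mirlink.syndep import (
    extract_agent_theme,
    extract_noun_mod,
    extract_null_argument,
)


def _deps(make_sentence, lexicon, text):
    sent = make_sentence(text)
    deps = extract_agent_theme(sent, lexicon)
    deps += extract_null_argument(sent, deps, lexicon)
    return sent, deps


def _tuples(deps):
    out = set()
    for d in deps:
        if d.agent is None or d.theme is None:
            continue
        out.add((
            d.agent.head_token.surface.lower(),
            d.predicate.lemma,
            d.theme.head_token.surface.lower(),
        ))
    return out


def test_passive_voice_normalized(make_sentence, lexicon):
    _, deps = _deps(make_sentence, lexicon, "apoptosis is regulated by miR-9.")
    assert ("mir-9", "regulate", "apoptosis") in _tuples(deps)
    (d,) = [d for d in deps if d.predicate.lemma == "regulate"]
    assert d.predicate.voice == "passive"


def test_nominalized_predicate(make_sentence, lexicon):
    _, deps = _deps(make_sentence, lexicon,
                    "miR-9 regulation of cell proliferation.")
    (d,) = [d for d in deps if d.predicate.is_nominalized]
    assert d.agent.head_token.surface == "miR-9"
    assert d.predicate.lemma == "regulate"
    assert d.theme.head_token.surface == "proliferation"


def test_multiword_predicate(make_sentence, lexicon):
    _, deps = _deps(make_sentence, lexicon,
                    "miR-146a may play a role in cell proliferation.")
    (d,) = [d for d in deps if d.predicate.multiword_trigger]
    assert d.predicate.multiword_trigger == "play a role in"
    assert d.theme.head_token.surface == "proliferation"


@pytest.mark.parametrize(
    "text,agent,lemma,theme,connective",
    [
        ("miR-126 was able to inhibit laryngeal squamous cell carcinoma "
         "partly by suppressing Camsap1 expression.",
         "miR-126", "suppress", "expression", "by+Ving"),
        ("Tumor suppressive miR-1 induces apoptosis through direct "
         "inhibition of SRSF9 in bladder cancer.",
         "miR-1", "inhibit", "SRSF9", "through+NOM"),
    ],
)
def test_null_argument_inheritance(make_sentence, lexicon, text, agent, lemma,
                                   theme, connective):
    _, deps = _deps(make_sentence, lexicon, text)
    hits = [d for d in deps if d.null_argument]
    assert any(
        d.agent.head_token.surface == agent
        and d.predicate.lemma == lemma
        and d.theme.head_token.surface == theme
        and d.connective == connective
        for d in hits
    )


def test_null_argument_requires_prior_agent(make_sentence, lexicon):
    # "by V-ing" with no governing clause agent -> nothing inherited
    sent = make_sentence("by suppressing Camsap1 expression.")
    deps = extract_agent_theme(sent, lexicon)
    assert extract_null_argument(sent, deps, lexicon) == []


def test_active_passive_equivalence_20_pairs(make_sentence, lexicon):
    """Voice property: A V+s B == B is V+ed by A (active-form oracle)."""
    verbs = ["regulates", "suppresses", "inhibits", "promotes", "modulates",
             "induces", "represses", "enhances", "blocks", "mediates"]
    ppl = ["regulated", "suppressed", "inhibited", "promoted", "modulated",
           "induced", "repressed", "enhanced", "blocked", "mediated"]
    fillers = [("mir-21", "apoptosis"), ("mir-9", "cell proliferation")]
    n = 0
    for v, p in zip(verbs, ppl):
        for a, b in fillers:
            _, active = _deps(make_sentence, lexicon, f"{a} {v} {b}.")
            _, passive = _deps(make_sentence, lexicon, f"{b} is {p} by {a}.")
            assert _tuples(active) == _tuples(passive) != set()
            n += 1
    assert n == 20


def test_every_dep_argument_bears_a_mention(make_sentence, lexicon):
    texts = [
        "MicroRNA-9 promotes tumor metastasis via repressing E-cadherin in "
        "esophageal squamous cell carcinoma.",
        "High miR-199a expression is associated with liver fibrosis.",
    ]
    for text in texts:
        _, deps = _deps(make_sentence, lexicon, text)
        for d in deps:
            args = [a for a in (d.agent, d.theme) if a is not None]
            assert args
            assert any(a.mentions() for a in args)


def test_no_relative_pronoun_arguments(make_sentence, lexicon):
    sent, deps = _deps(
        make_sentence, lexicon,
        "breast cancer metastasis suppressor 1 up-regulates mir-146, which "
        "suppresses breast cancer metastasis.",
    )
    for d in deps:
        for arg in (d.agent, d.theme):
            if arg is not None:
                assert "which" not in arg.surface.lower().split()


def test_negation_flagged(make_sentence, lexicon):
    _, deps = _deps(make_sentence, lexicon, "mir-9 does not regulate apoptosis.")
    (d,) = [d for d in deps if d.predicate.lemma == "regulate"]
    assert d.predicate.negated


@pytest.mark.parametrize(
    "text,head,modifier,form",
    [
        ("mir-21 overexpression is common.", "overexpression", "mir-21",
         "premodifier"),
        ("metastasis of gastric cancer was seen.", "metastasis",
         "gastric cancer", "prepositional_of"),
    ],
)
def test_noun_modification_forms(make_sentence, lexicon, text, head, modifier,
                                 form):
    nms = extract_noun_mod(make_sentence(text), lexicon)
    assert any(
        nm.head_surface == head
        and nm.modifier.surface.lower() == modifier
        and nm.form == form
        for nm in nms
    )


def test_bare_disease_np_has_no_noun_mod(make_sentence, lexicon):
    assert extract_noun_mod(make_sentence("gastric cancer."), lexicon) == []
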