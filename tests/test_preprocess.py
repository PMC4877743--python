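import pytest
from hypothesis import given, settings, strategies as st

from mirlink.corpus_io import DocumentRecord, Mention, MentionType
from mirlink.preprocess import (
    ChunkedSentence,
    VERB_TAGS,
    attach_mentions,
    chunk,
    filter_sentences,
    split_sentences,
    tokenize,
)


# --- sentence splitting ------------------------------------------------------


def test_title_is_sentence_zero_and_counting():
    rec = DocumentRecord(pmid="1", title="T.", abstract="mir-9 acts. It works.")
    sents = split_sentences(rec)
    assert [s.text for s in sents] == ["T.", "mir-9 acts.", "It works."]
    assert [s.index for s in sents] == [0, 1, 2]


def test_decimal_protected():
    rec = DocumentRecord(pmid="1", title="T.", abstract="levels (p < 0.05) fell.")
    assert [s.text for s in split_sentences(rec)][1:] == ["levels (p < 0.05) fell."]


def test_abbreviation_protected():
    rec = DocumentRecord(
        pmid="1", title="T.",
        abstract="As shown by Smith et al. the levels fell. Expression rose.",
    )
    texts = [s.text for s in split_sentences(rec)]
    assert texts[1].startswith("As shown by Smith et al. the levels")
    assert len(texts) == 3


def test_split_between_cells_and_expression():
    # hand segmentation: boundary after "cells." and before "Expression"
    rec = DocumentRecord(
        pmid="1", title="T.",
        abstract="mir-9 regulates proliferation of U87 cells. Expression of "
                 "mir-9 rose.",
    )
    texts = [s.text for s in split_sentences(rec)]
    assert texts[1].endswith("U87 cells.")
    assert texts[2].startswith("Expression of mir-9")


def test_sentence_spans_index_into_document():
    rec = DocumentRecord(pmid="1", title="A title.", abstract="One. Two here.")
    for s in split_sentences(rec):
        assert rec.text[s.start : s.end] == s.text


# --- filtering ---------------------------------------------------------------


def test_filter_keeps_mir_or_disease():
    rec = DocumentRecord(
        pmid="1", title="T.",
        abstract="miR-21 is overexpressed. PTEN is a gene. glioma grows.",
    )
    sents = split_sentences(rec)
    mentions = [
        Mention(rec.text.find("miR-21"), rec.text.find("miR-21") + 6, "miR-21",
                MentionType.MIR),
        Mention(rec.text.find("PTEN"), rec.text.find("PTEN") + 4, "PTEN",
                MentionType.GENE),
        Mention(rec.text.find("glioma"), rec.text.find("glioma") + 6, "glioma",
                MentionType.DISEASE),
    ]
    attach_mentions(sents, mentions)
    kept = filter_sentences(sents)
    assert [s.text for s in kept] == ["miR-21 is overexpressed.", "glioma grows."]


# --- chunking ----------------------------------------------------------------


def _chunk_surfaces(sent):
    return [
        (c.ctype, " ".join(t.surface for t in sent.tokens[c.start : c.end]))
        for c in sent.chunks
    ]


def test_two_consecutive_verb_groups(make_sentence):
    sent = make_sentence("mir-9 is known to directly regulate cell proliferation.")
    vgs = [s for t, s in _chunk_surfaces(sent) if t == "VG"]
    assert vgs == ["is known", "to directly regulate"]


def test_pp_attachment_right_association(make_sentence):
    sent = make_sentence("expression of mir-9 regulates proliferation of U87 cells.")
    pps = [c for c in sent.chunks if c.ctype == "PP"]
    assert all(c.attached_to is not None for c in pps)
    surf = _chunk_surfaces(sent)
    assert ("NP", "expression") in surf and ("NP", "proliferation") in surf


def test_single_token_sentence_is_np(make_sentence):
    sent = make_sentence("Apoptosis.")
    assert _chunk_surfaces(sent)[0] == ("NP", "Apoptosis")


@pytest.mark.parametrize(
    "text",
    [
        "Downregulation of mir-26a is associated with tumor metastasis in osteosarcoma.",
        "miR-126 was able to inhibit laryngeal squamous cell carcinoma partly by suppressing Camsap1 expression.",
        "Treatment of gastric cells with dihydroartemisinin (DHA) increased miR-15b and miR-16 expression, caused a downregulation of Bcl-2, resulting in apoptosis of gastric cancer cells.",
        "Plasma miR-601 and miR-760 can potentially serve as promising non-invasive biomarkers for the early detection of colorectal cancer.",
        "Apoptosis.",
    ],
)
def test_chunks_tile_tokens(make_sentence, text):
    sent = make_sentence(text)
    covered = [i for c in sent.chunks for i in range(c.start, c.end)]
    assert covered == list(range(len(sent.tokens)))  # no gaps, no overlaps
    for c in sent.chunks:
        assert c.start <= c.head < c.end  # head inside its chunk


def test_chunking_idempotent(make_sentence, tagger):
    sent = make_sentence(
        "High miR-199a expression is associated with liver fibrosis."
    )
    before = [(c.ctype, c.start, c.end, c.head) for c in sent.chunks]
    chunk(sent, tagger)
    after = [(c.ctype, c.start, c.end, c.head) for c in sent.chunks]
    assert before == after


def test_vg_head_is_last_verb(make_sentence):
    sent = make_sentence(
        "miR-23b is epigenetically down-regulated and restoration of miR-23b "
        "can effectively suppress cell growth in glioma stem cells."
    )
    for c in sent.chunks:
        if c.ctype == "VG":
            verb_idx = [
                i for i in range(c.start, c.end)
                if sent.tokens[i].pos in VERB_TAGS
            ]
            assert c.head == verb_idx[-1]


def test_mir_mentions_stay_single_tokens(make_sentence):
    sent = make_sentence("hsa-miR-21 and miR-17-92 act in breast cancer.")
    surfaces = [t.surface for t in sent.tokens]
    assert "hsa-miR-21" in surfaces and "miR-17-92" in surfaces


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.text(alphabet=st.characters(codec="ascii", exclude_categories=["Cc"]),
               min_size=0, max_size=60))
def test_tokenize_offsets_consistent(text):
    for surface, start, end in tokenize(text):
        assert text[start:end] == surface
        assert surface.strip() == surface and surface
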