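import re

import pytest

from mirlink.corpus_io import DocumentRecord, Mention, MentionType
from mirlink.entities import (
    detect_candidate_aspects,
    detect_disease_mentions,
    detect_linking_candidates,
    detect_mir_mentions,
    normalize_mir,
    resolve_overlaps,
)
from mirlink.lexicon import LexiconAuditError, load_lexicon


# --- miR mention regex -------------------------------------------------------


def _mir_grammar_strings():
    """Enumerated accept/reject set (the brute-force oracle: labels follow
    from the naming convention the matcher implements)."""
    positives = []
    for prefix in ("miR", "MIR", "mir", "miRNA", "microRNA", "MicroRNA"):
        for joint in ("-", ""):
            for num in ("9", "21", "155"):
                for suffix in ("", "a", "-1", "-3p", "-5p", "a-3p"):
                    positives.append(f"{prefix}{joint}{num}{suffix}")
    positives += ["hsa-miR-21", "mmu-mir-1a", "let-7i", "let-7", "miR 144",
                  "miR-17-92", "miR-221/222", "microRNA 1"]
    negatives = ["mirage", "admiral", "smirk", "casimir", "miRNA", "miR",
                 "mir-", "letter", "let 7", "miRNAs", "vladimir-21",
                 "microRNAx9", "amiR-21"]
    return positives, negatives


def test_mir_regex_agreement_with_enumeration_oracle():
    positives, negatives = _mir_grammar_strings()
    assert len(positives) + len(negatives) >= 200
    for s in positives:
        ms = detect_mir_mentions(f"We studied {s} here.")
        assert [m.surface for m in ms] == [s], f"should match whole: {s!r}"
    for s in negatives:
        ms = detect_mir_mentions(f"We studied {s} here.")
        full = [m for m in ms if m.surface == s]
        assert not full, f"should not match: {s!r}"


@pytest.mark.parametrize(
    "text,expected",
    [
        ("MicroRNA-9 promotes tumor metastasis", ["MicroRNA-9"]),
        ("let-7i is associated with colorectal cancer metastasis", ["let-7i"]),
        ("mirage admiration", []),
        ("miR-21, miR-210, miR-155, and miR-196a",
         ["miR-21", "miR-210", "miR-155", "miR-196a"]),
    ],
)
def test_mir_examples(text, expected):
    assert [m.surface for m in detect_mir_mentions(text)] == expected


@pytest.mark.parametrize(
    "surface,key",
    [
        ("MicroRNA-9", "mir-9"),
        ("miRNA-143", "mir-143"),
        ("hsa-miR-21", "mir-21"),
        ("let-7i", "let-7i"),
        ("MIR155", "mir-155"),
    ],
)
def test_mir_normalization(surface, key):
    assert normalize_mir(surface) == key


# --- disease lookup ----------------------------------------------------------


def _brute_force_disease_scan(text, terms):
    """All-substring oracle: at each boundary position the longest matching
    lexicon term wins."""
    low = text.lower()
    hits = []
    i = 0
    while i < len(low):
        if i > 0 and low[i - 1].isalnum():
            i += 1
            continue
        best = None
        for t in terms:
            j = i + len(t)
            if low[i:j] == t and (j == len(low) or not low[j].isalnum()):
                if best is None or j > best:
                    best = j
        if best is not None:
            hits.append((i, best))
            i = best
        else:
            i += 1
    return hits


def test_disease_longest_match_equals_bruteforce(lexicon):
    text = ("Patients with esophageal squamous cell carcinoma (ESCC) and "
            "breast cancer but not breast carcinoma controls were enrolled "
            "for gastric cancer screening.")
    rec = DocumentRecord(pmid="1", title=text, abstract="")
    got = [(m.start, m.end) for m in detect_disease_mentions(rec, lexicon)]
    assert got == _brute_force_disease_scan(text, lexicon.diseases)
    surfaces = [text[a:b].lower() for a, b in got]
    assert "esophageal squamous cell carcinoma" in surfaces
    assert "escc" in surfaces  # abbreviation matched separately


def test_disease_sidecar_passthrough(lexicon):
    rec = DocumentRecord(pmid="1", title="osteosarcoma study", abstract="")
    side = Mention(0, 12, "osteosarcoma", MentionType.DISEASE, norm_id="MESH:X")
    rec.external_mentions.append(side)
    assert detect_disease_mentions(rec, lexicon) == [side]


def test_no_disease_returns_empty(lexicon):
    rec = DocumentRecord(pmid="1", title="mir-21 and apoptosis", abstract="")
    assert detect_disease_mentions(rec, lexicon) == []


def test_overlap_resolution_prefers_longest():
    ms = [
        Mention(0, 13, "breast cancer", MentionType.DISEASE),
        Mention(7, 13, "cancer", MentionType.DISEASE),
        Mention(0, 6, "mir-21", MentionType.MIR),
    ]
    kept = resolve_overlaps(ms)
    same = [m for m in kept if m.mtype is MentionType.DISEASE]
    assert [m.surface for m in same] == ["breast cancer"]
    for a in kept:
        for b in kept:
            if a is not b and a.mtype is b.mtype:
                assert a.end <= b.start or b.end <= a.start


# --- aspect and linking candidates -------------------------------------------


@pytest.mark.parametrize(
    "text,surface,subtype",
    [
        ("low miR-335 levels were observed", "levels", "abundance"),
        ("relapse-free survival was shorter", "survival", "outcome"),
        ("a promising biomarker was proposed", "biomarker", "diagnostic"),
        ("a novel therapeutic target emerged", "therapeutic target", "treatment"),
        ("promoter hypermethylation was seen", "hypermethylation", "state"),
    ],
)
def test_candidate_aspects(make_sentence, lexicon, text, surface, subtype):
    cands = detect_candidate_aspects(make_sentence(text), lexicon)
    assert (surface, subtype) in {(m.surface, m.subtype) for m in cands}


def test_no_trigger_heads_no_candidates(make_sentence, lexicon):
    assert detect_candidate_aspects(make_sentence("mir-9 acts here."), lexicon) == []


def test_linking_candidates(make_sentence, lexicon):
    rec = DocumentRecord(pmid="1", title="x", abstract="")
    sent = make_sentence(
        "mir-320a down-regulation mediates bladder carcinoma invasion by "
        "targeting itgb3."
    )
    cands = detect_linking_candidates(sent, rec, lexicon)
    kinds = {(c.kind, c.mention.surface.lower()) for c in cands}
    assert ("gene", "itgb3") in kinds

    sent2 = make_sentence("miR-9 regulates cell proliferation.")
    cands2 = detect_linking_candidates(sent2, rec, lexicon)
    assert ("process", "proliferation") in {
        (c.kind, c.mention.surface.lower()) for c in cands2
    }


def test_aspect_heads_excluded_from_linking(make_sentence, lexicon):
    rec = DocumentRecord(pmid="1", title="x", abstract="")
    sent = make_sentence("overall survival of patients with mir-21 was long.")
    cands = detect_linking_candidates(sent, rec, lexicon)
    assert "survival" not in {c.mention.surface.lower() for c in cands}


def test_aspect_candidates_have_known_categories(make_sentence, lexicon):
    sent = make_sentence(
        "High miR-199a expression is a biomarker of overall survival and a "
        "therapeutic target after mutation."
    )
    for m in detect_candidate_aspects(sent, lexicon):
        assert m.subtype in ("abundance", "state", "outcome", "diagnostic",
                             "treatment")


# --- lexicon audit -----------------------------------------------------------


def test_relation_trigger_disjointness_audit(tmp_path, lexicon):
    import shutil
    from mirlink.lexicon import DATA_DIR

    dst = tmp_path / "lex"
    shutil.copytree(DATA_DIR, dst)
    with (dst / "rel_involvement.txt").open("a") as fh:
        fh.write("\nregulate\n")  # already claimed by regulation
    with pytest.raises(LexiconAuditError):
        load_lexicon(dst)
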