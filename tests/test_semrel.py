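import pytest

from mirlink.entities import DiseaseEntity, LinkingEntity, MiREntity
from mirlink.pipeline import process_text
from mirlink.semrel import relation_tuples


def _result(text, require_disease=True):
    res = process_text(text, require_disease=require_disease)
    assert res.sentences, f"no sentence survived for {text!r}"
    return res.sentences[0]


def _categories(sres):
    return {r.category for r in sres.relations if r.category != "state"}


@pytest.mark.parametrize(
    "text,category",
    [
        ("reduced circulating mir-150 levels are associated with poor "
         "survival in pulmonary arterial hypertension.", "association"),
        ("miR-155 was overexpressed in gallbladder cancer.", "found_in"),
        ("miR-21 may play a critical role in chronic myelogenous leukemia.",
         "involvement"),
    ],
)
def test_categorization(text, category):
    assert category in _categories(_result(text))


def test_is_a_via_conjunction_simplification():
    sres = _result(
        "Plasma miR-601 and miR-760 can potentially serve as promising "
        "non-invasive biomarkers for the early detection of colorectal cancer."
    )
    assert sres.tuples == {
        ("mir-601", "is_a", "colorectal cancer"),
        ("mir-760", "is_a", "colorectal cancer"),
    }


def test_non_trigger_predicate_yields_nothing():
    sres = _result("mir-9 eats apoptosis in glioma.")
    assert sres.tuples == set()


def test_bare_copula_is_not_is_a():
    # unrestricted copulas would flood false positives
    sres = _result("miR-21 is important in glioma.")
    assert not any(r.category == "is_a" for r in sres.relations)


def test_compose_mir_and_disease_aspects():
    sres = _result(
        "Downregulation of mir-26a is associated with tumor metastasis in "
        "osteosarcoma."
    )
    (rel,) = [r for r in sres.relations if r.category == "association"]
    mir, disease = rel.agent_entity, rel.theme_entity
    assert isinstance(mir, MiREntity) and mir.key == "mir-26a"
    assert mir.aspect_surface == "downregulation"
    assert isinstance(disease, DiseaseEntity)
    assert disease.key == "osteosarcoma" and disease.aspect_kind == "outcome"


def test_compose_found_in_general_aspect():
    sres = _result("high level of mir-155 was found in gallbladder cancer.")
    (rel,) = [r for r in sres.relations if r.category == "found_in"]
    mir = rel.agent_entity
    assert mir.aspect_surface == "high level" and mir.aspect_kind == "expression"


def test_compose_found_in_inferred_aspect():
    sres = _result("miR-155 was overexpressed in gallbladder cancer.")
    (rel,) = [r for r in sres.relations if r.category == "found_in"]
    assert rel.agent_entity.aspect_kind == "expression"
    assert rel.agent_entity.qualifier == "high"


def test_bare_entities_without_state_relations():
    sres = _result("mir-9 inhibits glioma.")
    (rel,) = [r for r in sres.relations if r.category == "regulation"]
    assert rel.agent_entity.aspect is None
    assert rel.theme_entity.aspect is None


# --- multiple predicate triggers ----------------------------------------------


def test_multiple_predicates_resolve_to_specific():
    sres = _result("miR-9 is involved in the regulation of apoptosis.",
                   require_disease=False)
    assert sres.tuples == {("mir-9", "regulation", "apoptosis")}
    assert not any(r.category == "involvement" for r in sres.relations)


def test_single_trigger_chain_unchanged():
    sres = _result("miR-9 is involved in apoptosis of glioma cells.")
    assert sres.tuples == {("mir-9", "involvement", "apoptosis")}


@pytest.mark.parametrize("general", ["is involved in", "is implicated in",
                                     "functions as", "serves as"])
@pytest.mark.parametrize("nominal", ["regulation", "regulator", "inhibition",
                                     "suppression", "induction"])
def test_specificity_over_trigger_pairs(general, nominal, lexicon):
    """Oracle = the specificity table: for every (general, regulation-nominal)
    trigger pair the resolved relation is the regulation one."""
    det = "a" if nominal.endswith("or") else "the"
    sres = _result(f"miR-9 {general} {det} {nominal} of apoptosis.",
                   require_disease=False)
    assert sres.tuples == {("mir-9", "regulation", "apoptosis")}
    # oracle: lexicon confirms the inner trigger is regulation-specific
    assert lexicon.relation_category(lexicon.nominal_lemma[nominal]) == "regulation"


def test_resolution_never_increases_or_drops_regulation():
    text = ("mir-9 promotes apoptosis and is involved in the regulation of "
            "cell growth in glioma.")
    sres = _result(text)
    cats = [r.category for r in sres.relations if r.category != "state"]
    assert cats.count("regulation") == len(cats)  # all resolved to regulation
    assert ("mir-9", "regulation", "apoptosis") in sres.tuples


# --- triplets ------------------------------------------------------------------


def test_triplet_with_linking_entity_and_chain():
    sres = _result(
        "MicroRNA-9 promotes tumor metastasis via repressing E-cadherin in "
        "esophageal squamous cell carcinoma."
    )
    (t,) = sres.triplets
    assert t.mir.key == "mir-9"
    assert t.disease.key == "esophageal squamous cell carcinoma"
    assert t.disease.aspect_kind == "outcome"
    assert [l.key for l in t.linking] == ["e-cadherin"]
    assert {r.trigger for r in t.relations} == {"promote", "repress"}


def test_triplet_with_two_linking_entities():
    sres = _result(
        "restoration of mirna-143 (mir-143) regulates cox-2 and inhibits "
        "cell proliferation of pancreatic cancer cells."
    )
    (t,) = sres.triplets
    assert sorted(l.key for l in t.linking) == ["cell proliferation", "cox-2"]
    assert {l.kind for l in t.linking} == {"gene", "process"}


def test_no_disease_no_triplet():
    res = process_text("miR-146a may play a role in cell proliferation.",
                       require_disease=False)
    assert res.sentences[0].tuples  # relation exists
    assert res.sentences[0].triplets == []  # but no association triplet


def test_evidence_sentence_contains_all_triplet_mentions():
    for text in [
        "MicroRNA-9 promotes tumor metastasis via repressing E-cadherin in "
        "esophageal squamous cell carcinoma.",
        "Tumor suppressive miR-1 induces apoptosis through direct inhibition "
        "of SRSF9 in bladder cancer.",
    ]:
        for t in _result(text).triplets:
            ev = t.evidence_sentence.lower()
            assert t.mir.mir.surface.lower() in ev
            if t.disease and t.disease.disease:
                assert t.disease.disease.surface.lower() in ev
            for l in t.linking:
                assert l.mention.surface.lower() in ev


def test_duplicates_from_original_and_simplified_merged():
    sres = _result(
        "Plasma miR-601 and miR-760 can potentially serve as promising "
        "non-invasive biomarkers for the early detection of colorectal cancer."
    )
    keys = [r.key() for r in sres.relations if r.category != "state"]
    assert len(keys) == len(set(keys))
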