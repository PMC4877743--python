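"""Gold evidence sentences and synthetic corpus generation.

``gold_corpus`` packages the worked-example sentences the extraction
rules were designed around -- each with its expected (miR, category, theme)
tuples, linking entities and (where defined) informativeness score -- so the
whole pipeline is testable end-to-end without any download.

``generate`` builds synthetic abstracts from slot templates with derivable
gold annotations: every template knows the tuples and score its instantiation
must produce, including active/passive pairs, null-argument chains,
conjunctions, hedged variants and deliberate *negative* fixtures (anaphora,
temporal clauses) on which the extractor must stay silent -- these mirror the
documented failure modes of purely local patterns.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

from .lexicon import TriggerLexicon, load_default_lexicon

__all__ = [
    "GoldSentence",
    "SentenceTemplate",
    "gold_corpus",
    "default_templates",
    "negative_templates",
    "default_fillers",
    "generate",
    "write_gold_jsonl",
]


@dataclass
class GoldSentence:
    """One evidence sentence with its expected extraction."""

    pmid: str
    text: str
    gold_relations: list[tuple[str, str, str]]  # (mir key, category, theme key)
    gold_linking: list[str] = field(default_factory=list)
    gold_score: int | None = None
    gold_surfaces: list[str] = field(default_factory=list)  # must occur in text
    requires_disease: bool = True  # bare dependency examples have no disease
    expect_simplified: list[str] = field(default_factory=list)  # substrings
    negative: bool = False  # gold = no extraction at all
    note: str = ""


def gold_corpus() -> list[GoldSentence]:
    """The packaged worked-example corpus (21 sentences)."""
    g = GoldSentence
    return [
        g("G01",
          "Downregulation of mir-26a is associated with tumor metastasis in "
          "osteosarcoma.",
          [("mir-26a", "association", "osteosarcoma")],
          gold_surfaces=["mir-26a", "Downregulation", "tumor metastasis",
                         "osteosarcoma"],
          note="miR aspect + disease aspect composition"),
        g("G02",
          "MicroRNA-9 promotes tumor metastasis via repressing E-cadherin in "
          "esophageal squamous cell carcinoma.",
          [("mir-9", "regulation", "esophageal squamous cell carcinoma"),
           ("mir-9", "regulation", "e-cadherin")],
          gold_linking=["e-cadherin"],
          gold_surfaces=["MicroRNA-9", "E-cadherin",
                         "esophageal squamous cell carcinoma"],
          note="linking entity with implicit disease connection"),
        g("G03",
          "We have profiled four miRNAs, miR-21, miR-210, miR-155, and "
          "miR-196a, all implicated in the development of pancreatic cancer "
          "with either proven or predicted target genes involved in critical "
          "cancer-associated cellular pathways.",
          [("mir-21", "involvement", "pancreatic cancer"),
           ("mir-210", "involvement", "pancreatic cancer"),
           ("mir-155", "involvement", "pancreatic cancer"),
           ("mir-196a", "involvement", "pancreatic cancer")],
          gold_surfaces=["miR-21", "miR-210", "miR-155", "miR-196a",
                         "pancreatic cancer"],
          expect_simplified=[
              "miR-21 is implicated in the development of pancreatic cancer"],
          note="appositive list + reduced relative clauses"),
        g("G04",
          "breast cancer metastasis suppressor 1 up-regulates mir-146, which "
          "suppresses breast cancer metastasis.",
          [("mir-146", "regulation", "breast cancer")],
          gold_surfaces=["mir-146", "breast cancer metastasis"],
          expect_simplified=["mir-146 suppresses breast cancer metastasis"],
          note="relative clause"),
        g("G05",
          "apoptosis is regulated by miR-9.",
          [("mir-9", "regulation", "apoptosis")],
          gold_surfaces=["miR-9", "apoptosis"],
          requires_disease=False,
          note="passive voice normalization"),
        g("G06",
          "miR-9 regulation of cell proliferation.",
          [("mir-9", "regulation", "cell proliferation")],
          gold_surfaces=["miR-9", "cell proliferation"],
          requires_disease=False,
          note="nominalized predicate"),
        g("G07",
          "miR-146a may play a role in cell proliferation.",
          [("mir-146a", "involvement", "cell proliferation")],
          gold_surfaces=["miR-146a", "cell proliferation"],
          requires_disease=False,
          note="multi-word predicate"),
        g("G08",
          "miR-126 was able to inhibit laryngeal squamous cell carcinoma "
          "partly by suppressing Camsap1 expression.",
          [("mir-126", "regulation", "laryngeal squamous cell carcinoma"),
           ("mir-126", "regulation", "camsap1")],
          gold_linking=["camsap1"],
          gold_surfaces=["miR-126", "Camsap1",
                         "laryngeal squamous cell carcinoma"],
          note="null argument: by + gerund"),
        g("G09",
          "Tumor suppressive miR-1 induces apoptosis through direct "
          "inhibition of SRSF9 in bladder cancer.",
          [("mir-1", "regulation", "apoptosis"),
           ("mir-1", "regulation", "srsf9")],
          gold_linking=["apoptosis", "srsf9"],
          gold_surfaces=["miR-1", "SRSF9", "bladder cancer", "apoptosis"],
          note="null argument: through + nominalization"),
        g("G10",
          "reduced circulating mir-150 levels are associated with poor "
          "survival in pulmonary arterial hypertension.",
          [("mir-150", "association", "pulmonary arterial hypertension")],
          gold_surfaces=["mir-150", "poor survival",
                         "pulmonary arterial hypertension"],
          note="association with outcome aspect"),
        g("G11",
          "Plasma miR-601 and miR-760 can potentially serve as promising "
          "non-invasive biomarkers for the early detection of colorectal "
          "cancer.",
          [("mir-601", "is_a", "colorectal cancer"),
           ("mir-760", "is_a", "colorectal cancer")],
          gold_surfaces=["miR-601", "miR-760", "biomarkers",
                         "colorectal cancer"],
          note="is-a through conjunction simplification"),
        g("G12",
          "high level of mir-155 was found in gallbladder cancer.",
          [("mir-155", "found_in", "gallbladder cancer")],
          gold_surfaces=["mir-155", "high level", "gallbladder cancer"],
          note="found-in, general trigger class"),
        g("G13",
          "miR-155 was overexpressed in gallbladder cancer.",
          [("mir-155", "found_in", "gallbladder cancer")],
          gold_surfaces=["miR-155", "overexpressed", "gallbladder cancer"],
          note="found-in, aspect inferred from predicate"),
        g("G14",
          "restoration of mirna-143 (mir-143) regulates cox-2 and inhibits "
          "cell proliferation of pancreatic cancer cells.",
          [("mir-143", "regulation", "cox-2"),
           ("mir-143", "regulation", "cell proliferation")],
          gold_linking=["cox-2", "cell proliferation"],
          gold_surfaces=["mirna-143", "cox-2", "cell proliferation",
                         "pancreatic cancer"],
          note="two linking entities; parenthetical"),
        g("G15",
          "miR-9 is involved in the regulation of apoptosis.",
          [("mir-9", "regulation", "apoptosis")],
          gold_surfaces=["miR-9", "regulation", "apoptosis"],
          requires_disease=False,
          note="multiple predicate triggers resolved to the specific one"),
        g("G16",
          "miR-137 functions as a tumor suppressor by targeting CtBP1 to "
          "inhibit epithelial-mesenchymal transition and inducing apoptosis "
          "of melanoma cells.",
          [("mir-137", "is_a", "tumor suppressor"),
           ("mir-137", "regulation", "ctbp1"),
           ("mir-137", "regulation", "transition"),
           ("mir-137", "regulation", "apoptosis")],
          gold_linking=["ctbp1"],
          gold_score=3,
          gold_surfaces=["miR-137", "tumor suppressor", "CtBP1", "melanoma"],
          note="highly informative: null-argument explanation"),
        g("G17",
          "Treatment of gastric cells with dihydroartemisinin (DHA) "
          "increased miR-15b and miR-16 expression, caused a downregulation "
          "of Bcl-2, resulting in apoptosis of gastric cancer cells.",
          [("mir-15b", "regulation", "gastric cancer"),
           ("mir-16", "regulation", "gastric cancer")],
          gold_score=3,
          gold_surfaces=["miR-15b", "miR-16", "Bcl-2", "gastric cancer"],
          note="highly informative: event sequence"),
        g("G18",
          "miR-23b is epigenetically down-regulated and restoration of "
          "miR-23b can effectively suppress cell growth in glioma stem "
          "cells.",
          [("mir-23b", "regulation", "cell growth")],
          gold_score=2,
          gold_surfaces=["miR-23b", "cell growth", "glioma"],
          note="informative: regulation of a linking process"),
        g("G19",
          "High miR-199a expression is associated with liver fibrosis.",
          [("mir-199a", "association", "liver fibrosis")],
          gold_score=1,
          gold_surfaces=["miR-199a", "High", "liver fibrosis"],
          note="somewhat informative: altered expression"),
        g("G20",
          "miR-125b could be an important prognostic indicator for "
          "colorectal cancer patients.",
          [("mir-125b", "is_a", "colorectal cancer")],
          gold_score=1,
          gold_surfaces=["miR-125b", "indicator", "colorectal cancer"],
          note="somewhat informative: diagnostic aspect, hedged at the floor"),
        g("G21",
          "let-7i is associated with colorectal cancer metastasis.",
          [("let-7i", "association", "colorectal cancer")],
          gold_surfaces=["let-7i", "colorectal cancer metastasis"],
          note="let-family miR name"),
    ]


# --- synthetic templates -----------------------------------------------------


@dataclass
class SentenceTemplate:
    """A slot pattern plus the gold its instantiation must produce.

    ``expected(slots)`` returns (tuples, score, negative): the relation
    tuples and informativeness score derivable from the filled slots.
    """

    name: str
    pattern: str
    slots: tuple[str, ...]
    score: int | None
    negative: bool = False
    easy: bool = True  # counted in the 100%-recall suite

    def expected(self, slots: dict[str, str]) -> list[tuple[str, str, str]]:
        if self.negative:
            return []
        return [
            (slots[a].lower(), cat, slots[b].lower())
            for a, cat, b in _TEMPLATE_GOLD[self.name]
        ]


_TEMPLATE_GOLD = {
    "active_regulation": [("MIR", "regulation", "PROCESS")],
    "passive_regulation": [("MIR", "regulation", "PROCESS")],
    "involvement": [("MIR", "involvement", "PROCESS")],
    "association": [("MIR", "association", "DISEASE")],
    "found_in": [("MIR", "found_in", "DISEASE")],
    "null_argument": [("MIR", "regulation", "DISEASE"),
                      ("MIR", "regulation", "GENE")],
    "is_a_biomarker": [("MIR", "is_a", "DISEASE")],
    "hedged_biomarker": [("MIR", "is_a", "DISEASE")],
    "conjunction": [("MIR", "association", "DISEASE"),
                    ("MIR2", "association", "DISEASE")],
}


def default_templates() -> list[SentenceTemplate]:
    T = SentenceTemplate
    return [
        T("active_regulation", "{MIR} {REG3} {PROCESS} in {DISEASE}.",
          ("MIR", "REG3", "PROCESS", "DISEASE"), score=2),
        T("passive_regulation", "{PROCESS} is {REG_PPL} by {MIR} in {DISEASE}.",
          ("PROCESS", "REG_PPL", "MIR", "DISEASE"), score=2),
        T("involvement", "{MIR} is involved in {PROCESS} in {DISEASE}.",
          ("MIR", "PROCESS", "DISEASE"), score=1),
        T("association", "{MIR} expression is associated with {DISEASE}.",
          ("MIR", "DISEASE"), score=1),
        T("found_in", "{MIR} is upregulated in {DISEASE}.",
          ("MIR", "DISEASE"), score=1),
        T("null_argument", "{MIR} {REG3} {DISEASE} by {REG_GER} {GENE}.",
          ("MIR", "REG3", "DISEASE", "REG_GER", "GENE"), score=3),
        T("is_a_biomarker", "{MIR} is a biomarker for {DISEASE}.",
          ("MIR", "DISEASE"), score=1),
        T("hedged_biomarker", "{MIR} might be a biomarker for {DISEASE}.",
          ("MIR", "DISEASE"), score=1),  # downgrade clamped at the floor
        T("conjunction", "{MIR} and {MIR2} are associated with {DISEASE}.",
          ("MIR", "MIR2", "DISEASE"), score=1),
    ]


def negative_templates() -> list[SentenceTemplate]:
    """Documented miss classes: the pipeline must extract nothing."""
    T = SentenceTemplate
    return [
        T("anaphora", "Its expression inhibits {PROCESS} in {DISEASE}.",
          ("PROCESS", "DISEASE"), score=None, negative=True, easy=False),
        T("temporal",
          "{DISEASE} cells were analyzed after knockdown of {MIR}.",
          ("DISEASE", "MIR"), score=None, negative=True, easy=False),
    ]


_REG_VERBS = ("regulate", "suppress", "inhibit", "promote", "modulate",
              "induce", "repress", "enhance", "block", "mediate")


def default_fillers(lexicon: TriggerLexicon | None = None) -> dict[str, list[str]]:
    lexicon = lexicon or load_default_lexicon()
    mirs = [f"mir-{i}" for i in
            (1, 7, 9, 10, 16, 21, 23, 26, 29, 31, 34, 92, 101, 122, 126,
             133, 143, 145, 150, 155)]
    diseases = [d for d in sorted(lexicon.diseases) if " " in d or len(d) > 6][:15]
    genes = sorted(lexicon.genes)[:10]
    processes = ["apoptosis", "cell proliferation", "angiogenesis",
                 "cell growth", "migration", "autophagy", "differentiation",
                 "cell motility", "metastasis", "invasion"][:10]
    # metastasis/invasion are outcome aspects, not plain processes: keep the
    # template gold derivable by excluding them from the PROCESS slot
    processes = [p for p in processes if p not in ("metastasis", "invasion")]
    return {
        "MIR": mirs,
        "MIR2": mirs,
        "DISEASE": diseases,
        "GENE": genes,
        "PROCESS": processes,
        "REG3": [v + ("es" if v.endswith(("s", "sh", "ch", "x", "z")) else "s")
                 for v in _REG_VERBS],
        "REG_PPL": [v + ("d" if v.endswith("e") else "ed") for v in _REG_VERBS],
        "REG_GER": [v[:-1] + "ing" if v.endswith("e") else v + "ing"
                    for v in _REG_VERBS],
    }


def generate(
    n: int,
    seed: int,
    templates: list[SentenceTemplate] | None = None,
    fillers: dict[str, list[str]] | None = None,
) -> list[GoldSentence]:
    """Generate ``n`` synthetic gold sentences (deterministic for a seed)."""
    templates = templates or default_templates()
    fillers = fillers or default_fillers()
    rng = random.Random(seed)
    out = []
    for k in range(n):
        t = templates[k % len(templates)]
        slots = {}
        for name in t.slots:
            pool = fillers.get(name)
            if not pool:
                raise ValueError(f"empty filler list for slot {name!r}")
            slots[name] = rng.choice(pool)
        if "MIR2" in slots:
            while slots["MIR2"] == slots.get("MIR"):
                slots["MIR2"] = rng.choice(fillers["MIR2"])
        out.append(
            GoldSentence(
                pmid=f"S{k:05d}",
                text=t.pattern.format(**slots),
                gold_relations=t.expected(slots),
                gold_score=t.score,
                negative=t.negative,
                note=f"template:{t.name}",
            )
        )
    return out


def write_gold_jsonl(corpus: list[GoldSentence], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for s in corpus:
            fh.write(json.dumps({
                "pmid": s.pmid, "text": s.text,
                "gold_relations": [list(t) for t in s.gold_relations],
                "gold_linking": s.gold_linking,
                "gold_score": s.gold_score,
                "negative": s.negative,
                "note": s.note,
            }, sort_keys=True) + "\n")
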