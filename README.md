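# mirlink

Rule-based extraction of microRNA–disease associations from biomedical
abstracts, with informativeness scoring of the evidence sentences.

## The problem

MicroRNAs (miRs) are linked to diseases in the literature in many indirect
ways: a miR's *aspect* (expression level, mutation, methylation state) may be
associated with a disease or with a disease *aspect* (outcome, biomarker,
therapy), or the miR may regulate a *linking entity* — a target gene or a
cellular process — whose connection to the co-mentioned disease is left
implicit. Curators of miR–disease databases and researchers studying disease
mechanisms both need these associations pulled out of abstracts at scale,
together with the explanation that bridges them.

`mirlink` extracts triplets **⟨miR, disease, evidence sentence⟩** with the
connecting semantic relations and linking entities, and assigns each evidence
sentence an informativeness score in {1, 2, 3}.

## How it works

1. **Entity detection** — miR mentions by the community naming convention
   (`miR/MIR/miRNA/microRNA/let` + identifying number + optional suffixes);
   diseases and genes from PubTator-style sidecar annotations or a bundled
   lexicon; aspect and process candidates from editable trigger lists.
2. **Preliminary syntactic processing** — sentence splitting, deterministic
   rule-based POS tagging (pluggable: any Penn-tagset tagger can be
   injected), and finite-state chunking into noun phrases, verb groups and
   prepositional phrases. Sentences without a miR or disease mention are
   filtered out.
3. **Simplification** — appositives, list/pair conjunctions, relative and
   reduced relative clauses and parentheticals are rewritten into simple
   clauses ("four miRNAs, miR-21, …, all implicated in …" →
   "miR-21 is implicated in …").
4. **Syntactic dependencies** — agent–theme of predicate (voice-normalized,
   with nominalized and multi-word predicates and null-argument clauses
   signalled by *to*+verb, *via/through/by*+gerund or nominalization) and
   noun modification (premodifier and of/in-PP forms).
5. **Semantic relations** — the predicate head is matched against six trigger
   categories: involvement, regulation, association, is-a, found-in, state.
   Stacked triggers resolve to the more specific relation
   ("involved in the regulation of X" → regulates X).
6. **Scoring** — 3 = the sentence explains the association (null-argument
   chain, event sequence, or target-gene information plus another relation);
   2 = diagnostic+treatment aspects, regulation of a linking entity, or a
   treatment-aspect theme; 1 = altered expression, involvement, or a
   diagnostic aspect; +1 for an outcome aspect, −1 for co-occurrence-only
   diagnostic/treatment aspects, −1 for hedging; clamped to [1, 3].

## Worked example

```python
from mirlink import process_text

res = process_text(
    "MicroRNA-9 promotes tumor metastasis via repressing E-cadherin "
    "in esophageal squamous cell carcinoma."
)
for ev in res.scored:
    t = ev.triplet
    print(t.mir.key, "|", t.disease.key, f"[{t.disease.aspect_surface}]",
          "| linking:", [l.key for l in t.linking],
          "| chain:", [r.trigger for r in t.relations],
          "| score:", ev.final_score)
```

prints

```
mir-9 | esophageal squamous cell carcinoma [metastasis] | linking: ['e-cadherin'] | chain: ['promote', 'repress'] | score: 3
```

i.e. miR-9 is tied to esophageal squamous cell carcinoma through its outcome
aspect (metastasis) and through repression of the target gene E-cadherin; the
sentence explains the association (a null-argument *via*-clause), so it is
scored highly informative (3).

The same pipeline is available from the shell:

```bash
mirlink fixtures gold --pubtator-out gold.pubtator --tuples-out gold_tuples.tsv
mirlink extract --input gold.pubtator --output triplets.tsv --tuples-out sys.tsv
mirlink eval --system sys.tsv --gold gold_tuples.tsv --out report.json
```

`extract` writes one TSV/JSONL row per association triplet (pmid, miR and
aspect, relation category and trigger, disease and aspect, linking entities,
evidence sentence, score); `eval` reports recall/precision/F of the relation
tuples plus Pearson/Kendall-τb/Spearman, a seeded permutation baseline and
nDCG over tie-consistent orderings for the informativeness ranking;
`fixtures generate` writes seeded synthetic gold corpora.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the full pipeline on three canonical exemplar sentences (packaged in
`mirlink.fixtures`) and writes the informativeness score the scoring rules
assign to each, after a seeded synthetic end-to-end self-check of the whole
extraction stack.

## Scope notes

The package consumes pre-computed disease/gene annotations (PubTator exchange
format) when available and otherwise falls back to a small bundled lexicon;
it does not re-implement statistical NER or concept normalization, does not
resolve pronouns, and does not follow temporal connectives — sentences whose
association is visible only through those devices are deliberately left
unextracted (see `docs/methods.md`).
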