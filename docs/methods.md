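# Methods

## Extraction model

The extractor is a deterministic, lexico-syntactic rule system. Its working
assumption is that miR–disease information in abstracts is carried by a small
number of local syntactic configurations over *chunks* (non-recursive NPs,
verb groups, PPs), provided complex sentences are first rewritten into simple
clauses. Two dependency families carry all the signal:

* **agent–theme of predicate.** Active `NP VG NP`, passive
  `NP VG(be+VBN) [by|with|in|to NP]`, two consecutive verb groups
  ("is known" + "to directly regulate" — the head of the *final* group is the
  predicate), nominalized predicates (`miR-9 regulation of X`: a premodifier
  agent plus an of-PP theme are both required; a lone modifier is a state,
  not an agent–theme pair), multi-word predicates ("play a role in",
  "is crucial for", "acts/functions/serves as"), and *null-argument* clauses
  in which the agent is elided and inherited from the nearest preceding
  explicit agent. Null-argument connectives: `to`+verb after a theme, and
  `by`/`via`/`through` followed by either a gerund or a nominalization with an
  of-PP theme. (The gerund form is accepted for all three prepositions: real
  usage mixes them, e.g. "promotes metastasis *via repressing* E-cadherin".)
  Arguments are maximal NPs — base NP plus attached PPs — with right
  association for PP attachment; `by/via/through` PPs never attach, since they
  signal passive agents and null-argument clauses.
* **noun modification.** An entity premodifying an aspect head
  ("mir-21 overexpression") or inside its of/in-PP ("metastasis of gastric
  cancer"); for diagnostic/treatment heads the disease argument is also
  accepted from for/with-PPs ("biomarker for … colorectal cancer"). miR
  aspects take miR or gene modifiers; disease aspects take disease modifiers.

A dependency becomes a **semantic relation** when its predicate lemma (plus
the theme's preposition, where one was consumed) matches a trigger category:
involvement, regulation, association, is-a, found-in (two trigger classes:
aspect stated in the miR entity vs. inferred from the predicate), or state
(noun modification only). Matching is lemma-based; all verbal triggers are
expanded to their inflections and paired with their nominalizations at
lexicon load time, and the load-time audit fails if two categories claim the
same (lemma, preposition) key. When triggers stack between one agent and one
ultimate theme, only the more specific relation survives (regulation >
involvement ≥ is-a): "involved in the regulation of apoptosis" yields
`[miR-9, regulates, apoptosis]`.

Entity resolution is head-driven: the base-NP head decides whether a maximal
NP denotes a miR entity, disease entity, or linking entity (gene / process /
role noun), composing aspect heads with their noun-modification modifier. An
outcome/diagnostic/treatment head with no local disease argument composes
with a co-occurring disease mention of the same sentence — the observable
realization of the "implicit linking-entity → disease connection". Processes
are recognized from a dictionary or by derivational suffix
(-sion/-tion/-sis/-or/-er/-ment); the suffix route is admitted only in theme
position, because agentive nouns ("suppressor 1") would otherwise masquerade
as processes in subject position. Negated predicates are extracted with a
flag and discarded at relation assignment (a conservative precision choice;
the source rules are silent on negation).

## Informativeness scoring

Base score: 3 when the sentence *explains* the association — a null-argument
dependency, ≥2 relations forming an event sequence, or target-gene
information plus another relation; 2 for diagnostic+treatment aspects, a
regulation of a linking entity, or a treatment-aspect theme; 1 for altered
expression, involvement, a diagnostic aspect, or anything weaker.
Adjustments, each at most once, additively then clamped to [1, 3]: +1 outcome
aspect present; −1 diagnostic/treatment aspect present only by co-occurrence
(outside every relation); −1 hedging (*might, could, suggest, propose* and
inflections — deliberately not *may* or *can*, which the exemplar sentences
use without a downgrade).

One rubric choice needs flagging: the event-sequence rule names the
connectives *contributes / results in / causes / supports* "and their textual
variations, as well as the conjunction and". Treating bare *and* as an event
connective would push the miR-23b exemplar (two relations joined by "and") to
3 although its defined score is 2, so plain *and* is **not** accepted as a
sequence marker here; the lexical connectives are. Whether an upgrade and a
downgrade can cancel (net 0) is undefined in the rubric; this implementation
is additive-then-clamp.

## Tagging and chunking

No statistical tagger is bundled (and none is assumed at runtime): POS
tagging is a contract — any callable from token surfaces to Penn tags — whose
default is a deterministic lexicon+suffix tagger. Its verb vocabulary is
generated from the trigger lexicon, so every predicate the rules can match is
guaranteed a verb reading; two repair passes resolve noun/verb homographs
("a therapeutic *target*") and -ed forms (perfect/passive participle vs.
premodifier vs. reduced relative vs. past tense) from local context. The
chunk grammar is a reconstruction validated against the worked examples in
the test suite; it is greedy, one-pass, and deliberately non-recursive.

## Synthetic data

`mirlink.fixtures.generate` emulates single-fact evidence sentences: one
clause, one trigger, slots filled from the bundled miR/disease/gene/process
lists, in active, passive, null-argument, conjunction, is-a and hedged
shapes, each with gold tuples and scores derivable from the template itself.
It does **not** emulate real Medline length or topic distribution,
multi-clause discourse, anaphora chains, or novel vocabulary outside the
bundled lexicons — so a green synthetic suite establishes that the machinery
is sound on the constructions it claims to handle, not that corpus-level
recall matches any published figure. Negative templates (anaphoric subjects,
temporal *after*-clauses) assert the documented miss classes stay missed
rather than being half-extracted. Generation is deterministic per seed.

## Evaluation machinery

Relation matching is exact-tuple after lowercasing; recall/precision/F are
reported as percentages with undefined denominators reported as absent.
Kendall uses the tau-b tie correction and Spearman average ranks (scores on a
3-point scale are heavily tied; the variant choice is documented rather than
prescribed). DCG uses the classical `rel(1) + Σ_{i≥2} rel(i)/log2(i)` form
with gold scores as graded relevance; because the system ranking only orders
score classes, nDCG is summarized (mean/min/median) over seeded shuffles of
the tied blocks. The permutation baseline reports mean and max Pearson over
seeded reorderings of the gold scores. All stochastic summaries carry their
seed and n.

## Defaults and parameters

| parameter | default | why |
| --- | --- | --- |
| copula inserted for reduced relatives | present tense, number-agreeing | matches the generated worked example |
| simplification passes | 1 (outside-in, no re-detection) | bounds output; covers all packaged constructs |
| appositive guard | counted anchor ("four miRNAs") or plural+numeral | precision guard against spurious parentheticals |
| agent tie-break | nearest mention-bearing NP left of the predicate | local rule; matches all packaged examples |
| score clamp | [1, 3] | the rubric never emits scores outside it |
| permutation / ordering draws | 10,000 | matches the evaluation design it reproduces |
| nDCG gain | classical; exponential behind a flag | canonical form of the cited measure |

## Known limitations

* No anaphora or coreference: "its target gene, BCL-2" is not linked.
* No temporal relations: "… after knockdown of miR-221/222" is not extracted.
* No cross-sentence assembly, no confidence scores, no MEDIC/HGNC
  normalization beyond sidecar pass-through.
* The bundled disease/gene lexicons cover the packaged examples and the
  synthetic generator; real corpus runs should supply PubTator sidecar
  annotations.
* Coordination scope is comma/CC-local; shared-head distributions
  ("miR-15b and miR-16 expression") substitute whole members rather than
  distributing the head noun.
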