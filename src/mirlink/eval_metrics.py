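"""Evaluation machinery: relation matching, rank correlations, nDCG.

Extraction quality is assessed by exact-tuple matching of (miR, category,
theme) relations against an annotated gold set (true positives / false
negatives / false positives with the derived recall, precision and F-score).
The informativeness ranking is assessed against annotator scores on the
1-3 scale with Pearson, Kendall tau-b and Spearman correlations (scipy), a
seeded permutation baseline, and normalized discounted cumulative gain
averaged over orderings consistent with the tied system ranking.

DCG uses the classical discounted-gain form

    DCG = rel(1) + sum_{i >= 2} rel(i) / log2(i)

with the graded relevance rel(i) equal to the gold score of the item at rank
i; nDCG divides by the DCG of the gold-sorted ideal ordering.  An
exponential-gain variant (2^rel - 1, 1/log2(i+1) discount) is available via
``exponential=True``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "MatchTally",
    "RankComparison",
    "match_relations",
    "correlations",
    "permutation_baseline",
    "dcg",
    "ndcg",
    "ndcg_over_orderings",
]


@dataclass
class MatchTally:
    """TP/FN/FP/TN counts with derived recall / precision / F-score.

    Metrics are fractions in [0, 1]; an undefined denominator yields None
    (reported as absent, never as 0).  Use ``as_percent`` for the 0-100
    scale evaluation tables conventionally print.
    """

    tp: int = 0
    fn: int = 0
    fp: int = 0
    tn: int = 0

    @property
    def recall(self) -> float | None:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else None

    @property
    def precision(self) -> float | None:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else None

    @property
    def f_score(self) -> float | None:
        p, r = self.precision, self.recall
        if p is None or r is None or (p + r) == 0:
            return None
        return 2 * p * r / (p + r)

    def as_percent(self, digits: int = 1) -> dict:
        def pct(x):
            return None if x is None else round(100 * x, digits)

        return {
            "tp": self.tp, "fn": self.fn, "fp": self.fp, "tn": self.tn,
            "recall": pct(self.recall), "precision": pct(self.precision),
            "f_score": pct(self.f_score),
        }


def _norm_tuple(t: Sequence[str]) -> tuple:
    return tuple(str(x).strip().lower() for x in t)


def match_relations(system: Iterable, gold: Iterable) -> MatchTally:
    """Exact-tuple matching of relation tuples after lowercasing.

    Tuples are typically (miR, category, theme); duplicates collapse.  TP are
    tuples in both sets, FN gold-only, FP system-only.
    """
    sys_set = {_norm_tuple(t) for t in system}
    gold_set = {_norm_tuple(t) for t in gold}
    return MatchTally(
        tp=len(sys_set & gold_set),
        fn=len(gold_set - sys_set),
        fp=len(sys_set - gold_set),
    )


@dataclass
class RankComparison:
    system_scores: list[int]
    gold_scores: list[int]
    pearson: float | None = None
    kendall: float | None = None
    spearman: float | None = None
    mean_abs_diff: float | None = None
    ndcg_mean: float | None = None
    ndcg_min: float | None = None
    ndcg_median: float | None = None

    def as_dict(self) -> dict:
        return {
            "n": len(self.system_scores),
            "pearson": self.pearson,
            "kendall": self.kendall,
            "spearman": self.spearman,
            "mean_abs_diff": self.mean_abs_diff,
            "ndcg_mean": self.ndcg_mean,
            "ndcg_min": self.ndcg_min,
            "ndcg_median": self.ndcg_median,
        }


def correlations(system_scores: Sequence[int], gold_scores: Sequence[int]) -> RankComparison:
    """Pearson, Kendall tau-b and Spearman between two score lists.

    Kendall uses the tau-b tie correction (scores on a 3-point scale are
    heavily tied); Spearman uses average ranks.  A constant list makes the
    correlations undefined: they are reported as None.
    """
    s = np.asarray(system_scores, dtype=float)
    g = np.asarray(gold_scores, dtype=float)
    if s.shape != g.shape or s.size < 2:
        raise ValueError("score lists must have equal length >= 2")
    cmp_ = RankComparison(list(map(int, s)), list(map(int, g)))
    cmp_.mean_abs_diff = float(np.mean(np.abs(s - g)))
    if np.ptp(s) == 0 or np.ptp(g) == 0:
        return cmp_  # constant input: correlations undefined
    cmp_.pearson = float(stats.pearsonr(s, g).statistic)
    cmp_.kendall = float(stats.kendalltau(s, g, variant="b").statistic)
    cmp_.spearman = float(stats.spearmanr(s, g).statistic)
    return cmp_


def permutation_baseline(
    system_scores: Sequence[int],
    gold_scores: Sequence[int],
    n_perm: int = 10_000,
    seed: int = 0,
) -> dict:
    """Pearson correlation of the system scores against permuted gold scores.

    Returns the mean and max over ``n_perm`` seeded random reorderings --
    the chance-level baseline for the observed correlation.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    s = np.asarray(system_scores, dtype=float)
    g = np.asarray(gold_scores, dtype=float)
    if np.ptp(s) == 0 or np.ptp(g) == 0:
        return {"mean": None, "max": None, "n_perm": n_perm, "seed": seed}
    vals = np.empty(n_perm)
    s_c = s - s.mean()
    s_norm = math.sqrt(float(s_c @ s_c))
    for i in range(n_perm):
        p = rng.permutation(g)
        p_c = p - p.mean()
        vals[i] = float(s_c @ p_c) / (s_norm * math.sqrt(float(p_c @ p_c)))
    return {
        "mean": float(vals.mean()),
        "max": float(vals.max()),
        "n_perm": n_perm,
        "seed": seed,
    }


def dcg(rels: Sequence[float], exponential: bool = False) -> float:
    """Discounted cumulative gain of a relevance sequence in rank order."""
    if exponential:
        return sum(
            (2 ** r - 1) / math.log2(i + 2) for i, r in enumerate(rels)
        )
    total = 0.0
    for i, r in enumerate(rels, start=1):
        total += r if i == 1 else r / math.log2(i)
    return total


def ndcg(
    ranked_gold_rels: Sequence[float],
    ideal_rels: Sequence[float] | None = None,
    exponential: bool = False,
) -> float | None:
    ideal = sorted(ideal_rels if ideal_rels is not None else ranked_gold_rels,
                   reverse=True)
    denom = dcg(ideal, exponential)
    if denom == 0:
        return None
    return dcg(ranked_gold_rels, exponential) / denom


def ndcg_over_orderings(
    system_scores: Sequence[int],
    gold_scores: Sequence[int],
    n_orderings: int = 10_000,
    seed: int = 0,
    exponential: bool = False,
) -> dict:
    """nDCG summarized over orderings consistent with the system's ranking.

    Items are ranked by system score descending; items with tied system
    scores can appear in any order, so ties are shuffled ``n_orderings``
    times and the nDCG of each full ordering (graded relevance = gold score)
    is computed.  Returns mean, min and median plus the RNG provenance.
    """
    rng = np.random.default_rng(seed)
    s = np.asarray(system_scores)
    g = np.asarray(gold_scores, dtype=float)
    if not g.any():
        return {"mean": None, "min": None, "median": None,
                "n_orderings": n_orderings, "seed": seed}
    groups = [np.flatnonzero(s == v) for v in sorted(set(s.tolist()), reverse=True)]
    ideal = sorted(g.tolist(), reverse=True)
    vals = np.empty(n_orderings)
    for k in range(n_orderings):
        order = np.concatenate([rng.permutation(idx) for idx in groups])
        vals[k] = dcg(g[order], exponential) / dcg(ideal, exponential)
    return {
        "mean": float(vals.mean()),
        "min": float(vals.min()),
        "median": float(np.median(vals)),
        "n_orderings": n_orderings,
        "seed": seed,
    }
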