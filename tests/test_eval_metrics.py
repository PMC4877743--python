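import math
import random

import numpy as np
import pytest

from mirlink.eval_metrics import (
    MatchTally,
    correlations,
    dcg,
    match_relations,
    ndcg,
    ndcg_over_orderings,
    permutation_baseline,
)


# --- tallies -------------------------------------------------------------------


@pytest.mark.parametrize(
    "tp,fn,fp,recall,precision,f",
    [
        (147, 28, 8, 84.0, 94.8, 89.1),  # general-extraction evaluation row
        (48, 4, 4, 92.3, 92.3, 92.3),  # expression-information evaluation row
    ],
)
def test_published_table_rows(tp, fn, fp, recall, precision, f):
    t = MatchTally(tp=tp, fn=fn, fp=fp)
    pct = t.as_percent()
    assert (pct["recall"], pct["precision"], pct["f_score"]) == (
        recall, precision, f,
    )


def test_f_equals_harmonic_mean_property():
    rng = random.Random(11)
    for _ in range(200):
        t = MatchTally(tp=rng.randint(0, 50), fn=rng.randint(0, 50),
                       fp=rng.randint(0, 50))
        p, r, f = t.precision, t.recall, t.f_score
        if p is None or r is None or p + r == 0:
            assert f is None or p + r == 0
        else:
            assert f == pytest.approx(2 * p * r / (p + r))


def test_match_relations_counts():
    gold = [("mir-9", "regulation", "apoptosis"),
            ("mir-21", "is_a", "glioma")]
    system = [("MIR-9", "regulation", "Apoptosis"),
              ("mir-7", "association", "glioma")]
    t = match_relations(system, gold)
    assert (t.tp, t.fn, t.fp) == (1, 1, 1)


def test_match_identical_sets_is_perfect():
    gold = [("a", "b", "c"), ("d", "e", "f")]
    t = match_relations(gold, gold)
    assert t.as_percent() == {
        "tp": 2, "fn": 0, "fp": 0, "tn": 0,
        "recall": 100.0, "precision": 100.0, "f_score": 100.0,
    }


def test_empty_tally_metrics_absent():
    t = match_relations([], [])
    assert t.recall is None and t.precision is None and t.f_score is None


# --- correlations ----------------------------------------------------------------


def test_identical_lists_all_one():
    c = correlations([3, 2, 1, 2, 3], [3, 2, 1, 2, 3])
    assert c.pearson == pytest.approx(1.0)
    assert c.kendall == pytest.approx(1.0)
    assert c.spearman == pytest.approx(1.0)
    assert c.mean_abs_diff == 0.0


def test_strict_reversal_kendall_minus_one():
    c = correlations([1, 2, 3, 4], [4, 3, 2, 1])
    assert c.kendall == pytest.approx(-1.0)
    assert c.spearman == pytest.approx(-1.0)


def _tau_b_bruteforce(x, y):
    """O(n^2) concordant/discordant pair counting with tie correction."""
    n = len(x)
    nc = nd = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            a = (x[i] > x[j]) - (x[i] < x[j])
            b = (y[i] > y[j]) - (y[i] < y[j])
            if a == 0 and b == 0:
                tx += 1
                ty += 1
            elif a == 0:
                tx += 1
            elif b == 0:
                ty += 1
            elif a == b:
                nc += 1
            else:
                nd += 1
    n0 = n * (n - 1) // 2
    denom = math.sqrt((n0 - tx) * (n0 - ty))
    return (nc - nd) / denom if denom else None


def test_tau_b_hand_case():
    got = correlations([3, 2, 1, 1], [3, 1, 2, 1]).kendall
    assert got == pytest.approx(_tau_b_bruteforce([3, 2, 1, 1], [3, 1, 2, 1]))


def test_tau_b_matches_bruteforce_on_100_random_lists():
    rng = random.Random(5)
    checked = 0
    while checked < 100:
        n = rng.randint(3, 30)
        x = [rng.randint(1, 3) for _ in range(n)]
        y = [rng.randint(1, 3) for _ in range(n)]
        if len(set(x)) < 2 or len(set(y)) < 2:
            continue
        expect = _tau_b_bruteforce(x, y)
        got = correlations(x, y).kendall
        assert got == pytest.approx(expect, abs=1e-12)
        checked += 1


def test_constant_list_correlations_absent():
    c = correlations([2, 2, 2], [1, 2, 3])
    assert c.pearson is None and c.kendall is None and c.spearman is None
    assert c.mean_abs_diff is not None


def test_length_mismatch_raises():
    with pytest.raises(ValueError):
        correlations([1, 2], [1, 2, 3])


# --- permutation baseline ---------------------------------------------------------


def test_permutation_mean_near_zero():
    rng = random.Random(7)
    s = [rng.randint(1, 3) for _ in range(200)]
    g = [rng.randint(1, 3) for _ in range(200)]
    out = permutation_baseline(s, g, n_perm=10_000, seed=123)
    assert abs(out["mean"]) < 3 / math.sqrt(200)  # analytic null expectation 0
    assert out["max"] <= 1.0


def test_permutation_constant_gold_absent():
    out = permutation_baseline([1, 2, 3], [2, 2, 2], n_perm=5, seed=0)
    assert out["mean"] is None and out["max"] is None


def test_permutation_single_perm_is_valid_pearson():
    out = permutation_baseline([1, 2, 3, 1], [3, 1, 2, 2], n_perm=1, seed=4)
    assert -1.0 <= out["mean"] == out["max"] <= 1.0


def test_permutation_reproducible():
    s, g = [1, 2, 3, 2, 1, 3] * 5, [3, 1, 2, 2, 3, 1] * 5
    a = permutation_baseline(s, g, n_perm=50, seed=9)
    b = permutation_baseline(s, g, n_perm=50, seed=9)
    assert a == b


# --- nDCG -------------------------------------------------------------------------


def test_ndcg_perfect_ranking_is_one():
    out = ndcg_over_orderings([3, 2, 1], [3, 2, 1], n_orderings=10, seed=0)
    assert out["mean"] == out["min"] == out["median"] == pytest.approx(1.0)


def test_ndcg_three_item_hand_summation():
    # gold relevances in system order [1, 3, 2] against ideal [3, 2, 1]:
    # DCG = 1 + 3/log2(2) + 2/log2(3); IDCG = 3 + 2/log2(2) + 1/log2(3)
    expect = (1 + 3 / math.log2(2) + 2 / math.log2(3)) / (
        3 + 2 / math.log2(2) + 1 / math.log2(3)
    )
    assert ndcg([1, 3, 2], [3, 2, 1]) == pytest.approx(expect)


def test_ndcg_no_ties_single_ordering():
    out = ndcg_over_orderings([3, 2, 1], [1, 2, 3], n_orderings=2, seed=1)
    assert out["mean"] == out["min"] == out["median"]


def test_ndcg_in_unit_interval_and_monotone_swap():
    rng = random.Random(3)
    for _ in range(30):
        n = rng.randint(3, 12)
        gold = [rng.randint(1, 3) for _ in range(n)]
        order = list(range(n))
        rng.shuffle(order)
        rels = [gold[i] for i in order]
        v = ndcg(rels, gold)
        assert v is None or 0 < v <= 1.0 + 1e-12
        # swapping two adjacent items into gold order never decreases nDCG
        for k in range(n - 1):
            if rels[k] < rels[k + 1]:
                swapped = rels[:k] + [rels[k + 1], rels[k]] + rels[k + 2:]
                assert ndcg(swapped, gold) >= ndcg(rels, gold) - 1e-12


def test_ndcg_all_zero_gold_absent():
    out = ndcg_over_orderings([1, 2], [0, 0], n_orderings=3, seed=0)
    assert out["mean"] is None


def test_exponential_gain_variant():
    assert dcg([3, 2], exponential=True) == pytest.approx(
        (2**3 - 1) / math.log2(2) + (2**2 - 1) / math.log2(3)
    )
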