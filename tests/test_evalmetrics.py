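"""Statistics vs independent brute-force / closed-form oracles."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from pdl1tps.annotio import CellAnnotation, CellClass
from pdl1tps.cnet import Detection
from pdl1tps.evalmetrics import (
    concordance_report,
    correlations,
    count_errors,
    fleiss_kappa_two_raters,
    icc_two_way,
    ips_tps_association,
    kappa_at_cutoffs,
    object_f1,
    match_points,
)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def brute_force_matching(pred, truth, radius):
    """Exhaustive optimal matching: max cardinality, then min total distance."""
    best = (0, 0.0)
    m, n = len(pred), len(truth)
    for k in range(min(m, n), -1, -1):
        found = None
        for ps in itertools.combinations(range(m), k):
            for ts in itertools.permutations(range(n), k):
                dists = [math.dist(pred[i], truth[j]) for i, j in zip(ps, ts)]
                if all(d <= radius for d in dists):
                    tot = sum(dists)
                    if found is None or tot < found:
                        found = tot
        if found is not None:
            return k, found
    return 0, 0.0


def brute_force_icc2(a, b):
    """ICC(2,1) from explicitly looped ANOVA sums of squares."""
    n, k = len(a), 2
    x = [[a[i], b[i]] for i in range(n)]
    grand = sum(sum(r) for r in x) / (n * k)
    row = [sum(r) / k for r in x]
    col = [sum(x[i][j] for i in range(n)) / n for j in range(2)]
    msr = sum(k * (r - grand) ** 2 for r in row) / (n - 1)
    msc = sum(n * (c - grand) ** 2 for c in col) / (k - 1)
    sse = sum((x[i][j] - row[i] - col[j] + grand) ** 2
              for i in range(n) for j in range(2))
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def brute_force_fleiss(cat_a, cat_b):
    """Fleiss' kappa from the explicit n_ij table, two raters, two cats."""
    n = len(cat_a)
    table = [[0, 0] for _ in range(n)]
    for i in range(n):
        table[i][cat_a[i]] += 1
        table[i][cat_b[i]] += 1
    pj = [sum(t[j] for t in table) / (2 * n) for j in range(2)]
    pe = sum(p ** 2 for p in pj)
    pi = [(t[0] * (t[0] - 1) + t[1] * (t[1] - 1)) / 2 for t in table]
    pbar = sum(pi) / n
    if pe == 1.0:
        return None
    return (pbar - pe) / (1 - pe)


# ---------------------------------------------------------------------------
# object F1
# ---------------------------------------------------------------------------

def _det(x, y, cls=CellClass.TC_POS):
    return Detection(x, y, cls, 1.0)


def _ann(x, y, cls=CellClass.TC_POS):
    return CellAnnotation(x, y, cls)


def test_perfect_detection():
    pts = [(3, 4), (20, 8), (11, 30)]
    res = object_f1([_det(*p) for p in pts], [_ann(*p) for p in pts], 5.0)
    assert res.precision == res.recall == res.f1 == 1.0


def test_totally_missed():
    res = object_f1([_det(0, 0)], [_ann(100, 100)], 10.0)
    assert res.f1 == 0.0


def test_extra_prediction_counts_fp():
    res = object_f1([_det(0, 0), _det(3, 0)], [_ann(0, 0)], 5.0)
    c = res.per_class[CellClass.TC_POS]
    assert (c.tp, c.fp, c.fn) == (1, 1, 0)
    assert c.precision == 0.5 and c.recall == 1.0
    assert c.f1 == pytest.approx(2 / 3)


def test_class_mismatch_not_matched():
    res = object_f1([_det(0, 0, CellClass.TC_NEG)], [_ann(0, 0)], 5.0)
    assert res.f1 == 0.0


def test_matching_equals_bruteforce_small_instances():
    rng = np.random.default_rng(0)
    for _ in range(60):
        m, n = rng.integers(0, 5, 2)
        pred = [tuple(p) for p in rng.uniform(0, 20, (m, 2))]
        truth = [tuple(p) for p in rng.uniform(0, 20, (n, 2))]
        radius = float(rng.uniform(2, 12))
        got = match_points(np.array(pred, float).reshape(-1, 2),
                           np.array(truth, float).reshape(-1, 2), radius)
        want_k, want_d = brute_force_matching(pred, truth, radius)
        assert len(got) == want_k
        tot = sum(math.dist(pred[i], truth[j]) for i, j in got)
        assert tot == pytest.approx(want_d, abs=1e-9)


def test_object_f1_symmetry_and_translation_invariance():
    rng = np.random.default_rng(1)
    pred = [_det(int(x), int(y)) for x, y in rng.integers(0, 50, (6, 2))]
    truth = [_ann(int(x), int(y)) for x, y in rng.integers(0, 50, (5, 2))]
    fwd = object_f1(pred, truth, 8.0)
    swapped = object_f1([_det(a.x, a.y) for a in truth],
                        [_ann(d.x, d.y) for d in pred], 8.0)
    assert fwd.precision == pytest.approx(swapped.recall)
    assert fwd.recall == pytest.approx(swapped.precision)
    shifted = object_f1([_det(d.x + 13, d.y + 7) for d in pred],
                        [_ann(a.x + 13, a.y + 7) for a in truth], 8.0)
    assert shifted.f1 == pytest.approx(fwd.f1)


# ---------------------------------------------------------------------------
# count errors
# ---------------------------------------------------------------------------

def test_count_errors_hand_example():
    res = count_errors([4, 6], [5, 6])
    assert res.mae == 0.5
    assert res.rmse == pytest.approx(0.70711, abs=1e-5)
    assert res.mape == pytest.approx(10.0)


def test_count_errors_perfect():
    res = count_errors([3, 3], [3, 3])
    assert res.mae == res.rmse == 0.0 and res.mape == 0.0


def test_count_errors_zero_truth_handling():
    res = count_errors([2, 5], [0, 5])
    assert res.mae == 1.0            # zero-truth patch still in MAE
    assert res.mape == 0.0           # but excluded from MAPE
    assert count_errors([1], [0]).mape is None
    assert res.rmse >= res.mae


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------

def test_icc_identical_raters():
    a = [0.0, 20.0, 40.0, 60.0, 80.0]
    res = icc_two_way(a, a)
    assert res.icc == pytest.approx(1.0)


def test_icc_constant_shift_below_one():
    a = [0.0, 20.0, 40.0, 60.0, 80.0]
    b = [x + 10 for x in a]
    res = icc_two_way(a, b)
    assert res.icc < 1.0
    assert res.icc == pytest.approx(brute_force_icc2(a, b), abs=1e-12)


def test_icc_matches_bruteforce_random():
    rng = np.random.default_rng(2)
    for _ in range(50):
        n = int(rng.integers(5, 13))
        a = rng.uniform(0, 100, n)
        b = np.clip(a + rng.normal(0, rng.uniform(1, 30), n), 0, 100)
        res = icc_two_way(a, b)
        assert res.icc == pytest.approx(brute_force_icc2(list(a), list(b)), abs=1e-10)
        assert res.ci_low <= res.icc <= res.ci_high


def test_icc_matches_pingouin():
    pg = pytest.importorskip("pingouin")
    import pandas as pd

    rng = np.random.default_rng(3)
    a = rng.uniform(0, 100, 20)
    b = np.clip(a + rng.normal(0, 15, 20), 0, 100)
    df = pd.DataFrame({
        "targets": np.repeat(np.arange(20), 2),
        "raters": np.tile(["A", "B"], 20),
        "scores": np.column_stack([a, b]).ravel(),
    })
    table = pg.intraclass_corr(df, targets="targets", raters="raters",
                               ratings="scores").set_index("Type")
    ref = table.loc["ICC(A,1)"] if "ICC(A,1)" in table.index else table.loc["ICC2"]
    res = icc_two_way(a, b)
    assert res.icc == pytest.approx(float(ref["ICC"]), abs=1e-9)
    ci = ref["CI95%"] if "CI95%" in ref.index else ref["CI95"]
    assert res.ci_low == pytest.approx(ci[0], abs=0.01)
    assert res.ci_high == pytest.approx(ci[1], abs=0.01)


def test_icc_near_zero_for_independent_scores():
    rng = np.random.default_rng(4)
    res = icc_two_way(rng.uniform(0, 100, 200), rng.uniform(0, 100, 200))
    assert abs(res.icc) <= 0.15


def test_icc_undefined_on_constant_input():
    res = icc_two_way([5.0] * 6, [5.0] * 6)
    assert res.icc is None


def test_icc_requires_five_pairs():
    with pytest.raises(ValueError):
        icc_two_way([1, 2], [1, 2])


# ---------------------------------------------------------------------------
# Fleiss' kappa
# ---------------------------------------------------------------------------

def test_kappa_perfect_agreement():
    a = [0.0, 10.0, 40.0, 80.0, 2.0, 60.0]
    res = kappa_at_cutoffs(a, a)
    assert set(res) == {1.0, 5.0, 10.0, 25.0, 50.0}
    for k in res.values():
        assert k == pytest.approx(1.0)


def test_kappa_systematic_disagreement_negative():
    a = np.array([0, 0, 0, 60, 60, 60], float)
    b = np.array([60, 60, 60, 0, 0, 0], float)
    res = kappa_at_cutoffs(a, b, cutoffs=[50.0])
    oracle = brute_force_fleiss((a >= 50).astype(int), (b >= 50).astype(int))
    assert res[50.0] == pytest.approx(oracle) and res[50.0] < 0


def test_kappa_matches_bruteforce_random():
    rng = np.random.default_rng(5)
    for _ in range(50):
        n = int(rng.integers(4, 13))
        a = rng.uniform(0, 100, n)
        b = rng.uniform(0, 100, n)
        for c in (1.0, 25.0, 50.0):
            ours = kappa_at_cutoffs(a, b, cutoffs=[c])[c]
            oracle = brute_force_fleiss((a >= c).astype(int), (b >= c).astype(int))
            if oracle is None:
                assert ours is None
            else:
                assert ours == pytest.approx(oracle, abs=1e-12)


def test_kappa_boundary_score_counts_positive():
    a, b = [25.0, 0.0, 30.0], [25.0, 0.0, 30.0]
    res = kappa_at_cutoffs(a, b, cutoffs=[25.0])
    # 25 at cutoff 25 dichotomizes positive for both raters -> kappa 1
    assert res[25.0] == pytest.approx(1.0)


def test_kappa_undefined_single_category():
    assert fleiss_kappa_two_raters(np.zeros(5, int), np.zeros(5, int)) is None


def test_kappa_scores_out_of_range_rejected():
    with pytest.raises(ValueError):
        kappa_at_cutoffs([101.0], [5.0])


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

def test_correlation_linear():
    x = np.array([1.0, 2, 3, 4, 5])
    p, s = correlations(x, 2 * x)
    assert p == pytest.approx(1.0) and s == pytest.approx(1.0)


def test_correlation_monotone_nonlinear():
    x = np.array([1.0, 2, 3, 4, 5])
    p, s = correlations(x, x ** 2)
    assert s == pytest.approx(1.0) and p < 1.0


def test_spearman_equals_rank_then_pearson():
    rng = np.random.default_rng(6)
    x = rng.uniform(0, 10, 12)
    y = rng.uniform(0, 10, 12)
    _, s = correlations(x, y)
    rp, _ = correlations(stats.rankdata(x), stats.rankdata(y))
    assert s == pytest.approx(rp, abs=1e-12)


def test_correlation_zero_variance_flagged():
    assert correlations([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]) == (None, None)


# ---------------------------------------------------------------------------
# IPS/TPS association
# ---------------------------------------------------------------------------

def test_chi_square_hand_example():
    """2x2 table [[30,5],[5,30]]: chi2 = sum (O-E)^2/E = 35.7143."""
    tps = [5.0] * 30 + [5.0] * 5 + [0.0] * 5 + [0.0] * 30
    ips = [5.0] * 30 + [0.0] * 5 + [5.0] * 5 + [0.0] * 30
    res = ips_tps_association(tps, ips)
    assert res.chi2 == pytest.approx(35.7143, abs=1e-3)


def test_mannwhitney_identical_groups():
    tps = [0.0] * 10 + [80.0] * 10
    ips = [30.0, 40.0] * 10
    res = ips_tps_association(tps, ips, tps_cutoffs=[50.0])
    _, p = res.mannwhitney[50.0]
    assert p == pytest.approx(1.0, abs=0.05)


def test_mannwhitney_perfect_separation_extreme_u():
    tps = [0.0] * 6 + [80.0] * 6
    ips = [1.0, 2, 3, 4, 5, 6] + [50.0, 51, 52, 53, 54, 55]
    res = ips_tps_association(tps, ips, tps_cutoffs=[50.0])
    u, p = res.mannwhitney[50.0]
    assert u == 36.0  # n1*n2: every high-TPS IPS beats every low-TPS IPS
    assert p < 0.01


def test_association_empty_group_flagged():
    res = ips_tps_association([80.0] * 6, [10.0] * 6, tps_cutoffs=[50.0])
    assert res.mannwhitney[50.0] == (None, None)


# ---------------------------------------------------------------------------
# concordance report
# ---------------------------------------------------------------------------

def test_concordance_report_truth_vs_truth():
    scores = [0.0, 5.0, 25.0, 50.0, 90.0, 3.0, 70.0]
    rep = concordance_report(scores, scores)
    assert rep.icc.icc == pytest.approx(1.0)
    assert rep.pearson == pytest.approx(1.0)
    assert all(v == pytest.approx(1.0) for v in rep.kappas.values())
    d = rep.to_dict()
    assert d["n"] == 7 and "50.0" in d["kappa"]
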