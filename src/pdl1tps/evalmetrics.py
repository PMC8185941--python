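"""Evaluation battery: detection metrics, count errors, rater concordance.

* object-level precision/recall/F1 by optimal one-to-one matching of
  predicted and ground-truth points within a match radius;
* count errors MAE / RMSE / MAPE over patches;
* ICC(2,1) — two-way random effects, absolute agreement, single measure —
  with its F-based 95% confidence interval;
* Fleiss' kappa after dichotomizing TPS at the clinically used cutoffs
  1/5/10/25/50% (score exactly at a cutoff counts as positive, matching the
  closed lower bounds of the expression bins);
* Pearson / Spearman correlations, Mann-Whitney U and chi-square
  association tests for IPS against TPS.

Statistics with no installed one-call equivalent for the exact forms fixed
here (ICC(2,1) + CI, two-rater Fleiss' kappa, optimal point matching) are
computed from their defining formulas; correlations and the U / chi-square
tests delegate to scipy.stats.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import linear_sum_assignment

from .annotio import CLASS_ORDER, CellAnnotation, CellClass
from .cnet import Detection

_BIG = 1e9  # forbidden-pair cost in the assignment problem


# ---------------------------------------------------------------------------
# object-level detection metrics
# ---------------------------------------------------------------------------

@dataclass
class ClassF1:
    precision: float
    recall: float
    f1: float
    tp: int
    fp: int
    fn: int


@dataclass
class DetectionEvalResult:
    per_class: dict[CellClass, ClassF1]
    precision: float  # macro average over evaluated classes
    recall: float
    f1: float


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f


def match_points(pred_xy: np.ndarray, truth_xy: np.ndarray,
                 match_radius: float) -> list[tuple[int, int]]:
    """Optimal one-to-one matching within ``match_radius``.

    Maximum-cardinality matching with minimum total distance among maximum
    matchings, via the Hungarian algorithm with a large penalty on
    out-of-radius pairs.
    """
    if len(pred_xy) == 0 or len(truth_xy) == 0:
        return []
    d = np.sqrt(((pred_xy[:, None, :] - truth_xy[None, :, :]) ** 2).sum(-1))
    cost = np.where(d <= match_radius, d, _BIG)
    rows, cols = linear_sum_assignment(cost)
    return [(int(i), int(j)) for i, j in zip(rows, cols) if d[i, j] <= match_radius]


def object_f1(pred: Sequence[Detection], truth: Sequence[CellAnnotation],
              match_radius: float,
              classes: Sequence[CellClass] | None = None) -> DetectionEvalResult:
    """Per-class and macro-averaged object-level precision/recall/F1.

    Matched prediction-truth pairs (same class, within ``match_radius``)
    are true positives; unmatched predictions are false positives and
    unmatched truths false negatives.  The macro average runs over the
    classes that occur in either list (or over ``classes`` when given).
    """
    if match_radius <= 0:
        raise ValueError("match_radius must be > 0")
    per_class: dict[CellClass, ClassF1] = {}
    if classes is None:
        classes = [c for c in CLASS_ORDER
                   if any(d.cls is c for d in pred) or any(a.cls is c for a in truth)]
    for c in classes:
        p_xy = np.array([[d.x, d.y] for d in pred if d.cls is c], dtype=float).reshape(-1, 2)
        t_xy = np.array([[a.x, a.y] for a in truth if a.cls is c], dtype=float).reshape(-1, 2)
        tp = len(match_points(p_xy, t_xy, match_radius))
        fp = len(p_xy) - tp
        fn = len(t_xy) - tp
        pr, rc, f1 = _prf(tp, fp, fn)
        per_class[c] = ClassF1(pr, rc, f1, tp, fp, fn)
    if per_class:
        avg = [np.mean([getattr(v, k) for v in per_class.values()])
               for k in ("precision", "recall", "f1")]
    else:
        avg = [0.0, 0.0, 0.0]
    return DetectionEvalResult(per_class=per_class, precision=float(avg[0]),
                               recall=float(avg[1]), f1=float(avg[2]))


# ---------------------------------------------------------------------------
# count errors
# ---------------------------------------------------------------------------

@dataclass
class CountErrorResult:
    mae: float
    rmse: float
    mape: float | None  # None when no patch has a nonzero truth count


def count_errors(pred_counts: Sequence[float],
                 truth_counts: Sequence[float]) -> CountErrorResult:
    """MAE, RMSE and MAPE of per-patch counts.

    MAPE averages ``100 * |pred - truth| / truth`` over patches with a
    nonzero truth count only; those patches still contribute to MAE/RMSE.
    """
    p = np.asarray(pred_counts, dtype=float)
    t = np.asarray(truth_counts, dtype=float)
    if p.shape != t.shape:
        raise ValueError("paired count vectors must have equal length")
    d = p - t
    mae = float(np.abs(d).mean())
    rmse = float(np.sqrt((d ** 2).mean()))
    nz = t > 0
    mape = float((100.0 * np.abs(d[nz]) / t[nz]).mean()) if nz.any() else None
    return CountErrorResult(mae=mae, rmse=rmse, mape=mape)


# ---------------------------------------------------------------------------
# ICC(2,1)
# ---------------------------------------------------------------------------

@dataclass
class ICCResult:
    icc: float | None
    ci_low: float | None
    ci_high: float | None
    n: int


def icc_two_way(scores_a: Sequence[float], scores_b: Sequence[float],
                alpha: float = 0.05) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    Computed from the mean squares of the two-way (subjects x raters)
    layout; the 95% CI follows the standard F-based interval (McGraw &
    Wong).  Returns an undefined flag when both raters are constant.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("scores must be paired 1-d vectors")
    n = len(a)
    if n < 5:
        raise ValueError("need at least 5 paired scores")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return ICCResult(None, None, None, n)

    x = np.stack([a, b], axis=1)  # n subjects x k raters
    k = 2
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)          # between-subject
    msc = ss_cols / (k - 1)          # between-rater
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        return ICCResult(None, None, None, n)
    icc = (msr - mse) / denom

    # F-based CI (McGraw & Wong 1996), as used for ICC(A,1)
    if mse > 0:
        fj = msc / mse
        vn = (k - 1) * (n - 1) * (k * icc * fj + n * (1 + (k - 1) * icc) - k * icc) ** 2
        vd = ((n - 1) * k ** 2 * icc ** 2 * fj ** 2
              + (n * (1 + (k - 1) * icc) - k * icc) ** 2)
        v = vn / vd
        f_upper = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_lower = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lb = n * (msr - f_upper * mse) / (
            f_upper * (k * msc + (k * n - k - n) * mse) + n * msr)
        ub = n * (f_lower * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_lower * msr)
        lb, ub = float(np.clip(lb, -1, 1)), float(np.clip(ub, -1, 1))
    else:
        lb = ub = float(icc)
    return ICCResult(icc=float(icc), ci_low=min(lb, float(icc)),
                     ci_high=max(ub, float(icc)), n=n)


# ---------------------------------------------------------------------------
# Fleiss' kappa at TPS cutoffs
# ---------------------------------------------------------------------------

DEFAULT_CUTOFFS = (1.0, 5.0, 10.0, 25.0, 50.0)


def fleiss_kappa_two_raters(cat_a: np.ndarray, cat_b: np.ndarray) -> float | None:
    """Fleiss' kappa for two raters assigning n subjects to 2 categories.

    Follows Fleiss' multi-rater definition with k = 2 ratings per subject.
    Undefined (None) when every rating falls in a single category.
    """
    cat_a = np.asarray(cat_a).astype(int)
    cat_b = np.asarray(cat_b).astype(int)
    n = len(cat_a)
    k = 2  # ratings per subject
    # n_ij: ratings of subject i in category j, categories {0, 1}
    n_i1 = cat_a + cat_b
    n_i0 = k - n_i1
    p0 = n_i0.sum() / (n * k)
    p1 = n_i1.sum() / (n * k)
    pe = p0 ** 2 + p1 ** 2
    if pe == 1.0:
        return None
    p_i = (n_i0 * (n_i0 - 1) + n_i1 * (n_i1 - 1)) / (k * (k - 1))
    pbar = p_i.mean()
    return float((pbar - pe) / (1.0 - pe))


def kappa_at_cutoffs(scores_a: Sequence[float], scores_b: Sequence[float],
                     cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
                     ) -> dict[float, float | None]:
    """Fleiss' kappa per TPS cutoff after dichotomizing at ``score >= cutoff``.

    A score exactly at the cutoff counts as positive, consistent with the
    closed lower bounds of the expression bins.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if ((a < 0) | (a > 100) | (b < 0) | (b > 100)).any():
        raise ValueError("scores must lie in [0, 100]")
    return {float(c): fleiss_kappa_two_raters(a >= c, b >= c) for c in cutoffs}


# ---------------------------------------------------------------------------
# correlations and association tests
# ---------------------------------------------------------------------------

def correlations(x: Sequence[float], y: Sequence[float]) -> tuple[float | None, float | None]:
    """(Pearson, Spearman) with average ranks for ties; None on zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None, None
    pearson = float(stats.pearsonr(x, y).statistic)
    spearman = float(stats.spearmanr(x, y).statistic)
    return pearson, spearman


@dataclass
class AssociationResult:
    mannwhitney: dict[float, tuple[float | None, float | None]]  # cutoff -> (U, p)
    chi2: float | None
    chi2_p: float | None
    pearson: float | None
    spearman: float | None


def ips_tps_association(tps: Sequence[float], ips: Sequence[float],
                        tps_cutoffs: Sequence[float] = (1.0, 25.0, 50.0),
                        ips_cutoff: float = 1.0) -> AssociationResult:
    """Association between IPS and TPS.

    Per TPS cutoff, a Mann-Whitney U test (normal approximation with tie
    correction, no continuity correction) compares IPS between TPS-high and
    TPS-low cases; a chi-square test without continuity correction is run
    on the 2x2 table at the simultaneous 1% TPS/IPS cutoffs.
    """
    t = np.asarray(tps, dtype=float)
    s = np.asarray(ips, dtype=float)
    if t.shape != s.shape:
        raise ValueError("paired vectors required")
    mw: dict[float, tuple[float | None, float | None]] = {}
    for c in tps_cutoffs:
        hi, lo = s[t >= c], s[t < c]
        if len(hi) == 0 or len(lo) == 0:
            mw[float(c)] = (None, None)
            continue
        res = stats.mannwhitneyu(hi, lo, alternative="two-sided",
                                 method="asymptotic", use_continuity=False)
        mw[float(c)] = (float(res.statistic), float(res.pvalue))

    table = np.array([
        [np.sum((t >= 1.0) & (s >= ips_cutoff)), np.sum((t >= 1.0) & (s < ips_cutoff))],
        [np.sum((t < 1.0) & (s >= ips_cutoff)), np.sum((t < 1.0) & (s < ips_cutoff))],
    ])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        chi2 = chi2_p = None
    else:
        res = stats.chi2_contingency(table, correction=False)
        chi2, chi2_p = float(res.statistic), float(res.pvalue)
    pearson, spearman = correlations(t, s) if len(t) >= 3 else (None, None)
    return AssociationResult(mannwhitney=mw, chi2=chi2, chi2_p=chi2_p,
                             pearson=pearson, spearman=spearman)


# ---------------------------------------------------------------------------
# concordance report
# ---------------------------------------------------------------------------

@dataclass
class ConcordanceReport:
    icc: ICCResult
    kappas: Mapping[float, float | None]
    pearson: float | None
    spearman: float | None
    n: int

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "icc": self.icc.icc,
            "icc_ci": [self.icc.ci_low, self.icc.ci_high],
            "pearson": self.pearson,
            "spearman": self.spearman,
            "kappa": {str(k): v for k, v in self.kappas.items()},
        }


def concordance_report(scores_a: Sequence[float], scores_b: Sequence[float],
                       cutoffs: Sequence[float] = DEFAULT_CUTOFFS) -> ConcordanceReport:
    """Full two-rater concordance: ICC(2,1) + CI, per-cutoff Fleiss' kappa,
    Pearson and Spearman correlations."""
    icc = icc_two_way(scores_a, scores_b)
    kappas = kappa_at_cutoffs(scores_a, scores_b, cutoffs)
    pearson, spearman = correlations(scores_a, scores_b)
    return ConcordanceReport(icc=icc, kappas=kappas, pearson=pearson,
                             spearman=spearman, n=len(list(scores_a)))
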