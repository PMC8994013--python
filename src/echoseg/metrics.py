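"""Segmentation overlap scores and paired-measurement agreement statistics.

Overlap: Dice (DSC), Jaccard (JSC), precision and recall between binary
masks.  Agreement between predicted and reference clinical parameters:
RMSE, MAE, R^2 (1 - SS_res/SS_tot), two-item Cronbach's alpha, Pearson
correlation, and Bland-Altman limits of agreement (mean difference
+/- 1.96 sample SD).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

__all__ = [
    "SegScores",
    "AgreementReport",
    "seg_scores",
    "regression_metrics",
    "cronbach_alpha",
    "bland_altman",
    "pearson",
    "agreement_report",
]


@dataclass(frozen=True)
class SegScores:
    dsc: float
    jsc: float
    precision: float
    recall: float

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class AgreementReport:
    rmse: float
    mae: float
    r_squared: float
    cronbach_alpha: float
    pearson_r: float
    ba_mean_diff: float
    ba_lower: float
    ba_upper: float
    ba_width: float

    def as_dict(self) -> dict:
        return asdict(self)


def seg_scores(pred_mask: np.ndarray, gt_mask: np.ndarray) -> SegScores:
    """Overlap scores with A = prediction, B = ground truth.

    DSC = 2|A∩B|/(|A|+|B|), JSC = |A∩B|/|A∪B|, precision = |A∩B|/|A|,
    recall = |A∩B|/|B|.  Two empty masks agree perfectly (all scores 1);
    one-sided empties score 0 on the affected ratios.
    """
    a = np.asarray(pred_mask).astype(bool)
    b = np.asarray(gt_mask).astype(bool)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    na, nb = a.sum(), b.sum()
    if na == 0 and nb == 0:
        return SegScores(1.0, 1.0, 1.0, 1.0)
    inter = np.logical_and(a, b).sum()
    union = np.logical_or(a, b).sum()
    dsc = 2.0 * inter / (na + nb)
    jsc = inter / union
    precision = inter / na if na else 0.0
    recall = inter / nb if nb else 0.0
    return SegScores(float(dsc), float(jsc), float(precision), float(recall))


def regression_metrics(pred_values, true_values) -> tuple[float, float, float]:
    """(RMSE, MAE, R^2) of predictions against reference values.

    R^2 = 1 - SS_res/SS_tot; with constant reference values SS_tot = 0 and
    R^2 is reported as NaN.
    """
    p = np.asarray(pred_values, dtype=float)
    t = np.asarray(true_values, dtype=float)
    if p.shape != t.shape or p.size < 2:
        raise ValueError("need two equal-length arrays with n >= 2")
    err = p - t
    rmse = float(np.sqrt(np.mean(err ** 2)))
    mae = float(np.mean(np.abs(err)))
    ss_tot = float(np.sum((t - t.mean()) ** 2))
    if ss_tot == 0:
        warnings.warn("constant reference values: R^2 undefined")
        r2 = float("nan")
    else:
        r2 = float(1.0 - np.sum(err ** 2) / ss_tot)
    return rmse, mae, r2


def cronbach_alpha(x, y) -> float:
    """Two-item Cronbach's alpha with sample variances.

    alpha = (k/(k-1)) * (1 - (var(x)+var(y)) / var(x+y)) with k = 2.
    Undefined (NaN) when the summed scores have zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two equal-length arrays with n >= 2")
    var_sum = np.var(x + y, ddof=1)
    if var_sum == 0:
        warnings.warn("zero total variance: Cronbach's alpha undefined")
        return float("nan")
    return float(2.0 * (1.0 - (np.var(x, ddof=1) + np.var(y, ddof=1)) / var_sum))


def bland_altman(x, y) -> tuple[float, float, float, float]:
    """(mean_diff, lower, upper, width) of the Bland-Altman limits of agreement.

    d = x - y; limits = mean(d) +/- 1.96 * sd(d) (sample SD); width is the
    distance between the limits.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two equal-length arrays with n >= 2")
    d = x - y
    mean_diff = float(d.mean())
    sd = float(d.std(ddof=1))
    lower = mean_diff - 1.96 * sd
    upper = mean_diff + 1.96 * sd
    return mean_diff, lower, upper, upper - lower


def pearson(x, y) -> float:
    """Sample Pearson correlation; NaN (with a warning) for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two equal-length arrays with n >= 2")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant input: Pearson correlation undefined")
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def agreement_report(pred_values, true_values) -> AgreementReport:
    """All paired-measurement statistics in one report (pred vs reference)."""
    rmse, mae, r2 = regression_metrics(pred_values, true_values)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        alpha = cronbach_alpha(pred_values, true_values)
        r = pearson(pred_values, true_values)
    mean_diff, lower, upper, width = bland_altman(pred_values, true_values)
    return AgreementReport(rmse=rmse, mae=mae, r_squared=r2, cronbach_alpha=alpha,
                           pearson_r=r, ba_mean_diff=mean_diff, ba_lower=lower,
                           ba_upper=upper, ba_width=width)
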