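"""Evaluation statistics for detections, trait estimates and trials.

Covers IOU-matched detection counts (TP/FP/FN at the usual 0.5 threshold),
precision/recall/bias, estimate-vs-reference regression with relative RMSE,
leave-one-out cross-validated linear models, and broad-sense heritability
H² = Vg / (Vg + Ve) from a one-way random-effects ANOVA.

Bias convention
---------------
The bias statistic summarizes the precision/recall imbalance and is zero when
they are equal. Two algebraic variants circulate: 1 − recall/precision and
1 − precision/recall. The default here is ``1 − recall/precision``, which is
negative when recall exceeds precision (over-detection leaning); the opposite
convention is available via ``formula="text"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .geometry import Box, Detection, iou

__all__ = [
    "EvalCounts",
    "DetectionMetrics",
    "RegressionMetrics",
    "VarianceComponents",
    "match_detections",
    "detection_metrics",
    "detection_bias",
    "regression_metrics",
    "relative_rmse",
    "summarize",
    "loocv_regression",
    "heritability",
]


@dataclass(frozen=True)
class EvalCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class DetectionMetrics:
    precision: float
    recall: float
    bias: float


@dataclass(frozen=True)
class RegressionMetrics:
    slope: float
    intercept: float
    r2: float
    rmse: float  # units of the response
    rrmse: float  # percent of the reference mean


@dataclass(frozen=True)
class VarianceComponents:
    vg: float  # genotypic variance
    ve: float  # residual (environmental) variance
    h2: float  # broad-sense heritability in [0, 1]


def match_detections(pred: list[Detection], truth: list[Box],
                     iou_threshold: float = 0.5) -> EvalCounts:
    """Greedy one-to-one matching of detections to labeled boxes.

    Detections are visited in descending score order (position-lexicographic
    on ties); each is matched to the unmatched truth box of highest IOU,
    provided that IOU is strictly larger than the threshold. Unmatched
    detections count as false positives, unmatched truths as false negatives.
    """
    order = sorted(range(len(pred)),
                   key=lambda i: (-pred[i].score, pred[i].box.as_tuple()))
    unmatched = set(range(len(truth)))
    tp = 0
    for i in order:
        best_j, best_iou = None, iou_threshold
        for j in unmatched:
            v = iou(pred[i].box, truth[j])
            if v > best_iou:
                best_j, best_iou = j, v
        if best_j is not None:
            unmatched.discard(best_j)
            tp += 1
    return EvalCounts(tp=tp, fp=len(pred) - tp, fn=len(unmatched))


def detection_bias(precision: float, recall: float, formula: str = "table") -> float:
    """Precision/recall imbalance; 0 iff precision == recall.

    ``formula="table"`` (default): 1 − recall/precision.
    ``formula="text"``: 1 − precision/recall.
    """
    if precision <= 0 or recall <= 0:
        raise ValueError("precision and recall must be > 0 for bias")
    if formula == "table":
        return 1.0 - recall / precision
    if formula == "text":
        return 1.0 - precision / recall
    raise ValueError(f"unknown bias formula {formula!r}")


def detection_metrics(c: EvalCounts, bias_formula: str = "table") -> DetectionMetrics:
    """Precision = TP/(TP+FP), recall = TP/(TP+FN), and their bias."""
    if c.tp + c.fp == 0:
        raise ValueError("precision undefined: TP + FP = 0")
    if c.tp + c.fn == 0:
        raise ValueError("recall undefined: TP + FN = 0")
    precision = c.tp / (c.tp + c.fp)
    recall = c.tp / (c.tp + c.fn)
    return DetectionMetrics(precision, recall,
                            detection_bias(precision, recall, bias_formula))


def relative_rmse(rmse: float, reference_mean: float) -> float:
    """RRMSE in percent: 100 * RMSE / mean of the reference values."""
    if reference_mean == 0:
        raise ValueError("reference mean is zero: RRMSE undefined")
    return 100.0 * rmse / reference_mean


def regression_metrics(estimated, reference) -> RegressionMetrics:
    """Agreement between estimated and reference values.

    Slope, intercept and R² come from the ordinary least-squares fit of the
    reference on the estimate; RMSE is the root mean squared difference
    between the two, and RRMSE expresses it as a percentage of the mean of
    the reference values.
    """
    x = np.asarray(estimated, dtype=float)
    y = np.asarray(reference, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if y.mean() == 0:
        raise ValueError("reference mean is zero: RRMSE undefined")
    fit = sps.linregress(x, y)
    rmse = float(np.sqrt(np.mean((x - y) ** 2)))
    return RegressionMetrics(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        rmse=rmse,
        rrmse=relative_rmse(rmse, float(y.mean())),
    )


def summarize(values) -> dict:
    """Min, mean, max, range, SD (n−1) and CV % of a sample."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    sd = float(v.std(ddof=1))
    mean = float(v.mean())
    return {
        "min": float(v.min()),
        "mean": mean,
        "max": float(v.max()),
        "range": float(v.max() - v.min()),
        "sd": sd,
        "cv": 100.0 * sd / mean,
    }


def loocv_regression(predictors, response, model: str = "single") -> RegressionMetrics:
    """Leave-one-out cross-validated linear regression of a response on traits.

    For each plot, an ordinary linear model (with intercept) is fitted on the
    remaining plots and used to predict the held-out response. Fold
    predictions are pooled and summarized once: predictive R²
    (1 − SS_res/SS_tot of the pooled out-of-fold predictions, which is ~0 or
    slightly negative for a skill-less model), RMSE of the prediction errors,
    RRMSE relative to the mean observed response. ``model="single"`` expects
    one predictor column; ``model="all"`` uses every column jointly in a
    multiple regression.
    """
    X = np.atleast_2d(np.asarray(predictors, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1:
        X = X.T
    y = np.asarray(response, dtype=float)
    n = y.size
    if X.shape[0] != n:
        raise ValueError("predictors and response lengths differ")
    if n < 5:
        raise ValueError("need at least 5 plots for leave-one-out")
    if model == "single" and X.shape[1] != 1:
        raise ValueError("model='single' expects exactly one predictor column")
    A = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise ValueError("rank-deficient predictor table")
    preds = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        coef, *_ = np.linalg.lstsq(A[keep], y[keep], rcond=None)
        preds[i] = A[i] @ coef
    base = regression_metrics(preds, y)
    ss_res = float(np.sum((y - preds) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return RegressionMetrics(
        slope=base.slope,
        intercept=base.intercept,
        r2=1.0 - ss_res / ss_tot,
        rmse=base.rmse,
        rrmse=base.rrmse,
    )


def heritability(genotype_ids, values) -> VarianceComponents:
    """Broad-sense heritability from replicated plot values.

    One-way random-effects ANOVA on genotype: Ve is the within-genotype mean
    square; Vg = (between MS − within MS) / r̄ with r̄ the harmonic mean of
    the replicate counts (handles unbalanced replication), clipped at zero;
    H² = Vg / (Vg + Ve).
    """
    ids = np.asarray(genotype_ids)
    y = np.asarray(values, dtype=float)
    if ids.shape != y.shape:
        raise ValueError("genotype_ids and values lengths differ")
    groups = [y[ids == g] for g in np.unique(ids)]
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 genotypes")
    sizes = np.array([len(g) for g in groups], dtype=float)
    if np.all(sizes < 2):
        raise ValueError("need replicated genotypes")
    n = sizes.sum()
    grand = y.mean()
    ss_between = float(sum(m * (g.mean() - grand) ** 2 for m, g in zip(sizes, groups)))
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    ms_between = ss_between / (k - 1)
    ms_within = ss_within / (n - k)
    r_bar = k / np.sum(1.0 / sizes)  # harmonic mean replicate count
    vg = max(0.0, (ms_between - ms_within) / r_bar)
    ve = ms_within
    h2 = vg / (vg + ve) if (vg + ve) > 0 else 0.0
    return VarianceComponents(vg=vg, ve=ve, h2=h2)
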