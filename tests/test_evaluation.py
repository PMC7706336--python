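"""Detection matching, precision/recall/bias, regression metrics, LOOCV, H²."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from stemscan.evaluation import (
    EvalCounts,
    detection_bias,
    detection_metrics,
    heritability,
    loocv_regression,
    match_detections,
    regression_metrics,
    summarize,
)
from stemscan.geometry import Box, Detection, iou


def det(x0, y0, x1, y1, score=0.9):
    return Detection(box=Box(x0, y0, x1, y1), score=score)


def optimal_tp(pred, truth, threshold=0.5):
    """Maximum one-to-one matching with IOU > threshold (assignment oracle)."""
    if not pred or not truth:
        return 0
    w = np.zeros((len(pred), len(truth)))
    for i, p in enumerate(pred):
        for j, t in enumerate(truth):
            w[i, j] = 1.0 if iou(p.box, t) > threshold else 0.0
    ri, cj = linear_sum_assignment(-w)
    return int(w[ri, cj].sum())


class TestMatchDetections:
    def test_perfect_predictions(self):
        truth = [Box(i * 20, 0, i * 20 + 10, 10) for i in range(5)]
        pred = [Detection(box=b, score=0.9) for b in truth]
        c = match_detections(pred, truth)
        assert (c.tp, c.fp, c.fn) == (5, 0, 0)

    def test_one_detection_cannot_match_two_truths(self):
        truth = [Box(0, 0, 10, 10), Box(4, 0, 14, 10)]
        pred = [det(1, 0, 11, 10)]
        c = match_detections(pred, truth)
        assert (c.tp, c.fp, c.fn) == (1, 0, 1)

    def test_threshold_is_strict(self):
        # IOU exactly 0.5 does not match.
        truth = [Box(0, 0, 10, 10)]
        c = match_detections([det(0, 0, 10, 5)], truth)  # IOU = 0.5
        assert (c.tp, c.fp, c.fn) == (0, 1, 1)

    def test_greedy_never_beats_assignment_oracle(self, rng):
        for _ in range(150):
            n_p, n_t = rng.integers(0, 9), rng.integers(1, 9)
            pred = [det(x, y, x + 10, y + 10, float(rng.uniform(0.8, 1.0)))
                    for x, y in rng.uniform(0, 40, size=(n_p, 2))]
            truth = [Box(x, y, x + 10, y + 10)
                     for x, y in rng.uniform(0, 40, size=(n_t, 2))]
            c = match_detections(pred, truth)
            assert c.tp <= optimal_tp(pred, truth)
            assert c.tp + c.fp == len(pred)
            assert c.tp + c.fn == len(truth)

    def test_greedy_equals_oracle_on_unambiguous_scenes(self, rng):
        # Well-separated clusters: each prediction overlaps at most one truth,
        # where greedy matching is provably optimal.
        for _ in range(60):
            n = int(rng.integers(1, 9))
            truth, pred = [], []
            for k in range(n):
                x, y = 40.0 * k, 0.0
                truth.append(Box(x, y, x + 10, y + 10))
                if rng.uniform() < 0.8:  # some truths stay unmatched
                    dx, dy = rng.uniform(-2, 2, 2)
                    pred.append(det(x + dx, y + dy, x + dx + 10, y + dy + 10,
                                    float(rng.uniform(0.8, 1.0))))
            c = match_detections(pred, truth)
            assert c.tp == optimal_tp(pred, truth)


class TestDetectionMetrics:
    def test_counts_to_precision_recall(self):
        m = detection_metrics(EvalCounts(9, 1, 0))
        assert (m.precision, m.recall) == (0.9, 1.0)

    @pytest.mark.parametrize(
        "precision,recall,expected",
        # Every published-style precision/recall pair must reproduce its
        # bias at 2 decimals under the 1 - recall/precision convention.
        [(0.95, 0.97, -0.02), (0.91, 0.93, -0.02), (0.92, 0.94, -0.02),
         (0.92, 0.95, -0.03), (0.96, 0.95, 0.01), (0.94, 0.95, -0.01),
         (0.95, 0.95, 0.00)],
    )
    def test_bias_table_convention(self, precision, recall, expected):
        assert round(detection_bias(precision, recall), 2) == pytest.approx(expected)

    def test_bias_sign_follows_imbalance(self):
        assert detection_bias(0.9, 0.95) < 0  # recall > precision
        assert detection_bias(0.95, 0.9) > 0
        assert detection_bias(0.9, 0.9) == 0.0

    def test_text_variant_flips_the_ratio(self):
        assert detection_bias(0.95, 0.97, formula="text") == pytest.approx(
            1 - 0.95 / 0.97
        )

    def test_empty_denominator_raises(self):
        with pytest.raises(ValueError, match="TP \\+ FP"):
            detection_metrics(EvalCounts(0, 0, 3))


class TestRegressionMetrics:
    def test_perfect_agreement(self, rng):
        x = rng.uniform(100, 600, 20)
        m = regression_metrics(x, x)
        assert m.slope == pytest.approx(1.0)
        assert m.intercept == pytest.approx(0.0, abs=1e-9)
        assert m.r2 == pytest.approx(1.0)
        assert m.rmse == pytest.approx(0.0, abs=1e-9)

    def test_rrmse_is_rmse_over_reference_mean(self, rng):
        ref = rng.uniform(300, 400, 30)
        est = ref + rng.normal(0, 25, 30)
        m = regression_metrics(est, ref)
        assert m.rrmse == pytest.approx(100 * m.rmse / ref.mean())

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            regression_metrics([1, 2, 3], [1, 2])


class TestSummarize:
    def test_moments_and_cv(self, rng):
        v = rng.normal(500, 100, 200)
        s = summarize(v)
        assert s["range"] == pytest.approx(s["max"] - s["min"])
        assert s["sd"] == pytest.approx(np.std(v, ddof=1))
        assert s["cv"] == pytest.approx(100 * s["sd"] / s["mean"])

    def test_constant_vector(self):
        s = summarize([5.0, 5.0, 5.0])
        assert s["sd"] == s["cv"] == s["range"] == 0.0

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            summarize([1.0])


class TestLoocv:
    def test_exact_linear_relation(self, rng):
        x = rng.uniform(0, 1, 20)
        y = 3.0 * x + 2.0
        m = loocv_regression(x.reshape(-1, 1), y)
        assert m.r2 == pytest.approx(1.0)
        assert m.rmse == pytest.approx(0.0, abs=1e-9)

    def test_independent_response_has_no_skill(self, rng):
        x = rng.uniform(0, 1, 37)
        y = rng.normal(10.0, 1.0, 37)
        m = loocv_regression(x.reshape(-1, 1), y)
        # Predictive R² of a skill-less model hovers around zero (it may dip
        # slightly negative); predictions stay near the training mean.
        assert -0.5 < m.r2 < 0.2
        assert np.all(np.abs(m.rmse - 1.0) < 0.6)

    def test_rank_deficient_rejected(self, rng):
        x = rng.uniform(0, 1, 10)
        X = np.column_stack([x, 2 * x])
        with pytest.raises(ValueError, match="rank"):
            loocv_regression(X, x, model="all")

    def test_single_model_requires_one_column(self, rng):
        X = rng.uniform(0, 1, (10, 2))
        with pytest.raises(ValueError):
            loocv_regression(X, X[:, 0], model="single")


class TestHeritability:
    def test_pure_genotypic_signal(self):
        ids = np.repeat(["a", "b", "c"], 4)
        vals = np.repeat([1.0, 2.0, 3.0], 4)
        assert heritability(ids, vals).h2 == pytest.approx(1.0)

    def test_pure_noise_clips_to_small_h2(self, rng):
        ids = np.repeat([f"g{i}" for i in range(10)], 6)
        vals = rng.normal(0, 1, ids.size)
        vc = heritability(ids, vals)
        assert 0.0 <= vc.h2 < 0.5
        assert vc.vg >= 0.0

    def test_location_and_scale_behaviour(self, rng):
        ids = np.repeat([f"g{i}" for i in range(8)], 5)
        g = np.repeat(rng.normal(0, 2, 8), 5)
        vals = 10 + g + rng.normal(0, 1, ids.size)
        base = heritability(ids, vals).h2
        assert heritability(ids, vals + 100.0).h2 == pytest.approx(base)
        assert heritability(ids, 3.0 * vals).h2 == pytest.approx(base)

    def test_single_genotype_rejected(self):
        with pytest.raises(ValueError):
            heritability(["a"] * 5, np.arange(5.0))
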