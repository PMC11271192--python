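"""AUROC, Youden thresholding and the MetSCORE sigmoid calibration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.base import clone

from metscore.scoring import (MetScoreCalibrator, ScoreCalibration,
                              calibrate_metscore, evaluate_against_factor,
                              roc_auc, youden_threshold)


def auroc_bruteforce(scores, labels):
    """Pair counting: concordant pairs + half ties over all pos-neg pairs."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    pos, neg = s[y == 1], s[y == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


def youden_bruteforce(scores, labels):
    """Exhaustive sweep over every midpoint between distinct scores."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    u = np.unique(s)
    cands = np.concatenate([[u[0] - 1.0], (u[:-1] + u[1:]) / 2.0,
                            [u[-1] + 1.0]]) if u.size > 1 else u
    best_t, best_j = None, -np.inf
    for t in cands:
        sens = (s[y == 1] > t).mean()
        spec = (s[y == 0] <= t).mean()
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_t, best_j = t, j
    return best_t, best_j


class TestRocAuc:
    def test_separable_and_hand_examples(self):
        assert roc_auc([1, 2, 3, 4], [0, 0, 1, 1])[0] == 1.0
        # 3 of 4 positive-negative pairs concordant
        assert roc_auc([1, 3, 2, 4], [0, 0, 1, 1])[0] == 0.75

    def test_tie_counts_half_a_pair(self):
        # pairs: (2,1)=1, (2,3)=0, (4,1)=1, (4,3)=1 -> without tie 0.75;
        # replacing the losing pair with a tie adds half a pair
        assert roc_auc([1, 2, 2, 4], [0, 0, 1, 1])[0] == 0.875

    def test_matches_bruteforce_pair_counting(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = int(rng.integers(4, 31))
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                y[0], y[1] = 0, 1
            s = rng.integers(0, 6, n).astype(float)  # integer scores force ties
            assert roc_auc(s, y)[0] == pytest.approx(
                auroc_bruteforce(s, y), abs=1e-12)

    def test_label_flip_complements_auc(self):
        rng = np.random.default_rng(1)
        s = rng.normal(size=100)
        y = rng.integers(0, 2, 100)
        assert roc_auc(s, y)[0] + roc_auc(s, 1 - y)[0] == pytest.approx(1.0)

    def test_ci_contains_point_estimate_and_single_class_rejected(self):
        rng = np.random.default_rng(2)
        s = np.concatenate([rng.normal(0, 1, 200), rng.normal(1, 1, 200)])
        y = np.repeat([0, 1], 200)
        auc, (lo, hi) = roc_auc(s, y)
        assert lo <= auc <= hi and 0.0 <= lo and hi <= 1.0
        with pytest.raises(ValueError, match="two classes"):
            roc_auc([1.0, 2.0], [1, 1])


class TestYouden:
    def test_perfect_separation(self):
        t, sens, spec = youden_threshold([1, 2, 10, 11], [0, 0, 1, 1])
        assert 2 < t <= 10
        assert sens == 1.0 and spec == 1.0

    def test_hand_example_tie_broken_to_smallest_threshold(self):
        t, sens, spec = youden_threshold([1, 3, 2, 4], [0, 0, 1, 1])
        assert 1 < t <= 2  # J = 0.5 also achievable in (3, 4]
        assert sens + spec - 1 == pytest.approx(0.5)

    def test_matches_exhaustive_sweep(self):
        rng = np.random.default_rng(3)
        for _ in range(300):
            n = int(rng.integers(6, 40))
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                y[0], y[1] = 0, 1
            s = np.round(rng.normal(size=n) + y, 1)
            t, sens, spec = youden_threshold(s, y)
            bt, bj = youden_bruteforce(s, y)
            assert sens + spec - 1 == pytest.approx(bj, abs=1e-12)
            assert t == pytest.approx(bt, abs=1e-12)

    def test_independent_scores_give_near_zero_j(self):
        rng = np.random.default_rng(4)
        s = rng.normal(size=5000)
        y = rng.integers(0, 2, 5000)
        _, sens, spec = youden_threshold(s, y)
        assert sens + spec - 1 < 0.08


class TestCalibration:
    def make(self, seed=5, n=600, shift=2.0):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, n)
        t = rng.normal(size=n) + shift * y
        return t, y

    def test_score_is_half_at_threshold_exactly(self):
        t, y = self.make()
        cal = calibrate_metscore(t, y)
        assert cal.metscore(cal.threshold) == pytest.approx(0.5, abs=1e-12)

    def test_strictly_increasing_and_bounded(self):
        t, y = self.make()
        cal = calibrate_metscore(t, y)
        # strict monotonicity over the representable sigmoid range
        # (beyond ~700/slope the float64 sigmoid saturates exactly)
        grid = cal.threshold + np.linspace(-30, 30, 2001) / cal.slope
        vals = cal.metscore(grid)
        assert np.all(np.diff(vals) > 0)
        assert vals.min() > 0.0 and vals.max() < 1.0
        assert cal.metscore(1e6) == pytest.approx(1.0, abs=1e-6)
        assert cal.metscore(-1e6) == pytest.approx(0.0, abs=1e-6)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(min_value=-1e6, max_value=1e6,
                     allow_nan=False, allow_infinity=False))
    def test_any_finite_input_stays_inside_unit_interval(self, x):
        cal = ScoreCalibration(threshold=0.3, slope=2.0, intercept=-0.6)
        v = float(cal.metscore(x))
        assert 0.0 <= v <= 1.0
        if abs(cal.slope * x + cal.intercept) < 30:  # away from saturation
            assert 0.0 < v < 1.0
            assert cal.metscore(x + 1.0) > v

    def test_balanced_symmetric_case_needs_little_recentering(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(6)
        n = 4000
        y = np.repeat([0, 1], n // 2)
        t = np.where(y == 1, 1.0, -1.0) + rng.normal(size=n)
        cal = calibrate_metscore(t, y)
        w = np.where(y == 1, n / (2 * y.sum()), n / (2 * (n - y.sum())))
        fitted = sm.GLM(y, sm.add_constant(t),
                        family=sm.families.Binomial(), var_weights=w).fit()
        from scipy.special import expit
        uncentered_at_thr = expit(fitted.params[1] * cal.threshold
                                  + fitted.params[0])
        assert abs(uncentered_at_thr - 0.5) < 0.1

    def test_anti_predictive_score_rejected(self):
        t, y = self.make(shift=-2.0)
        with pytest.raises(ValueError, match="anti-predictive"):
            calibrate_metscore(t, y)

    def test_nonpositive_slope_rejected_by_type(self):
        with pytest.raises(ValueError, match="positive"):
            ScoreCalibration(threshold=0.0, slope=-1.0, intercept=0.0)

    def test_perfectly_separated_scores_still_calibrate(self):
        y = np.repeat([0, 1], 50)
        t = np.concatenate([np.linspace(-3, -1, 50), np.linspace(1, 3, 50)])
        cal = calibrate_metscore(t, y)
        assert cal.metscore(cal.threshold) == pytest.approx(0.5)
        assert np.isfinite(cal.slope)

    def test_estimator_wrapper_round_trip(self):
        t, y = self.make(seed=7)
        est = MetScoreCalibrator().fit(t, y)
        assert est.transform([est.threshold_])[0] == pytest.approx(0.5)
        assert set(np.unique(est.predict(t))) <= {0, 1}
        clone(est)  # sklearn-compatible

    def test_serialization_round_trip(self):
        t, y = self.make(seed=8)
        cal = calibrate_metscore(t, y)
        back = ScoreCalibration.from_dict(cal.to_dict())
        grid = np.linspace(-3, 3, 11)
        assert np.allclose(cal.metscore(grid), back.metscore(grid))


class TestFactorEvaluation:
    def test_score_tracking_one_factor(self):
        rng = np.random.default_rng(9)
        n = 4000
        factors = {name: rng.integers(0, 2, n)
                   for name in ("diabetes", "obesity", "dyslipidemia",
                                "hypertension")}
        score = factors["diabetes"] + 0.01 * rng.normal(size=n)
        table = evaluate_against_factor(score, factors).set_index("factor")
        assert table.loc["diabetes", "auroc"] > 0.99
        for other in ("obesity", "dyslipidemia", "hypertension"):
            assert 0.45 <= table.loc[other, "auroc"] <= 0.55

    def test_constant_factor_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            table = evaluate_against_factor(
                np.arange(10.0), {"diabetes": np.zeros(10)})
        assert np.isnan(table["auroc"]).all()

    def test_diabetes_dominates_on_generator_cohort(self, cohort, fitted):
        score = fitted.metscore(cohort)
        table = evaluate_against_factor(
            score, {f: cohort.factor_labels(f)
                    for f in ("diabetes", "obesity", "dyslipidemia",
                              "hypertension")}).set_index("factor")
        assert table["auroc"].idxmax() == "diabetes"
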