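"""ROC analysis, Youden thresholding and the sigmoid MetSCORE calibration.

The discriminant score ``t_pred`` is turned into a decision rule and a
probability-like risk score in three steps:

1. AUROC with a DeLong 95% confidence interval measures separation
   (AUROC = probability a random positive outscores a random negative,
   ties counted 1/2);
2. the Youden index J = sensitivity + specificity - 1, maximised over
   midpoints between consecutive distinct scores, fixes the decision
   threshold;
3. a class-weighted logistic regression of the label on ``t_pred`` (weights
   inversely proportional to class frequency, correcting the heavy class
   imbalance of an asymptomatic-dominated population) gives a strictly
   increasing sigmoid; its intercept is then re-centred exactly so the
   score equals 0.5 at the Youden threshold.  The result — MetSCORE —
   lives in (0, 1) and reads as a risk of metabolic syndrome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted


def _check_binary(scores, labels):
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels).ravel()
    if s.size != y.size:
        raise ValueError("scores and labels have different lengths")
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(
            f"need exactly two classes, got {classes.tolist()}")
    yb = (y == classes.max()).astype(int)
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    return s, yb


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def roc_auc(scores, labels, ci: float = 0.95):
    """AUROC with a DeLong confidence interval.

    Returns ``(auc, (lo, hi))``.  The point estimate is the tie-aware
    Mann–Whitney statistic; the variance follows DeLong's structural-
    components method, with the interval clipped to [0, 1].
    """
    s, y = _check_binary(scores, labels)
    pos, neg = s[y == 1], s[y == 0]
    m, n = pos.size, neg.size
    all_ranks = _midranks(s)
    pos_ranks = _midranks(pos)
    neg_ranks = _midranks(neg)
    auc = (all_ranks[y == 1].sum() - m * (m + 1) / 2.0) / (m * n)
    # DeLong structural components
    v10 = (all_ranks[y == 1] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[y == 0] - neg_ranks) / m
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) \
        + (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    z = stats.norm.ppf(0.5 + ci / 2.0)
    half = z * np.sqrt(max(var, 0.0))
    return float(auc), (float(max(0.0, auc - half)), float(min(1.0, auc + half)))


def auroc(scores, labels) -> float:
    """AUROC point estimate only."""
    return roc_auc(scores, labels)[0]


def roc_curve_points(scores, labels) -> pd.DataFrame:
    """(threshold, sensitivity, specificity) over all midpoint thresholds."""
    s, y = _check_binary(scores, labels)
    thresholds = _candidate_thresholds(s)
    rows = []
    for t in thresholds:
        sens, spec = _sens_spec(s, y, t)
        rows.append({"threshold": t, "sensitivity": sens, "specificity": spec})
    return pd.DataFrame(rows)


def _candidate_thresholds(s: np.ndarray) -> np.ndarray:
    u = np.unique(s)
    if u.size == 1:
        return np.array([u[0]])
    mids = (u[:-1] + u[1:]) / 2.0
    return np.concatenate([[u[0] - 1.0], mids, [u[-1] + 1.0]])


def _sens_spec(s, y, threshold) -> tuple[float, float]:
    calls = s > threshold
    sens = calls[y == 1].mean() if (y == 1).any() else np.nan
    spec = (~calls[y == 0]).mean() if (y == 0).any() else np.nan
    return float(sens), float(spec)


def youden_threshold(scores, labels):
    """Decision threshold maximising J = sensitivity + specificity - 1.

    Candidates are midpoints between consecutive distinct scores (plus
    sentinels beyond the range); ties are broken toward the smallest
    threshold.  Returns ``(threshold, sensitivity, specificity)``.
    """
    s, y = _check_binary(scores, labels)
    best_t, best_j, best = None, -np.inf, (np.nan, np.nan)
    for t in _candidate_thresholds(s):
        sens, spec = _sens_spec(s, y, t)
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_t, best_j, best = float(t), j, (sens, spec)
    return best_t, best[0], best[1]


@dataclass
class ScoreCalibration:
    """Sigmoid map t_pred -> MetSCORE in (0, 1), centred on the threshold.

    ``metscore(t) = expit(slope * t + intercept)`` with slope > 0 and
    ``intercept = -slope * threshold`` so the threshold maps to 0.5.
    """

    threshold: float
    slope: float
    intercept: float
    sensitivity: float = np.nan
    specificity: float = np.nan

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")

    def metscore(self, t_pred) -> np.ndarray:
        t = np.asarray(t_pred, dtype=float)
        return expit(self.slope * t + self.intercept)

    def classify(self, t_pred) -> np.ndarray:
        """MetS call at MetSCORE > 0.5, i.e. t_pred > threshold."""
        return (np.asarray(t_pred, dtype=float) > self.threshold).astype(int)

    def to_dict(self) -> dict:
        return {"threshold": self.threshold, "slope": self.slope,
                "intercept": self.intercept, "sensitivity": self.sensitivity,
                "specificity": self.specificity}

    @classmethod
    def from_dict(cls, d: dict) -> "ScoreCalibration":
        return cls(**{k: d[k] for k in
                      ("threshold", "slope", "intercept",
                       "sensitivity", "specificity") if k in d})


def calibrate_metscore(t_pred, labels, threshold: float | None = None
                       ) -> ScoreCalibration:
    """Fit the class-weighted sigmoid calibration.

    Sample weights are inversely proportional to class frequency so both
    groups contribute equally despite imbalance.  The fitted slope must
    be positive (an anti-predictive score is an error); the intercept is
    replaced by ``-slope * threshold`` so the centring property holds
    exactly rather than approximately.
    """
    import statsmodels.api as sm

    t, y = _check_binary(t_pred, labels)
    if threshold is None:
        threshold, sens, spec = youden_threshold(t, y)
    else:
        sens, spec = _sens_spec(t, y, threshold)
    n = y.size
    w = np.where(y == 1, n / (2.0 * y.sum()), n / (2.0 * (n - y.sum())))
    model = sm.GLM(y, sm.add_constant(t), family=sm.families.Binomial(),
                   var_weights=w)
    try:
        fitted = model.fit()
        slope = float(fitted.params[1])
    except Exception:  # perfect separation: fall back to a steep finite slope
        spread = np.abs(t - threshold)
        slope = 10.0 / max(np.median(spread), 1e-6)
    if slope <= 0:
        raise ValueError(
            "fitted calibration slope is not positive; the score is "
            "anti-predictive for the class")
    if not np.isfinite(slope) or slope > 1e6:
        slope = 1e6
    return ScoreCalibration(threshold=float(threshold), slope=slope,
                            intercept=-slope * float(threshold),
                            sensitivity=sens, specificity=spec)


class MetScoreCalibrator(BaseEstimator):
    """Estimator wrapper: fit the Youden threshold + sigmoid on (t_pred, y)."""

    def fit(self, t_pred, y):
        t, yb = _check_binary(t_pred, y)
        threshold, _, _ = youden_threshold(t, yb)
        self.calibration_ = calibrate_metscore(t, yb, threshold)
        self.threshold_ = self.calibration_.threshold
        self.slope_ = self.calibration_.slope
        self.intercept_ = self.calibration_.intercept
        return self

    def transform(self, t_pred) -> np.ndarray:
        check_is_fitted(self, "calibration_")
        return self.calibration_.metscore(t_pred)

    predict_proba = transform

    def predict(self, t_pred) -> np.ndarray:
        check_is_fitted(self, "calibration_")
        return self.calibration_.classify(t_pred)


def evaluate_against_factor(scores, factor_labels: dict[str, np.ndarray]
                            ) -> pd.DataFrame:
    """AUROC of one score against each single risk factor separately.

    Constant factors are skipped with a warning row (NaN AUROC).
    """
    import warnings

    rows = []
    for name, labels in factor_labels.items():
        labels = np.asarray(labels).ravel()
        if np.unique(labels).size < 2:
            warnings.warn(f"risk factor {name!r} is constant; skipped",
                          stacklevel=2)
            rows.append({"factor": name, "auroc": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan})
            continue
        auc, (lo, hi) = roc_auc(scores, labels)
        rows.append({"factor": name, "auroc": auc, "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(rows)
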