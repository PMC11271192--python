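"""Train/test splitting and repeated cross-validation with permutation tests.

Model assessment follows the two-stage protocol common in metabolomics:
an 80/20 train/test split for the headline fit, then a final refit on all
samples assessed by repeated stratified k-fold cross-validation (default
10 x 5-fold) combined with a label-permutation test (default 100
permutations).  Crucially, variable selection is re-run inside every
training fold — selecting on the full data and then cross-validating
optimistically biases the AUROC, and this module refuses that path
unless explicitly forced (useful only to demonstrate the bias).

The permutation p-value uses the add-one estimator
``p = (1 + #{perm >= observed}) / (n_perm + 1)``, so its floor with 100
permutations is 1/101.  Labels are permuted once per replicate before
fold assignment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Protocol

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .scoring import auroc, youden_threshold, _sens_spec
from .synthetic import CohortTable


def train_test_split(cohort: CohortTable, fraction: float = 0.8,
                     seed: int = 0) -> tuple[list[str], list[str]]:
    """Seeded random split of sample ids into train/test (no stratification).

    Train size is ``round(fraction * n)``; the partition is disjoint and
    exhaustive.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    ids = list(cohort.data["sample_id"])
    if len(ids) < 5:
        raise ValueError("cohort too small to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n_train = int(round(fraction * len(ids)))
    train = [ids[i] for i in sorted(order[:n_train])]
    test = [ids[i] for i in sorted(order[n_train:])]
    return train, test


class ScoringPipeline(Protocol):
    """What repeated CV needs from a pipeline: fit on a cohort with labels,
    then produce a per-sample decision score for a new cohort."""

    def fit(self, cohort: CohortTable, y: np.ndarray | None = None): ...

    def decision_scores(self, cohort: CohortTable) -> np.ndarray: ...


@dataclass
class CVReport:
    """Fold-level metrics, pooled estimates and the permutation null."""

    folds: pd.DataFrame              # rep, fold, auroc, sensitivity, specificity
    pooled: dict[str, float]
    permutation_auroc: np.ndarray
    permutation_p: float
    seed: int
    n_permutations: int
    extras: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        doc = {
            "folds": self.folds.to_dict(orient="records"),
            "pooled": self.pooled,
            "permutation_auroc": [float(a) for a in self.permutation_auroc],
            "permutation_p": self.permutation_p,
            "seed": self.seed,
            "n_permutations": self.n_permutations,
            **self.extras,
        }
        text = json.dumps(doc, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _cv_fold_metrics(pipeline_factory: Callable[[], ScoringPipeline],
                     cohort: CohortTable, y: np.ndarray,
                     folds: int, seed: int, rep: int) -> list[dict]:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    rows = []
    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
        ids = cohort.data["sample_id"].to_numpy()
        train_cohort = cohort.subset(ids[tr])
        test_cohort = cohort.subset(ids[te])
        pipe = pipeline_factory()
        pipe.fit(train_cohort, y[tr])
        train_scores = pipe.decision_scores(train_cohort)
        thr, _, _ = youden_threshold(train_scores, y[tr])
        test_scores = pipe.decision_scores(test_cohort)
        sens, spec = _sens_spec(np.asarray(test_scores), y[te], thr)
        rows.append({"rep": rep, "fold": fold,
                     "auroc": auroc(test_scores, y[te]),
                     "sensitivity": sens, "specificity": spec})
    return rows


def repeated_cv_permutation(
    pipeline_factory: Callable[[], ScoringPipeline],
    cohort: CohortTable,
    y: np.ndarray | None = None,
    reps: int = 10,
    folds: int = 5,
    n_perm: int = 100,
    seed: int = 0,
    fixed_variables: list[str] | None = None,
    allow_full_data_selection: bool = False,
) -> CVReport:
    """Repeated stratified k-fold CV with a label-permutation null.

    The pipeline (including its variable selection) is refit inside every
    training fold.  ``fixed_variables`` — a variable set chosen on the
    full data — is refused unless ``allow_full_data_selection`` is set,
    because it leaks test information into selection.

    Each permutation shuffles the labels once, then runs a single
    repetition of k-fold CV; its statistic is the mean fold AUROC.
    """
    if fixed_variables is not None and not allow_full_data_selection:
        raise ValueError(
            "refusing to cross-validate with a variable set selected on the "
            "full data: selection must happen inside each training fold "
            "(set allow_full_data_selection=True only to demonstrate the bias)")
    if y is None:
        y = cohort.mets_labels()
    y = np.asarray(y).astype(int).ravel()
    counts = np.bincount(y, minlength=2)
    if counts.min() < folds:
        raise ValueError(
            f"rarest class has {counts.min()} samples, fewer than {folds} "
            f"folds; use fewer folds")

    rng = np.random.default_rng(seed)
    fold_rows: list[dict] = []
    for rep in range(reps):
        rep_seed = int(rng.integers(2**31 - 1))
        fold_rows.extend(_cv_fold_metrics(pipeline_factory, cohort, y,
                                          folds, rep_seed, rep))
    folds_df = pd.DataFrame(fold_rows)
    observed = float(folds_df["auroc"].mean())

    perm_stats = np.empty(n_perm)
    for k in range(n_perm):
        y_perm = rng.permutation(y)
        perm_seed = int(rng.integers(2**31 - 1))
        rows = _cv_fold_metrics(pipeline_factory, cohort, y_perm,
                                folds, perm_seed, rep=0)
        perm_stats[k] = np.mean([r["auroc"] for r in rows])
    p_value = (1.0 + np.sum(perm_stats >= observed)) / (n_perm + 1.0)

    pooled = {
        "auroc": observed,
        "sensitivity": float(folds_df["sensitivity"].mean()),
        "specificity": float(folds_df["specificity"].mean()),
    }
    return CVReport(folds=folds_df, pooled=pooled,
                    permutation_auroc=perm_stats,
                    permutation_p=float(p_value), seed=seed,
                    n_permutations=n_perm)
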