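"""End-to-end MetSCORE pipeline: selection -> O-PLS-DA -> calibration.

`MetScorePipeline` is the fit/predict surface over the whole analysis.
Fitting a cohort runs, in order: per-variable profile contrasts
(univariate stage), the variable-filtering cascade (manual discards,
near-zero-variance, effect/significance filter, one representative per
correlation cluster), the O-PLS-DA discriminant on the selected panel,
the Youden threshold on the predictive score, and the class-weighted
sigmoid calibration that defines MetSCORE.  `run_full_pipeline` drives
the published protocol around it — 80/20 split, test evaluation, final
refit on all samples with repeated CV + permutation — and writes every
artifact with the config hash and seed embedded.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import io as mio
from .opls import OplsDiscriminant
from .profiles import build_profile_graph, graph_to_tables
from .scoring import (ScoreCalibration, calibrate_metscore, evaluate_against_factor,
                      roc_auc, youden_threshold)
from .selection import (DEFAULT_CUT_HEIGHTS, DEFAULT_EXCLUSION_PATTERNS,
                        SelectionResult, reduced_model_patterns,
                        run_selection_cascade)
from .som import SelfOrganizingMap, cell_statistics
from .synthetic import CohortTable
from .univariate import effect_table, heatmap_matrix
from .validation import CVReport, repeated_cv_permutation, train_test_split
from .profiles import RISK_FACTORS

logger = logging.getLogger("metscore")


class MetScorePipeline(BaseEstimator):
    """Selection + O-PLS-DA + Youden threshold + MetSCORE calibration.

    Parameters mirror the analysis defaults: dendrogram cut heights 0.5
    (serum) / 0.85 (urine bins), effect-size threshold 0.5 SD, FDR level
    0.05, one predictive + one orthogonal component.
    """

    def __init__(self, cut_heights: dict | None = None,
                 effect_threshold: float = 0.5, alpha: float = 0.05,
                 exclusion_patterns: tuple = DEFAULT_EXCLUSION_PATTERNS,
                 n_orth: int = 1, log_transform: bool = True,
                 definition: str = "WHO"):
        self.cut_heights = cut_heights
        self.effect_threshold = effect_threshold
        self.alpha = alpha
        self.exclusion_patterns = exclusion_patterns
        self.n_orth = n_orth
        self.log_transform = log_transform
        self.definition = definition

    def fit(self, cohort: CohortTable, y: np.ndarray | None = None):
        if y is None:
            y = cohort.mets_labels(self.definition)
        y = np.asarray(y).astype(int).ravel()
        logger.info("univariate stage on %d variables, %d samples",
                    len(cohort.variables), cohort.n_samples)
        self.effects_ = effect_table(cohort)
        self.selection_: SelectionResult = run_selection_cascade(
            cohort, self.effects_, cut_heights=self.cut_heights,
            exclusion_patterns=self.exclusion_patterns,
            effect_threshold=self.effect_threshold, alpha=self.alpha)
        logger.info("selection kept %d of %d variables",
                    len(self.selection_.selected), len(cohort.variables))
        X = cohort.data[self.selection_.selected]
        self.model_ = OplsDiscriminant(
            n_orth=self.n_orth, log_transform=self.log_transform).fit(X, y)
        t_pred = self.model_.t_pred_
        threshold, sens, spec = youden_threshold(t_pred, y)
        self.calibration_: ScoreCalibration = calibrate_metscore(
            t_pred, y, threshold)
        self.threshold_ = self.calibration_.threshold
        self.variables_ = self.selection_.selected
        self.train_auroc_, self.train_auroc_ci_ = roc_auc(t_pred, y)
        logger.info("training AUROC %.3f, Youden threshold %.3f "
                    "(sens %.3f, spec %.3f)",
                    self.train_auroc_, threshold, sens, spec)
        return self

    def decision_scores(self, cohort: CohortTable) -> np.ndarray:
        """t_pred for the samples of a cohort."""
        t_pred, _ = self.model_.transform(cohort.data[self.variables_])
        return t_pred

    def metscore(self, cohort: CohortTable) -> np.ndarray:
        return self.calibration_.metscore(self.decision_scores(cohort))

    def predict(self, cohort: CohortTable) -> np.ndarray:
        return self.calibration_.classify(self.decision_scores(cohort))

    def score_table(self, cohort: CohortTable) -> pd.DataFrame:
        t_pred = self.decision_scores(cohort)
        return pd.DataFrame({
            "sample_id": cohort.data["sample_id"],
            "t_pred": t_pred,
            "metscore": self.calibration_.metscore(t_pred),
            "mets_call": self.calibration_.classify(t_pred),
        })

    def to_document(self, seed=None, config_hash=None,
                    metadata=None) -> mio.ModelDocument:
        return mio.ModelDocument.from_fitted(
            self.model_, self.calibration_, seed=seed,
            config_hash=config_hash, metadata=metadata)


@dataclass
class PipelineConfig:
    """Every tunable of the end-to-end run, with the published defaults."""

    dataset: str = "serum_only"            # or serum_plus_urine
    cut_heights: dict = field(default_factory=lambda: dict(DEFAULT_CUT_HEIGHTS))
    effect_threshold: float = 0.5
    alpha: float = 0.05
    split_fraction: float = 0.8
    n_orth: int = 1
    cv_reps: int = 10
    cv_folds: int = 5
    n_permutations: int = 100
    som_groups: int = 6
    som_rows: int | None = None
    som_cols: int | None = None
    som_epochs: int = 20
    exclusion_patterns: list = field(
        default_factory=lambda: list(DEFAULT_EXCLUSION_PATTERNS))
    reduced_model: bool = False
    reduced_model_blocks: dict = field(default_factory=dict)  # variable -> block
    definition: str = "WHO"
    seed: int = 0

    def validate(self) -> None:
        if self.dataset not in ("serum_only", "serum_plus_urine"):
            raise ValueError(f"unknown dataset selection {self.dataset!r}")
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must be in (0, 1)")
        for key in ("effect_threshold", "alpha"):
            if getattr(self, key) < 0:
                raise ValueError(f"{key} must be nonnegative")
        if min(self.cv_reps, self.cv_folds, self.n_permutations) < 1:
            raise ValueError("cv_reps, cv_folds and n_permutations must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def patterns(self) -> tuple:
        pats = tuple(self.exclusion_patterns)
        if self.reduced_model:
            if not self.reduced_model_blocks:
                raise ValueError(
                    "reduced_model requires reduced_model_blocks "
                    "(variable -> cluster-name map)")
            pats = pats + reduced_model_patterns(self.reduced_model_blocks)
        return pats

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed fan-out from the global seed."""
        order = ("split", "cv", "som")
        ss = np.random.SeedSequence(self.seed, spawn_key=(order.index(stage),))
        return int(ss.generate_state(1)[0] % (2**31 - 1))


def _restrict_dataset(cohort: CohortTable, dataset: str) -> CohortTable:
    if dataset == "serum_plus_urine":
        return cohort
    keep = [v for v in cohort.variables
            if cohort.variable_types[v] != "urine_bin"]
    meta = list(CohortTable.METADATA_COLUMNS)
    return CohortTable(cohort.data[meta + keep].copy(),
                       {v: cohort.variable_types[v] for v in keep})


def run_full_pipeline(cohort: CohortTable, config: PipelineConfig,
                      out_dir=None) -> dict:
    """The full published protocol on one cohort.

    Split -> fit on train (clustering, univariate, selection, O-PLS-DA,
    threshold, calibration) -> evaluate on test -> final refit on all
    samples assessed by repeated CV + permutation.  Also builds the
    profile progression graph, the heatmap matrix, the SOM map and
    per-risk-factor AUROCs.  Returns a results dict; writes artifacts
    (model JSON, tables, CV report) when ``out_dir`` is given.
    """
    config.validate()
    cohort = _restrict_dataset(cohort, config.dataset)
    chash = mio.config_hash(config.to_dict())
    logger.info("pipeline run: n=%d, config %s, seed %d",
                cohort.n_samples, chash, config.seed)

    def make_pipeline() -> MetScorePipeline:
        return MetScorePipeline(
            cut_heights=config.cut_heights,
            effect_threshold=config.effect_threshold, alpha=config.alpha,
            exclusion_patterns=config.patterns(), n_orth=config.n_orth,
            definition=config.definition)

    stage = {"name": "train_test_split"}
    try:
        train_ids, test_ids = train_test_split(
            cohort, config.split_fraction, seed=config.stage_seed("split"))
        train, test = cohort.subset(train_ids), cohort.subset(test_ids)

        stage["name"] = "train_fit"
        pipe = make_pipeline().fit(train)

        stage["name"] = "test_evaluation"
        y_test = test.mets_labels(config.definition)
        test_scores = pipe.decision_scores(test)
        test_auroc, test_ci = roc_auc(test_scores, y_test)

        stage["name"] = "final_refit"
        final = make_pipeline().fit(cohort)
        y_all = cohort.mets_labels(config.definition)
        scores_all = final.score_table(cohort)

        stage["name"] = "cross_validation"
        cv: CVReport = repeated_cv_permutation(
            make_pipeline, cohort, y=y_all, reps=config.cv_reps,
            folds=config.cv_folds, n_perm=config.n_permutations,
            seed=config.stage_seed("cv"))

        stage["name"] = "profile_graph"
        graph = build_profile_graph(scores_all["metscore"],
                                    cohort.data["profile"])

        stage["name"] = "per_factor_evaluation"
        factors = {f: cohort.factor_labels(f) for f in RISK_FACTORS}
        factor_auc = evaluate_against_factor(scores_all["metscore"], factors)

        stage["name"] = "som_mapping"
        Z = np.column_stack([
            (lambda x: (x - x.mean()) / x.std(ddof=1))(
                cohort.data[v].to_numpy(dtype=float))
            for v in final.variables_])
        som = SelfOrganizingMap(rows=config.som_rows, cols=config.som_cols,
                                epochs=config.som_epochs,
                                random_state=config.stage_seed("som")).fit(Z)
        som.group_cells(config.som_groups)
        som_stats = cell_statistics(som, y_all, scores_all["metscore"])
    except Exception as err:
        raise RuntimeError(
            f"pipeline failed at stage {stage['name']!r}: {err}") from err

    heat = heatmap_matrix(
        final.effects_[final.effects_["variable"].isin(final.variables_)])
    document = final.to_document(seed=config.seed, config_hash=chash,
                                 metadata={"n_samples": cohort.n_samples})
    results = {
        "config_hash": chash,
        "train_ids": train_ids, "test_ids": test_ids,
        "train_pipeline": pipe, "final_pipeline": final,
        "model_document": document,
        "train_auroc": pipe.train_auroc_,
        "test_auroc": test_auroc, "test_auroc_ci": test_ci,
        "cv_report": cv,
        "scores": scores_all,
        "profile_graph": graph,
        "factor_auroc": factor_auc,
        "som": som, "som_stats": som_stats,
        "heatmap": heat,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        mio.save_model(document, out / "model.json")
        final.effects_.to_csv(out / "effects.csv", index=False)
        final.selection_.provenance_table().to_csv(
            out / "selection_provenance.csv", index=False)
        scores_all.to_csv(out / "scores.csv", index=False)
        cv.to_json(out / "cv_report.json")
        nodes, edges = graph_to_tables(graph)
        nodes.to_csv(out / "profile_graph_nodes.csv", index=False)
        edges.to_csv(out / "profile_graph_edges.csv", index=False)
        factor_auc.to_csv(out / "factor_auroc.csv", index=False)
        som_stats.to_csv(out / "som_cells.csv", index=False)
        heat.effects.to_csv(out / "heatmap_effects.csv")
        heat.stars.to_csv(out / "heatmap_stars.csv")
        mio.write_yaml({"config": config.to_dict(), "config_hash": chash,
                        "test_auroc": float(test_auroc)},
                       out / "run_summary.yaml")
    return results


def score_samples(document: mio.ModelDocument,
                  cohort: CohortTable) -> pd.DataFrame:
    """Score a new cohort with a serialized model document.

    Returns sample_id, t_pred, MetSCORE and the MetS call at score 0.5.
    """
    missing = [v for v in document.variables if v not in cohort.data.columns]
    if missing:
        raise ValueError(f"cohort is missing model variables: {missing}")
    est = document.to_estimator()
    t_pred, _ = est.transform(cohort.data[document.variables])
    out = pd.DataFrame({"sample_id": cohort.data["sample_id"],
                        "t_pred": t_pred})
    if document.calibration is not None:
        out["metscore"] = document.calibration.metscore(t_pred)
        out["mets_call"] = document.calibration.classify(t_pred)
    return out
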