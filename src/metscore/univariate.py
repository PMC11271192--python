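"""Per-variable profile contrasts: adjusted linear models, FDR, heatmap.

For every metabolomic variable, an ordinary least-squares model regresses
the standardized variable on the risk-profile factor (reference level
0000, the asymptomatic profile) with gender and age group as categorical
adjustment covariates.  The profile coefficients are effect sizes in
standard-deviation units.  Raw two-sided p-values are Benjamini–Hochberg
adjusted within each variable-type family (serum metabolites, serum
lipoproteins, urine bins), and cells with adjusted p < 0.05 count as
significant.

The heatmap view truncates effects to [-1, 1] and orders variables and
profiles by complete-linkage Euclidean dendrograms, with significance
stars at the 0.05 / 0.01 / 0.001 / 0.0001 levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

from .synthetic import CohortTable

REFERENCE_PROFILE = "0000"
SIGNIFICANCE_LEVEL = 0.05
STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def standardize_variable(values) -> np.ndarray:
    """Center to mean 0 and scale to unit sample SD (n-1 denominator)."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1D vector")
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd <= 0:
        raise ValueError(
            "cannot standardize a (near-)constant variable; apply the "
            "near-zero-variance filter first")
    return (x - x.mean()) / sd


def _design_matrix(profiles, gender, age_group):
    """Intercept + profile dummies (ref 0000) + gender + age-group dummies."""
    prof = pd.Categorical(profiles)
    if REFERENCE_PROFILE not in prof.categories:
        raise ValueError(
            f"reference profile {REFERENCE_PROFILE} absent from the data")
    present = [c for c in prof.categories if c != REFERENCE_PROFILE]
    frame = pd.DataFrame({"profile": prof,
                          "gender": pd.Categorical(gender),
                          "age_group": pd.Categorical(age_group)})
    dummies = pd.get_dummies(frame, drop_first=False, dtype=float)
    cols = ([f"profile_{c}" for c in present]
            + [f"gender_{g}" for g in frame["gender"].cat.categories[1:]]
            + [f"age_group_{a}" for a in frame["age_group"].cat.categories[1:]])
    X = np.column_stack([np.ones(len(frame))] + [dummies[c].to_numpy() for c in cols])
    names = ["intercept"] + cols
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the aliased columns: those whose removal restores full rank
        aliased = [names[j] for j in range(X.shape[1])
                   if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank]
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"aliased columns: {aliased}")
    return X, names, present


def _ols_multiresponse(X: np.ndarray, Y: np.ndarray):
    """OLS of many responses on one design; returns (beta, se, p)."""
    n, k = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ Y)
    resid = Y - X @ beta
    dof = n - k
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = beta / se
    p = 2.0 * stats.t.sf(np.abs(tval), dof)
    return beta, se, p


def fit_profile_regression(values, profiles, gender, age_group,
                           variable: str = "variable",
                           dataset_type: str = "serum_metabolite") -> pd.DataFrame:
    """Effect-table rows for one variable.

    Returns one row per profile present in the data (other than 0000)
    with the standardized-scale OLS coefficient and its classical
    two-sided t-test p-value; ``p_adj`` is left unset (NaN) for the
    family-wise FDR step.
    """
    y = standardize_variable(values)
    X, names, present = _design_matrix(profiles, gender, age_group)
    beta, se, p = _ols_multiresponse(X, y[:, None])
    rows = []
    for code in present:
        j = names.index(f"profile_{code}")
        rows.append({"variable": variable, "dataset_type": dataset_type,
                     "profile": code, "effect": beta[j, 0],
                     "p_raw": p[j, 0], "p_adj": np.nan, "significant": False})
    return pd.DataFrame(rows)


def effect_table(cohort: CohortTable, variables: list[str] | None = None,
                 adjust: bool = True) -> pd.DataFrame:
    """Vectorized profile contrasts for many variables of a cohort.

    All variables share one design matrix, so the fit is a single
    multi-response least squares; results match the per-variable
    :func:`fit_profile_regression` exactly.  With ``adjust=True`` the BH
    step runs within each dataset-type family and fills ``p_adj`` /
    ``significant``.
    """
    if variables is None:
        variables = cohort.variables
    X, names, present = _design_matrix(cohort.data["profile"],
                                       cohort.data["gender"],
                                       cohort.data["age_group"])
    Y = np.column_stack([standardize_variable(cohort.data[v]) for v in variables])
    beta, se, p = _ols_multiresponse(X, Y)
    prof_rows = [(code, names.index(f"profile_{code}")) for code in present]
    records = []
    for vi, v in enumerate(variables):
        vtype = cohort.variable_types[v]
        for code, j in prof_rows:
            records.append((v, vtype, code, beta[j, vi], p[j, vi]))
    table = pd.DataFrame.from_records(
        records, columns=["variable", "dataset_type", "profile", "effect", "p_raw"])
    table["p_adj"] = np.nan
    table["significant"] = False
    if adjust:
        table = adjust_fdr_by_family(table)
    return table


def adjust_fdr(p_raw) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values for one family."""
    p = np.asarray(p_raw, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def adjust_fdr_by_family(table: pd.DataFrame,
                         alpha: float = SIGNIFICANCE_LEVEL) -> pd.DataFrame:
    """Apply BH within each dataset-type family, pooling all profiles."""
    out = table.copy()
    for _, idx in out.groupby("dataset_type").groups.items():
        out.loc[idx, "p_adj"] = adjust_fdr(out.loc[idx, "p_raw"].to_numpy())
    out["significant"] = out["p_adj"] < alpha
    return out


def significance_stars(p_adj: float) -> str:
    if not np.isfinite(p_adj):
        return ""
    for threshold, stars in STAR_THRESHOLDS:
        if p_adj < threshold:
            return stars
    return ""


@dataclass
class HeatmapMatrix:
    """Ordered, truncated effect matrix with per-cell significance stars."""

    effects: pd.DataFrame   # variables x profiles, truncated to [-1, 1]
    stars: pd.DataFrame     # same shape, star strings
    row_order: list[str]
    col_order: list[str]


def _dendrogram_order(matrix: np.ndarray, labels: list[str]) -> list[str]:
    if len(labels) < 2:
        return list(labels)
    link = hierarchy.linkage(matrix, method="complete", metric="euclidean")
    return [labels[i] for i in hierarchy.leaves_list(link)]


def heatmap_matrix(effects: pd.DataFrame) -> HeatmapMatrix:
    """Arrange an effect table for display the way profile heatmaps are drawn."""
    if effects.empty:
        raise ValueError("effect table is empty")
    wide = effects.pivot_table(index="variable", columns="profile",
                               values="effect", aggfunc="first").fillna(0.0)
    pmat = effects.pivot_table(index="variable", columns="profile",
                               values="p_adj", aggfunc="first")
    truncated = wide.clip(-1.0, 1.0)
    row_order = _dendrogram_order(truncated.to_numpy(), list(truncated.index))
    col_order = _dendrogram_order(truncated.to_numpy().T, list(truncated.columns))
    truncated = truncated.loc[row_order, col_order]
    stars = pmat.reindex(index=row_order, columns=col_order).map(
        lambda p: significance_stars(p) if pd.notna(p) else "")
    return HeatmapMatrix(truncated, stars, row_order, col_order)
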