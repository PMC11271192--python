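"""Redundancy reduction and the variable-filtering cascade.

Correlated metabolomic panels (especially lipoprotein subclasses and
urine bins) would dominate a multivariate model by sheer repetition, so
variables are first clustered per dataset type with Spearman-correlation
distance (d = 1 - rho, signed) and average linkage, cutting the
dendrogram at 0.5 for serum variables and 0.85 for urine bins.  The
filtering cascade then runs, in fixed order:

1. manual exclusions (particle-number lipoproteins, EDTA adduct signals,
   and optionally the reduced-model list that drops glucose and the
   HDL/LDL clusters used by the clinical definitions);
2. the near-zero-variance filter (frequency ratio > 19 and unique-value
   fraction < 10%);
3. the univariate filter: keep variables with an FDR-significant effect
   of at least 0.5 SD in at least one profile;
4. one representative per cluster — the member with the highest
   cumulative absolute effect size across profiles.

Every input variable ends with exactly one provenance flag.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .synthetic import CohortTable
from .univariate import SIGNIFICANCE_LEVEL

DEFAULT_CUT_HEIGHTS = {"serum_metabolite": 0.5, "serum_lipoprotein": 0.5,
                       "urine_bin": 0.85}
EFFECT_THRESHOLD = 0.5
NZV_FREQ_RATIO = 19.0
NZV_UNIQUE_FRACTION = 0.10

#: Default manual-discard patterns: particle-number parameters (perfectly
#: collinear with Apo-B) and the EDTA adduct signals.
DEFAULT_EXCLUSION_PATTERNS = (r"(^|-)PN$", r"^Ca-EDTA$", r"^K-EDTA$")

#: Cluster names whose members (plus glucose) are dropped for the reduced
#: model that is independent of the clinical risk-factor definitions.
REDUCED_MODEL_CLUSTERS = ("HDLs_1_3_noTGs", "HDLs_4_noTGs", "LDLs_6",
                          "HDLs_1_3_TGs", "LDLs_4_5")
REDUCED_MODEL_EXTRA = ("Glucose",)

PROVENANCE_FLAGS = ("kept", "manual_discard", "near_zero_variance",
                    "effect_filtered", "non_representative")


@dataclass
class VariableClusterSet:
    """Average-linkage Spearman clustering of one dataset type's variables."""

    dataset_type: str
    variables: list[str]
    linkage: np.ndarray | None
    cut_height: float
    cluster_id: dict[str, int]

    @property
    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for v in self.variables:
            out.setdefault(self.cluster_id[v], []).append(v)
        return out

    @property
    def n_clusters(self) -> int:
        return len(set(self.cluster_id.values()))


@dataclass
class SelectionResult:
    """Outcome of the full cascade with per-variable provenance."""

    selected: list[str]
    provenance: dict[str, str]
    cluster_sets: dict[str, VariableClusterSet]
    representatives: dict[str, str] = field(default_factory=dict)  # cluster key -> var

    def provenance_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.provenance.items()), columns=["variable", "flag"])


def cluster_variables(values: pd.DataFrame, cut_height: float,
                      dataset_type: str = "serum_metabolite") -> VariableClusterSet:
    """Cluster the columns of *values* (samples x variables).

    Distance is 1 - Spearman rho (signed, so anti-correlated variables do
    not merge); linkage is average; the tree is cut at ``cut_height`` on
    the cophenetic distance scale.  Column order is canonicalised by name
    so results do not depend on input order.
    """
    variables = sorted(values.columns)
    X = values[variables].to_numpy(dtype=float)
    for j, v in enumerate(variables):
        if np.std(X[:, j]) == 0:
            raise ValueError(
                f"variable {v!r} is constant; run the near-zero-variance "
                f"filter before clustering")
    if len(variables) < 2:
        return VariableClusterSet(dataset_type, variables, None, cut_height,
                                  {v: 1 for v in variables})
    rho = stats.spearmanr(X).statistic
    if np.ndim(rho) == 0:  # spearmanr collapses the 2-variable case
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    dist = 1.0 - rho
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    labels = hierarchy.fcluster(link, t=cut_height, criterion="distance")
    return VariableClusterSet(dataset_type, variables, link, cut_height,
                              dict(zip(variables, (int(c) for c in labels))))


def near_zero_variance_filter(values) -> tuple[bool, dict]:
    """(keep, diagnostics) under the frequency-ratio / unique-fraction rule.

    Discard iff the ratio of the most common to the second most common
    value exceeds 19 AND fewer than 10% of values are unique; a constant
    vector has infinite ratio and is discarded.
    """
    x = np.asarray(values)
    if x.size == 0:
        raise ValueError("empty vector")
    _, counts = np.unique(x, return_counts=True)
    counts = np.sort(counts)[::-1]
    ratio = np.inf if counts.size == 1 else counts[0] / counts[1]
    unique_fraction = counts.size / x.size
    discard = (ratio > NZV_FREQ_RATIO) and (unique_fraction < NZV_UNIQUE_FRACTION)
    return (not discard), {"freq_ratio": float(ratio),
                           "unique_fraction": float(unique_fraction)}


def manual_exclusions(variable_names, patterns=DEFAULT_EXCLUSION_PATTERNS):
    """Names surviving the configured regex discard patterns."""
    names = list(variable_names)
    kept = names
    for pat in patterns:
        rx = re.compile(pat)
        matched = [v for v in kept if rx.search(v)]
        if not matched:
            warnings.warn(f"exclusion pattern {pat!r} matched no variable",
                          stacklevel=2)
        kept = [v for v in kept if not rx.search(v)]
    return kept


def reduced_model_patterns(block_of: dict[str, str]) -> tuple[str, ...]:
    """Exclusion patterns for the definition-independent reduced model.

    ``block_of`` maps variable name -> generator/annotation block name;
    members of the HDL/LDL clusters named in ``REDUCED_MODEL_CLUSTERS``
    plus glucose are excluded.
    """
    members = [re.escape(v) for v, b in block_of.items()
               if b in REDUCED_MODEL_CLUSTERS]
    pats = tuple(f"^{m}$" for m in members)
    return pats + tuple(f"^{re.escape(v)}$" for v in REDUCED_MODEL_EXTRA)


def select_variables(effects: pd.DataFrame,
                     clusters: VariableClusterSet,
                     effect_threshold: float = EFFECT_THRESHOLD,
                     alpha: float = SIGNIFICANCE_LEVEL) -> tuple[list[str], dict]:
    """Effect/significance filter + one representative per cluster.

    A variable survives if some profile row is FDR-significant with
    |effect| >= ``effect_threshold``.  Survivors are grouped by cluster
    and the member with the highest cumulative |effect| across all
    profiles represents its cluster (ties broken by name).

    Returns (selected names, provenance flags for this stage).
    """
    eff = effects[effects["variable"].isin(clusters.variables)]
    passing = (eff["p_adj"] < alpha) & (eff["effect"].abs() >= effect_threshold)
    survivors = set(eff.loc[passing, "variable"])
    flags = {v: ("effect_filtered" if v not in survivors else "non_representative")
             for v in clusters.variables}
    if not survivors:
        raise ValueError(
            "no variable passed the significance/effect filter; review the "
            f"effect threshold ({effect_threshold}) and alpha ({alpha})")
    cumulative = eff.groupby("variable")["effect"].apply(lambda s: s.abs().sum())
    selected = []
    for _, members in sorted(clusters.clusters.items()):
        alive = sorted(v for v in members if v in survivors)
        if not alive:
            continue
        rep = sorted(alive, key=lambda v: (-cumulative.get(v, 0.0), v))[0]
        selected.append(rep)
        flags[rep] = "kept"
    return sorted(selected), flags


def run_selection_cascade(
    cohort: CohortTable,
    effects: pd.DataFrame,
    cut_heights: dict[str, float] | None = None,
    exclusion_patterns=DEFAULT_EXCLUSION_PATTERNS,
    effect_threshold: float = EFFECT_THRESHOLD,
    alpha: float = SIGNIFICANCE_LEVEL,
) -> SelectionResult:
    """Run the fixed-order cascade over all dataset types of a cohort."""
    cut_heights = {**DEFAULT_CUT_HEIGHTS, **(cut_heights or {})}
    provenance: dict[str, str] = {}
    cluster_sets: dict[str, VariableClusterSet] = {}
    representatives: dict[str, str] = {}
    selected_all: list[str] = []

    all_vars = cohort.variables
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # per-type pattern misses are expected
        after_manual = set(manual_exclusions(all_vars, exclusion_patterns))
    for v in all_vars:
        if v not in after_manual:
            provenance[v] = "manual_discard"

    for dtype in ("serum_metabolite", "serum_lipoprotein", "urine_bin"):
        dvars = [v for v in cohort.variables_of_type(dtype) if v in after_manual]
        if not dvars:
            continue
        alive = []
        for v in dvars:
            keep, _ = near_zero_variance_filter(cohort.data[v])
            if keep:
                alive.append(v)
            else:
                provenance[v] = "near_zero_variance"
        if len(alive) == 0:
            continue
        cset = cluster_variables(cohort.data[alive], cut_heights[dtype], dtype)
        cluster_sets[dtype] = cset
        try:
            selected, flags = select_variables(effects, cset,
                                               effect_threshold, alpha)
        except ValueError:
            selected, flags = [], {v: "effect_filtered" for v in cset.variables}
        provenance.update(flags)
        selected_all.extend(selected)
        for v in selected:
            representatives[f"{dtype}:{cset.cluster_id[v]}"] = v

    if not selected_all:
        raise ValueError(
            "selection cascade left no variables; review the effect "
            "threshold and significance level")
    return SelectionResult(sorted(selected_all), provenance, cluster_sets,
                           representatives)
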