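"""Profile contrasts: standardization, adjusted OLS, BH-FDR, heatmap."""

import numpy as np
import pandas as pd
import pytest

import metscore as ms
from metscore.synthetic import CovariateEffect
from metscore.univariate import (adjust_fdr, adjust_fdr_by_family,
                                 effect_table, fit_profile_regression,
                                 heatmap_matrix, significance_stars,
                                 standardize_variable)
from tests.test_synthetic import small_config


def bh_stepup_bruteforce(p):
    """Literal step-up definition: adj p_(i) = min_{k>=i} min(1, m p_(k) / k)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    adj_sorted = np.empty(m)
    for i in range(m):
        adj_sorted[i] = min(
            min(m * sorted_p[k] / (k + 1) for k in range(i, m)), 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


class TestStandardize:
    def test_hand_example_with_sample_sd(self):
        assert np.allclose(standardize_variable([1, 2, 3]), [-1.0, 0.0, 1.0])

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            standardize_variable([2.0, 2.0, 2.0])

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        x = rng.normal(3.0, 2.0, 100)
        once = standardize_variable(x)
        assert np.allclose(standardize_variable(once), once, atol=1e-12)
        assert abs(once.mean()) < 1e-12
        assert once.std(ddof=1) == pytest.approx(1.0, abs=1e-12)


class TestAdjustFdr:
    def test_hand_computed_step_up(self):
        assert np.allclose(adjust_fdr([0.01, 0.02, 0.03, 0.04]),
                           [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged_and_all_ones(self):
        assert adjust_fdr([0.3]) == pytest.approx([0.3])
        assert np.allclose(adjust_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_fdr([0.5, 1.5])

    def test_matches_bruteforce_step_up_on_random_vectors(self):
        rng = np.random.default_rng(12)
        for _ in range(1000):
            p = rng.random(int(rng.integers(1, 20)))
            assert np.allclose(adjust_fdr(p), bh_stepup_bruteforce(p),
                               atol=1e-12)

    def test_monotone_in_raw_p(self):
        rng = np.random.default_rng(13)
        p = rng.random(50)
        adj = adjust_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestProfileRegression:
    def test_recovers_configured_shift(self):
        cfg = small_config(n=4000, seed=5,
                           loadings={"C1": {"diabetes": 1.0}},
                           prevalence={"0000": 0.9, "1111": 0.1})
        cohort = ms.generate_cohort(cfg)
        rows = fit_profile_regression(cohort.data["C1"],
                                      cohort.data["profile"],
                                      cohort.data["gender"],
                                      cohort.data["age_group"])
        eff = rows.set_index("profile").loc["1111", "effect"]
        # +1 noise-SD shift, mildly attenuated by the between-group variance
        # that standardization folds into the marginal SD
        assert 0.9 <= eff <= 1.1

    def test_null_variable_has_small_effects(self):
        cohort = ms.generate_cohort(small_config(
            n=4000, seed=6, prevalence={"0000": 0.5, "1111": 0.5}))
        rows = fit_profile_regression(cohort.data["C1"],
                                      cohort.data["profile"],
                                      cohort.data["gender"],
                                      cohort.data["age_group"])
        assert rows["effect"].abs().max() < 0.15

    def test_gender_confounding_removed_by_adjustment(self):
        # the shift exists only through gender; gender balanced across
        # profiles, so adjusted profile effects vanish
        cfg = small_config(n=6000, seed=7,
                           prevalence={"0000": 0.5, "1111": 0.5})
        cfg.covariate_effects = {"C1": CovariateEffect(gender=1.0)}
        cohort = ms.generate_cohort(cfg)
        rows = fit_profile_regression(cohort.data["C1"],
                                      cohort.data["profile"],
                                      cohort.data["gender"],
                                      cohort.data["age_group"])
        adjusted = rows.set_index("profile").loc["1111", "effect"]
        assert abs(adjusted) < 0.1
        # sanity: gender itself does carry the shift
        z = standardize_variable(cohort.data["C1"])
        by_gender = pd.Series(z).groupby(cohort.data["gender"].values).mean()
        assert by_gender["male"] - by_gender["female"] > 0.5

    def test_effects_invariant_to_affine_rescaling(self):
        cohort = ms.generate_cohort(small_config(
            n=1000, seed=8, loadings={"C1": {"diabetes": 0.8}},
            prevalence={"0000": 0.5, "1111": 0.5}))
        args = (cohort.data["profile"], cohort.data["gender"],
                cohort.data["age_group"])
        a = fit_profile_regression(cohort.data["C1"], *args)
        b = fit_profile_regression(1000.0 * cohort.data["C1"] + 7.0, *args)
        assert np.allclose(a["effect"], b["effect"], atol=1e-10)
        assert np.allclose(a["p_raw"], b["p_raw"], atol=1e-10)

    def test_absent_reference_profile_rejected(self):
        cohort = ms.generate_cohort(small_config(
            n=200, seed=9, prevalence={"0011": 0.5, "1111": 0.5}))
        with pytest.raises(ValueError, match="reference profile"):
            fit_profile_regression(cohort.data["C1"], cohort.data["profile"],
                                   cohort.data["gender"],
                                   cohort.data["age_group"])

    def test_rank_deficiency_names_aliased_columns(self):
        cohort = ms.generate_cohort(small_config(
            n=200, seed=10, prevalence={"0000": 0.5, "1111": 0.5}))
        gender = np.where(cohort.data["profile"] == "1111", "male", "female")
        with pytest.raises(ValueError, match="aliased"):
            fit_profile_regression(cohort.data["C1"], cohort.data["profile"],
                                   gender, cohort.data["age_group"])

    def test_vectorized_table_matches_per_variable_fit(self, cohort):
        variables = cohort.variables[:5]
        table = effect_table(cohort, variables=variables, adjust=False)
        for v in variables:
            single = fit_profile_regression(
                cohort.data[v], cohort.data["profile"],
                cohort.data["gender"], cohort.data["age_group"], variable=v)
            merged = table[table["variable"] == v].set_index("profile")
            ref = single.set_index("profile")
            assert np.allclose(merged["effect"], ref.loc[merged.index, "effect"],
                               atol=1e-10)
            assert np.allclose(merged["p_raw"], ref.loc[merged.index, "p_raw"],
                               atol=1e-10)


def test_fdr_families_are_per_dataset_type(cohort):
    table = effect_table(cohort)
    for _, fam in table.groupby("dataset_type"):
        assert np.allclose(fam["p_adj"], adjust_fdr(fam["p_raw"].to_numpy()),
                           atol=1e-12)
        assert (fam["p_adj"] >= fam["p_raw"] - 1e-12).all()


def test_type_one_error_controlled_under_global_null(null_cohort):
    table = effect_table(null_cohort)
    frac = table["significant"].mean()
    n = len(table)
    assert frac <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n)


class TestHeatmap:
    def test_truncation_and_stars(self):
        eff = pd.DataFrame({
            "variable": ["v1", "v1", "v2", "v2"],
            "dataset_type": "serum_metabolite",
            "profile": ["0001", "0010"] * 2,
            "effect": [2.3, -1.4, 0.2, 0.4],
            "p_raw": [1e-5, 0.01, 0.3, 0.02],
            "p_adj": [0.0005, 0.02, 0.5, 0.04],
            "significant": [True, True, False, True],
        })
        hm = heatmap_matrix(eff)
        assert hm.effects.loc["v1", "0001"] == 1.0
        assert hm.effects.loc["v1", "0010"] == -1.0
        assert hm.stars.loc["v1", "0001"] == "***"
        assert hm.stars.loc["v1", "0010"] == "*"
        assert hm.stars.loc["v2", "0001"] == ""

    def test_star_thresholds(self):
        assert significance_stars(0.02) == "*"
        assert significance_stars(0.0005) == "***"
        assert significance_stars(5e-5) == "****"
        assert significance_stars(0.06) == ""

    def test_identical_variables_are_adjacent_leaves(self):
        rng = np.random.default_rng(0)
        rows = []
        base = {"twin_a": 0.0, "twin_b": 0.0, "other": 5.0}
        for v, offset in base.items():
            for k, prof in enumerate(["0001", "0010", "0100"]):
                rows.append({"variable": v, "dataset_type": "serum_metabolite",
                             "profile": prof, "effect": offset + 0.1 * k,
                             "p_raw": 0.5, "p_adj": 0.5, "significant": False})
        hm = heatmap_matrix(pd.DataFrame(rows))
        ia, ib = hm.row_order.index("twin_a"), hm.row_order.index("twin_b")
        assert abs(ia - ib) == 1

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            heatmap_matrix(pd.DataFrame(
                columns=["variable", "profile", "effect", "p_adj"]))
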