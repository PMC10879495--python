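"""Mixed models, sequential closed testing, Welch tests, correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from gazesal.inference import (
    correlate_clinical,
    fit_lme,
    sequential_duration_test,
    two_sample_summary_test,
)

CATS = ["congruent", "incongruent", "physically_salient",
        "social_interaction", "social_landscape"]


def _simulate_nss(rng, n_schz=28, n_hc=25, n_per_cat=20, tau_s=0.002,
                  tau_c=0.001, sigma2=0.02, interaction=0.05):
    """Draw a sqrt-NSS table from the crossed-intercept generative model,
    with a group x physically_salient interaction of the given size."""
    subs = [f"schz_{i}" for i in range(n_schz)] + [f"hc_{i}" for i in range(n_hc)]
    grp = {s: ("SCHZ" if s.startswith("schz") else "HC") for s in subs}
    cat_fx = dict(zip(CATS, [0.0, 0.01, -0.04, -0.08, -0.02]))
    inter = dict(zip(CATS, [0.0, 0.01, interaction, 0.01, 0.01]))
    u_s = dict(zip(subs, rng.normal(0, np.sqrt(tau_s), len(subs))))
    u_c = dict(zip(CATS, rng.normal(0, np.sqrt(tau_c), len(CATS))))
    rows = []
    for s in subs:
        for c in CATS:
            for i in range(n_per_cat):
                mu = (0.44 + (grp[s] == "SCHZ") * 0.01 + cat_fx[c]
                      + (grp[s] == "SCHZ") * inter[c] + u_s[s] + u_c[c])
                rows.append((s, grp[s], c, f"{c}_{i}",
                             mu + rng.normal(0, np.sqrt(sigma2))))
    return pd.DataFrame(rows, columns=["subject_id", "group", "category",
                                       "stimulus_id", "sqrt_nss"])


@pytest.fixture(scope="module")
def lmer_fixture_fit():
    table = _simulate_nss(np.random.default_rng(42))
    return fit_lme(table)


class TestFitLME:
    # Oracle values from an lme4 + lmerTest REML fit (Satterthwaite tests)
    # of the identical fixture (seed 42), frozen from:
    #   lmer(sqrt_nss ~ group*category + (1|subject_id) + (1|category))
    R_ESTIMATES = {
        "(Intercept)": 4.24531e-01,
        "SCHZ": 6.80668e-03,
        "incongruent": 1.67089e-02,
        "physically_salient": -2.80208e-02,
        "social_interaction": -6.17341e-02,
        "social_landscape": 4.90090e-02,
        "SCHZ x incongruent": -5.24808e-05,
        "SCHZ x physically_salient": 2.78453e-02,
        "SCHZ x social_interaction": -2.90808e-03,
        "SCHZ x social_landscape": 1.23094e-02,
    }
    R_SE_DF = {  # terms whose SE/df do not touch the unidentified category ridge
        "SCHZ": (0.0138573, 108.776),
        "SCHZ x incongruent": (0.0123164, 5239.0),
        "SCHZ x physically_salient": (0.0123164, 5239.0),
        "SCHZ x social_interaction": (0.0123164, 5239.0),
        "SCHZ x social_landscape": (0.0123164, 5239.0),
    }
    R_VC = {"residual": 2.0035e-02, "subject": 1.5344e-03}

    @pytest.fixture()
    def fit(self, lmer_fixture_fit):
        return lmer_fixture_fit

    def test_estimates_match_lmer_oracle(self, fit):
        got = dict(zip(fit.fixed_effects["term"], fit.fixed_effects["estimate"]))
        for term, ref in self.R_ESTIMATES.items():
            assert got[term] == pytest.approx(ref, abs=2e-5), term

    def test_se_and_satterthwaite_df_match_lmer_oracle(self, fit):
        fe = fit.fixed_effects.set_index("term")
        for term, (se, df) in self.R_SE_DF.items():
            assert fe.loc[term, "se"] == pytest.approx(se, abs=2e-4), term
            assert fe.loc[term, "df"] == pytest.approx(df, abs=1.0), term

    def test_variance_components_match_lmer_oracle(self, fit):
        assert fit.variance_components["residual"] == pytest.approx(
            self.R_VC["residual"], rel=1e-3)
        assert fit.variance_components["subject"] == pytest.approx(
            self.R_VC["subject"], rel=1e-2)

    def test_category_variance_flagged_unidentified(self, fit):
        # the category indicators lie inside the fixed-effect column space,
        # so REML is flat in that variance: pinned at zero, fit is singular
        assert fit.variance_components["category"] == 0.0
        assert fit.singular
        assert "category" in fit.optimizer["unidentified"]

    def test_icc_bookkeeping(self, fit):
        vc = fit.variance_components
        tau = vc["subject"] + vc["category"]
        assert fit.icc == pytest.approx(tau / (tau + vc["residual"]))
        assert 0 <= fit.r2_marginal <= fit.r2_conditional <= 1

    def test_collapses_to_ols_without_random_variance(self):
        rng = np.random.default_rng(7)
        table = _simulate_nss(rng, tau_s=0.0, tau_c=0.0, n_per_cat=10)
        res = fit_lme(table)
        # rebuild the same design and compare with plain least squares
        X = []
        for _, r in table.iterrows():
            g = 1.0 if r["group"] == "SCHZ" else 0.0
            cat = [1.0 if r["category"] == c else 0.0 for c in CATS[1:]]
            X.append([1.0, g] + cat + [g * c for c in cat])
        beta_ols, *_ = np.linalg.lstsq(np.asarray(X),
                                       table["sqrt_nss"].to_numpy(), rcond=None)
        np.testing.assert_allclose(
            res.fixed_effects["estimate"].to_numpy(), beta_ols, atol=1e-6)

    def test_interaction_recovery_at_cohort_scale(self):
        # bias of the group x physically_salient interaction < 10% of the
        # injected effect, and its 95% CI covers the truth in most replicates
        rng = np.random.default_rng(2024)
        true = 0.05
        estimates, covered = [], 0
        reps = 60
        for _ in range(reps):
            table = _simulate_nss(rng, n_per_cat=50)  # 50 images x 5 categories
            res = fit_lme(table)
            row = res.fixed_effects.set_index("term").loc["SCHZ x physically_salient"]
            estimates.append(row["estimate"])
            covered += row["ci_low"] <= true <= row["ci_high"]
        bias = np.mean(estimates) - true
        assert abs(bias) < 0.1 * true
        assert covered / reps >= 0.80

    def test_null_group_effect_ci_coverage(self):
        rng = np.random.default_rng(99)
        reps, covered = 50, 0
        for _ in range(reps):
            table = _simulate_nss(rng, n_per_cat=10, interaction=0.01)
            res = fit_lme(table)
            row = res.fixed_effects.set_index("term").loc["SCHZ"]
            covered += row["ci_low"] <= 0.01 <= row["ci_high"]
        assert covered / reps >= 0.86  # ~95% nominal, binomial noise allowed

    def test_requires_two_groups(self):
        table = _simulate_nss(np.random.default_rng(1), n_hc=0, n_per_cat=5)
        with pytest.raises(ValueError):
            fit_lme(table)


class TestSequentialDurationTest:
    @staticmethod
    def _means(group_arrays):
        rows = []
        for k, (a, b) in group_arrays.items():
            for i, v in enumerate(a):
                rows.append(("HC", f"hc_{i}", k, v))
            for i, v in enumerate(b):
                rows.append(("SCHZ", f"schz_{i}", k, v))
        return pd.DataFrame(rows, columns=["group", "subject_id", "fix_index",
                                           "mean_duration_ms"])

    def test_closed_rule_truncates_after_first_failure(self, rng):
        sep = lambda: (rng.normal(250, 5, 20), rng.normal(400, 5, 20))
        same = lambda: (rng.normal(300, 5, 20), rng.normal(300, 5, 20))
        means = self._means({1: sep(), 2: sep(), 3: same(), 4: sep()})
        res = sequential_duration_test(means)
        per = res.per_index.set_index("fix_index")
        assert per.loc[[1, 2], "rejected"].all()
        assert per.loc[4, "rejected"]  # raw test still reported
        assert per["declared_significant"].tolist() == [True, True, False, False]
        assert res.stop_index == 3

    def test_tested_range_ends_when_subjects_run_out(self, rng):
        means = self._means({1: (rng.normal(0, 1, 10), rng.normal(0, 1, 10)),
                             2: (rng.normal(0, 1, 1), rng.normal(0, 1, 10))})
        res = sequential_duration_test(means)
        assert res.per_index["fix_index"].tolist() == [1]

    @given(st.integers(0, 2**31 - 1))
    @settings(derandomize=True, max_examples=25)
    def test_declared_significance_never_resumes(self, seed):
        rng = np.random.default_rng(seed)
        means = self._means({
            k: (rng.normal(300, 30, 8), rng.normal(300 + rng.normal(0, 20), 30, 8))
            for k in range(1, 8)})
        res = sequential_duration_test(means)
        d = res.per_index["declared_significant"].to_numpy()
        assert (np.diff(d.astype(int)) <= 0).all()
        np.testing.assert_array_equal(
            d, np.cumprod(res.per_index["rejected"].to_numpy()).astype(bool))

    def test_group_curves_separate_then_converge(self, rng):
        # SCHZ-like vs HC-like duration curves: significant early, not after
        # the convergence region
        from gazesal.cohort import simulate_duration_table, study_group_params

        gp = study_group_params()
        tab = simulate_duration_table(gp, {"SCHZ": 28, "HC": 25}, 50, rng)
        res = sequential_duration_test(tab)
        per = res.per_index.set_index("fix_index")
        assert per.loc[1, "declared_significant"]
        assert per.loc[5, "declared_significant"]
        late = per.index[per.index >= gp["SCHZ"].dur_converge_index]
        assert not per.loc[late, "declared_significant"].any()


class TestTwoSampleSummary:
    def test_identical_groups(self):
        res = two_sample_summary_test(([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]))
        assert res.t_stat == 0.0 and res.p == pytest.approx(1.0)

    def test_separated_groups_p_vanishes(self, rng):
        a = rng.normal(0.0, 1e-4, 30)
        b = rng.normal(1.0, 1e-4, 30)
        res = two_sample_summary_test({"HC": a, "SCHZ": b})
        assert res.p < 1e-20

    def test_matches_permutation_oracle(self, rng):
        a = rng.normal(0.0, 1.0, 10)
        b = rng.normal(0.8, 1.0, 10)
        res = two_sample_summary_test((a, b))
        pooled = np.concatenate([a, b])
        obs = abs(a.mean() - b.mean())
        count = 0
        n_perm = 20_000
        for _ in range(n_perm):
            rng.shuffle(pooled)
            count += abs(pooled[:10].mean() - pooled[10:].mean()) >= obs
        p_perm = count / n_perm
        se = np.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert abs(res.p - p_perm) < 4 * se + 0.01

    def test_constant_groups_error(self):
        with pytest.raises(ValueError, match="zero variance"):
            two_sample_summary_test(([1.0, 1.0], [2.0, 2.0]))


class TestCorrelateClinical:
    def _ocu(self, n=10, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(n)],
            "group": ["SCHZ"] * n,
            "mean_fix_duration_ms": rng.normal(300, 30, n),
        })

    def test_exact_linear_relation(self):
        ocu = self._ocu()
        clin = pd.DataFrame({"subject_id": ocu["subject_id"],
                             "panss_total": 2 * ocu["mean_fix_duration_ms"]})
        out = correlate_clinical(ocu, clin)
        assert out["r"].iloc[0] == pytest.approx(1.0)

    def test_constant_column_unavailable(self):
        ocu = self._ocu()
        clin = pd.DataFrame({"subject_id": ocu["subject_id"], "dose": 5.0})
        out = correlate_clinical(ocu, clin)
        assert not out["available"].iloc[0]

    def test_missing_values_pairwise_deleted(self):
        ocu = self._ocu()
        clin = pd.DataFrame({"subject_id": ocu["subject_id"],
                             "cpt": np.r_[np.nan, np.nan,
                                          np.arange(8, dtype=float)]})
        out = correlate_clinical(ocu, clin)
        assert out["n"].iloc[0] == 8 and out["n_missing"].iloc[0] == 2

    def test_null_calibration_at_conservative_alpha(self, rng):
        # independent columns: |r| exceeds the alpha = 0.001 critical value
        # in about 0.1% of replicates (vectorized over 10^4 draws)
        n, reps = 30, 10_000
        x = rng.normal(size=(reps, n))
        y = rng.normal(size=(reps, n))
        xc = x - x.mean(1, keepdims=True)
        yc = y - y.mean(1, keepdims=True)
        r = (xc * yc).sum(1) / np.sqrt((xc**2).sum(1) * (yc**2).sum(1))
        t = r * np.sqrt((n - 2) / (1 - r**2))
        p = 2 * stats.t.sf(np.abs(t), n - 2)
        rate = (p < 0.001).mean()
        assert rate < 0.004
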