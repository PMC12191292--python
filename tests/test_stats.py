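"""Rank statistics, effect sizes, agreement, regression and the SFN plan."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drgpd._errors import ValidationError
from drgpd.stats import (
    binomial_null_deviance,
    cliffs_delta,
    delta_to_auc,
    icc_agreement,
    icc_consistency,
    ks_normality,
    linear_fit,
    logistic_fit,
    mann_whitney,
    roc_auc,
    sfn_analysis,
    spearman,
)

samples = st.lists(st.floats(-50, 50, allow_nan=False), min_size=2, max_size=15)


class TestMannWhitney:
    def test_exact_small_sample(self):
        u, p = mann_whitney([1, 2], [3, 4])
        assert u == 0
        assert p == pytest.approx(1 / 3)

    def test_identical_samples(self):
        u, p = mann_whitney([1, 2, 3, 4], [1, 2, 3, 4])
        assert p >= 0.99

    def test_exact_close_to_asymptotic_at_n50(self):
        from scipy import stats as sps

        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 50)
        y = rng.normal(0.3, 1, 50)
        _, p_asym = mann_whitney(x, y)  # n_x*n_y > 400 -> asymptotic
        p_exact = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        assert abs(p_asym - p_exact) < 0.005

    def test_group_exchange_invariance(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=12), rng.normal(0.5, 1, 9)
        assert mann_whitney(x, y)[1] == pytest.approx(mann_whitney(y, x)[1])

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney([], [1.0])


class TestCliffsDelta:
    def test_complete_separation(self):
        d, (lo, hi) = cliffs_delta([5, 6, 7], [1, 2, 3])
        assert d == 1.0

    def test_brute_force_example(self):
        d, _ = cliffs_delta([1, 2, 3], [2, 3, 4])
        assert d == pytest.approx((1 - 6) / 9)

    def test_identical_samples_give_zero(self):
        d, _ = cliffs_delta([1, 2, 3], [1, 2, 3])
        assert d == 0.0

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(x=samples, y=samples)
    def test_pair_count_oracle_and_sign_flip(self, x, y):
        """delta equals the direct O(nm) pair count and flips sign under
        group exchange; the CI stays inside [-1, 1] and contains delta."""
        d, (lo, hi) = cliffs_delta(x, y)
        brute = sum(np.sign(xi - yj) for xi in x for yj in y) / (len(x) * len(y))
        assert d == pytest.approx(brute, abs=1e-12)
        d2, _ = cliffs_delta(y, x)
        assert d2 == pytest.approx(-d, abs=1e-12)
        assert -1 <= lo <= d + 1e-12 and d - 1e-12 <= hi <= 1

    def test_bootstrap_ci_is_seeded(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(0.8, 1, 20), rng.normal(0, 1, 25)
        a = cliffs_delta(x, y, ci_method="bootstrap", seed=3)
        b = cliffs_delta(x, y, ci_method="bootstrap", seed=3)
        assert a == b


class TestAucDeltaIdentity:
    def test_published_worked_example(self):
        """The printed classical-phenotype effect size of 0.92 converts to
        the printed AUC of 0.96 under AUC = (delta+1)/2."""
        assert delta_to_auc(0.92) == pytest.approx(0.96)

    def test_endpoints(self):
        assert delta_to_auc(1.0) == 1.0
        assert delta_to_auc(0.0) == 0.5

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            delta_to_auc(1.2)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        x=st.lists(st.integers(0, 6), min_size=2, max_size=20),
        y=st.lists(st.integers(0, 6), min_size=2, max_size=20),
    )
    def test_identity_holds_with_ties(self, x, y):
        """Midrank AUC and pair-count delta agree to machine precision on
        arbitrary integer data with heavy ties."""
        scores = np.array(x + y, dtype=float)
        labels = np.array([1] * len(x) + [0] * len(y))
        auc = roc_auc(scores, labels).auc
        d, _ = cliffs_delta(np.array(x, float), np.array(y, float))
        assert abs(delta_to_auc(d) - auc) < 1e-12


class TestRoc:
    def test_perfect_separation(self):
        r = roc_auc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1])
        assert r.auc == 1.0
        assert np.all(np.diff(r.sensitivities) >= 0)

    def test_null_auc_band(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(size=2000)
        labels = (rng.random(2000) < 0.5).astype(int)
        assert 0.46 <= roc_auc(scores, labels).auc <= 0.54

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc([1, 2, 3], [1, 1, 1])


class TestSpearman:
    def test_hand_computed_example(self):
        rho, _ = spearman([1, 2, 3], [3, 1, 2])
        assert rho == pytest.approx(-0.5)

    def test_monotone_transform_gives_one(self):
        x = np.array([0.3, 1.2, 2.0, 5.5, 9.1])
        rho, _ = spearman(x, np.exp(x))
        assert rho == pytest.approx(1.0)
        rho, _ = spearman(x, -(x**3))
        assert rho == pytest.approx(-1.0)

    def test_constant_input_is_undefined(self):
        rho, p = spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert np.isnan(rho) and np.isnan(p)


def _icc_bruteforce(m):
    """Independent sums-of-squares oracle for ICC(2,1) on an n x k matrix."""
    n, k = m.shape
    grand = m.mean()
    msr = k * sum((m[i].mean() - grand) ** 2 for i in range(n)) / (n - 1)
    msc = n * sum((m[:, j].mean() - grand) ** 2 for j in range(k)) / (k - 1)
    sse = sum(
        (m[i, j] - m[i].mean() - m[:, j].mean() + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestIcc:
    def test_identical_raters(self):
        m = np.column_stack([np.arange(8.0), np.arange(8.0)])
        assert icc_agreement(m).icc == pytest.approx(1.0)

    def test_matches_variance_component_oracle(self):
        m = np.array(
            [[9, 2], [1, 10], [8, 9], [2, 6], [10, 6], [4, 8]], dtype=float
        )
        res = icc_agreement(m)
        assert res.icc == pytest.approx(_icc_bruteforce(m), abs=1e-10)
        rng = np.random.default_rng(13)
        for _ in range(20):
            m = rng.normal(size=(rng.integers(5, 12), 2)) + rng.normal(size=(1, 2))
            assert icc_agreement(m).icc == pytest.approx(_icc_bruteforce(m), abs=1e-10)

    def test_matches_pingouin_icc2(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(1)
        m = rng.normal(size=(12, 2)) * 2 + rng.normal(size=(12, 1)) * 3
        df = pd.DataFrame(
            {
                "s": np.repeat(np.arange(12), 2),
                "r": np.tile([0, 1], 12),
                "v": m.ravel(),
            }
        )
        ref = pg.intraclass_corr(df, targets="s", raters="r", ratings="v")
        ref = ref[ref["Type"] == "ICC(A,1)"].iloc[0] if "ICC(A,1)" in set(ref["Type"]) else ref.iloc[1]
        res = icc_agreement(m)
        assert res.icc == pytest.approx(float(ref["ICC"]), abs=1e-9)

    def test_agreement_penalises_rater_offset(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=20)
        m = np.column_stack([base, base + 4.0])
        assert icc_agreement(m).icc < icc_consistency(m)

    def test_incomplete_matrix_rejected(self):
        m = np.ones((6, 2))
        m[2, 1] = np.nan
        with pytest.raises(ValidationError):
            icc_agreement(m)


class TestLogisticFit:
    def test_two_by_two_closed_form(self):
        y = np.array([1] * 20 + [0] * 10 + [1] * 10 + [0] * 20)
        x = pd.DataFrame({"x": [1] * 30 + [0] * 30})
        fit = logistic_fit(x, y)
        slope = fit.table.loc[fit.table.term == "x", "estimate"].item()
        assert slope == pytest.approx(np.log(4.0), abs=1e-6)

    def test_random_two_by_two_tables(self):
        """MLE slope equals the closed-form log odds ratio for 100 random
        tables with all cells >= 5."""
        rng = np.random.default_rng(17)
        for _ in range(100):
            a, b, c, d = rng.integers(5, 40, 4)
            y = np.array([1] * a + [0] * b + [1] * c + [0] * d)
            x = pd.DataFrame({"x": [1] * (a + b) + [0] * (c + d)})
            fit = logistic_fit(x, y)
            slope = fit.table.loc[fit.table.term == "x", "estimate"].item()
            assert slope == pytest.approx(np.log(a * d / (b * c)), abs=1e-5)

    def test_constant_outcome_rejected(self):
        with pytest.raises(ValidationError):
            logistic_fit(pd.DataFrame({"x": [1.0, 2.0, 3.0]}), [1, 1, 1])

    def test_collinearity_names_columns(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=40)
        design = pd.DataFrame({"a": x, "b": 2 * x})
        y = (rng.random(40) < 0.5).astype(int)
        with pytest.raises(ValidationError, match="b"):
            logistic_fit(design, y)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(10)
        n = 5000
        x1, x2 = rng.normal(size=n), rng.normal(size=n)
        eta = 0.5 * x1 - 1.0 * x2
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        fit = logistic_fit(pd.DataFrame({"x1": x1, "x2": x2}), y)
        t = fit.table.set_index("term")
        for term, truth in [("x1", 0.5), ("x2", -1.0)]:
            assert abs(t.loc[term, "estimate"] - truth) < 3 * t.loc[term, "std_error"]

    def test_fit_statistics_mutually_consistent(self):
        """AIC = deviance + 2k, and McFadden R2 = 1 - (AIC - 2k)/null_dev."""
        rng = np.random.default_rng(2)
        n = 200
        x = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-x))).astype(int)
        fit = logistic_fit(pd.DataFrame({"x": x}), y)
        assert fit.aic == pytest.approx(fit.deviance + 2 * fit.k)
        assert fit.mcfadden_r2 == pytest.approx(
            1 - (fit.aic - 2 * fit.k) / fit.null_deviance
        )
        assert fit.null_deviance == pytest.approx(
            binomial_null_deviance(int(y.sum()), n)
        )
        # Wald z column is estimate / std_error by construction
        assert np.allclose(fit.table.z_or_t, fit.table.estimate / fit.table.std_error)

    def test_separation_flagged(self):
        y = np.array([0] * 10 + [1] * 10)
        x = pd.DataFrame({"x": np.arange(20.0)})
        fit = logistic_fit(x, y)
        assert fit.separation_flag


class TestLinearFit:
    def test_exact_linear_data(self):
        rng = np.random.default_rng(0)
        x = pd.DataFrame({"a": rng.normal(size=30), "b": rng.normal(size=30)})
        y = 2.0 + 1.5 * x["a"] - 0.5 * x["b"]
        fit = linear_fit(x, y)
        est = fit.table.set_index("term")["estimate"]
        assert est["const"] == pytest.approx(2.0, abs=1e-10)
        assert est["a"] == pytest.approx(1.5, abs=1e-10)
        assert fit.resid_var == pytest.approx(0.0, abs=1e-18)

    def test_duplicated_column_rejected(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=25)
        with pytest.raises(ValidationError):
            linear_fit(pd.DataFrame({"a": x, "b": x}), rng.normal(size=25))

    def test_parameter_recovery(self):
        rng = np.random.default_rng(6)
        n = 500
        x = rng.normal(size=n)
        y = 1.0 + 0.8 * x + rng.normal(0, 1, n)
        fit = linear_fit(pd.DataFrame({"x": x}), y)
        t = fit.table.set_index("term")
        assert abs(t.loc["x", "estimate"] - 0.8) < 3 * t.loc["x", "std_error"]


class TestKsNormality:
    def test_calibrated_under_normality(self):
        """With Monte-Carlo Lilliefors p-values the nominal 5% level is
        honoured: over 100 seeded normal samples of n=500 the rejection
        count stays near 5.  The bound (12) is the binomial ~97.5% envelope
        widened for the Monte-Carlo error of the shared 10,000-replicate
        null table, which correlates the p-values across draws.  The
        p-values themselves must also be consistent with uniformity."""
        from scipy import stats as sps

        rng = np.random.default_rng(0)
        ps = np.array(
            [ks_normality(rng.standard_normal(500))[1] for _ in range(100)]
        )
        assert (ps <= 0.05).sum() <= 12
        assert sps.kstest(ps, "uniform").pvalue > 1e-3

    def test_detects_exponential(self):
        rng = np.random.default_rng(1)
        d, p = ks_normality(rng.exponential(size=500))
        assert p < 0.01
        assert 0.0 <= d <= 1.0

    def test_constant_sample_degenerate(self):
        d, p = ks_normality(np.full(10, 3.0))
        assert np.isnan(d) and np.isnan(p)


class TestSfnAnalysis:
    @staticmethod
    def _toy_cohort(n=60, seed=0, separate_classical=False):
        rng = np.random.default_rng(seed)
        sex = np.where(rng.random(n) < 0.5, "m", "f")
        pheno = rng.choice(
            ["classical", "late_onset_benign", "VUS"], size=n, p=[0.3, 0.6, 0.1]
        )
        sfn = (rng.random(n) < 0.35).astype(int)
        drg_pd = rng.uniform(0.6, 0.75, n)
        if separate_classical:
            cls = pheno == "classical"
            drg_pd[cls & (sfn == 1)] = rng.uniform(0.80, 0.90, (cls & (sfn == 1)).sum())
            drg_pd[cls & (sfn == 0)] = rng.uniform(0.60, 0.70, (cls & (sfn == 0)).sum())
        return pd.DataFrame(
            {
                "id": [f"S{i}" for i in range(n)],
                "age": rng.uniform(20, 70, n),
                "sex": sex,
                "bmi": rng.uniform(19, 32, n),
                "phenotype": pheno,
                "alpha_gal": rng.uniform(0.02, 0.4, n),
                "lyso_gb3": rng.lognormal(1.5, 1, n),
                "ienfd_leg": rng.uniform(1, 9, n),
                "ienfd_thigh": rng.uniform(10, 30, n),
                "prior_fd_therapy": (rng.random(n) < 0.5).astype(int),
                "sfn": sfn,
                "pain_avg": rng.integers(0, 8, n),
                "pain_max": rng.integers(0, 10, n),
                "drg_pd": drg_pd,
                "drg_t2": rng.uniform(85, 110, n),
                "drg_vol": rng.uniform(700, 1600, n),
            }
        )

    def test_forced_separation_gives_delta_and_auc_one(self):
        res = sfn_analysis(self._toy_cohort(seed=3, separate_classical=True))
        gc = res["group_comparisons"][("classical", "drg_pd")]
        assert gc.delta == 1.0 and gc.delta_abs == 1.0
        assert res["roc"]["classical"].auc == 1.0

    def test_constant_sfn_emits_sentinels(self):
        cohort = self._toy_cohort(seed=1)
        cohort["sfn"] = 0
        res = sfn_analysis(cohort)
        assert all(v is None for v in res["group_comparisons"].values())
        assert res["logistic"] is None
        assert res["roc"]["classical"] is None

    def test_missing_column_listed(self):
        cohort = self._toy_cohort().drop(columns=["lyso_gb3", "drg_t2"])
        with pytest.raises(ValidationError, match="lyso_gb3"):
            sfn_analysis(cohort)

    def test_full_plan_structure(self):
        res = sfn_analysis(self._toy_cohort(seed=5))
        assert len(res["group_comparisons"]) == 27  # 9 strata x 3 metrics
        assert set(res["linear_models"]) == {"drg_vol", "drg_t2", "drg_pd"}
        assert res["logistic"].k == 10  # intercept + 9 covariates
        assert {"classical", "benign"} <= set(res["roc"])
        assert res["holm_p"] is None  # no adjustment by default

    def test_holm_option_never_decreases_p(self):
        res = sfn_analysis(self._toy_cohort(seed=5), holm=True)
        for key, adj in res["holm_p"].items():
            raw = res["group_comparisons"][key].p_value
            assert adj >= raw - 1e-12

    def test_standardize_flag_preserves_wald_z_of_continuous_terms(self):
        """Rescaling a continuous covariate changes its coefficient but not
        its Wald z, so the standardised fit reproduces the native-scale
        inference."""
        rng = np.random.default_rng(4)
        n = 300
        x = rng.normal(50, 10, n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(x - 50) / 10))).astype(int)
        raw = logistic_fit(pd.DataFrame({"x": x}), y)
        std = logistic_fit(pd.DataFrame({"x": x}), y, standardize=True)
        zr = raw.table.set_index("term").loc["x", "z_or_t"]
        zs = std.table.set_index("term").loc["x", "z_or_t"]
        assert zs == pytest.approx(zr, rel=1e-6)
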