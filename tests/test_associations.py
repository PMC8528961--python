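"""Association statistics against closed-form and enumeration oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from graftage.associations import (
    anova_nested,
    cohort_table,
    correlate,
    fit_linear,
    ratio_summary,
    sequential_models,
    two_group_test,
)
from graftage.errors import (
    CollinearityError,
    DegenerateDataError,
    PairingError,
    ValidationError,
)
from graftage.simulate import SimulationConfig, simulate_cohort


class TestCorrelate:
    def test_perfect_linearity(self):
        x = np.array([1.0, 2, 3, 4])
        r, r2, p = correlate(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_hand_computed_r(self):
        # closed form on x=(0,1,2), y=(0,1,3): r = 3/sqrt(2*14/3)... = 0.9820
        r, r2, p = correlate([0, 1, 2], [0, 1, 3])
        sxy = np.cov([0, 1, 2], [0, 1, 3])[0, 1]
        r_hand = sxy / (np.std([0, 1, 2], ddof=1) * np.std([0, 1, 3], ddof=1))
        assert r == pytest.approx(r_hand, abs=1e-12)
        assert r == pytest.approx(0.9820, abs=1e-4)

    def test_null_pvalues_uniform(self):
        """Under independence the correlation p-value is U(0, 1)."""
        rng = np.random.default_rng(12)
        pvals = [correlate(rng.normal(size=15), rng.normal(size=15))[2]
                 for _ in range(1000)]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateDataError):
            correlate([1, 1, 1], [0, 1, 2])


class TestFitLinear:
    def test_three_point_closed_form(self):
        fit = fit_linear([0, 1, 3], pd.DataFrame({"x": [0.0, 1, 2]}))
        assert fit.coef("x") == pytest.approx(1.5, abs=1e-12)
        assert fit.coef("intercept") == pytest.approx(-1 / 6, abs=1e-12)

    def test_exact_fit_zero_width_ci(self):
        fit = fit_linear([5.0, 5, 5, 5],
                         pd.DataFrame({"x": [0.0, 1, 2, 3]}))
        lo, hi = fit.ci("x")
        assert fit.coef("x") == pytest.approx(0.0, abs=1e-12)
        assert hi - lo == pytest.approx(0.0, abs=1e-10)

    def test_matches_normal_equations_on_random_designs(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n, p = rng.integers(6, 15), rng.integers(1, 4)
            X = rng.normal(size=(n, p))
            y = rng.normal(size=n)
            fit = fit_linear(y, pd.DataFrame(
                X, columns=[f"c{j}" for j in range(p)]))
            Xi = np.column_stack([np.ones(n), X])
            beta = np.linalg.solve(Xi.T @ Xi, Xi.T @ y)
            assert np.allclose(fit.params.to_numpy(), beta, atol=1e-10)
            rss = float(((y - Xi @ beta) ** 2).sum())
            assert fit.rss == pytest.approx(rss, abs=1e-10)

    def test_collinearity_names_aliased_columns(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8]})
        with pytest.raises(CollinearityError) as exc:
            fit_linear([1.0, 2, 3, 4], df)
        assert set(exc.value.aliased) >= {"a", "b"}

    def test_categorical_reference_is_alphabetical(self):
        df = pd.DataFrame({"grp": ["b", "a", "c", "a", "b", "c"]})
        fit = fit_linear([1.0, 0, 2, 0, 1, 2], df)
        assert "grp[b]" in fit.params.index
        assert "grp[c]" in fit.params.index
        assert "grp[a]" not in fit.params.index  # reference level

    def test_anova_matches_rss_closed_form(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 2))
        y = X[:, 0] + rng.normal(size=20)
        small = fit_linear(y, pd.DataFrame({"x1": X[:, 0]}))
        big = fit_linear(y, pd.DataFrame({"x1": X[:, 0], "x2": X[:, 1]}))
        f, p = anova_nested(small, big)
        f_hand = ((small.rss - big.rss) / 1) / (big.rss / big.df_resid)
        assert f == pytest.approx(f_hand, abs=1e-12)
        assert p == pytest.approx(stats.f.sf(f_hand, 1, big.df_resid),
                                  abs=1e-12)


class TestTwoGroupTest:
    def test_exact_mann_whitney_small_example(self):
        _, p = two_group_test([1, 2, 3, 4], [0, 0, 1, 1],
                              mode="mann_whitney")
        assert p == pytest.approx(1 / 3, abs=1e-12)

    def test_all_ties_give_p_one(self):
        _, p = two_group_test([2.0, 2, 2, 2], [0, 0, 1, 1],
                              mode="mann_whitney")
        assert p == 1.0

    def test_paired_wilcoxon_zero_differences(self):
        stat, p = two_group_test(
            [1.0, 2, 3, 1, 2, 3], [0, 0, 0, 1, 1, 1],
            mode="wilcoxon_paired", pair_id=["a", "b", "c", "a", "b", "c"])
        assert p == 1.0

    def test_paired_requires_matching_ids(self):
        with pytest.raises(PairingError):
            two_group_test([1.0, 2, 3, 4], [0, 0, 1, 1],
                           mode="wilcoxon_paired",
                           pair_id=["a", "b", "a", "c"])

    def test_auto_routes_by_normality(self):
        rng = np.random.default_rng(0)
        normal = np.concatenate([rng.normal(0, 1, 30), rng.normal(0, 1, 30)])
        grp = np.repeat([0, 1], 30)
        stat, _ = two_group_test(normal, grp, mode="auto")
        t_stat, _ = two_group_test(normal, grp, mode="t")
        assert stat == t_stat


class TestSequentialModels:
    def test_rss_non_increasing_and_shape(self, default_cohort):
        meth = 0.38 * default_cohort.truth.epigenetic_age
        ladder = sequential_models(default_cohort.samples, meth)
        rss = [f.rss for f in ladder.fits]
        assert all(b <= a + 1e-9 for a, b in zip(rss, rss[1:]))
        frame = ladder.to_frame()
        assert list(frame["model"])[0] == "PGD"
        assert len(frame) == 4
        assert len(ladder.anova_p) == 3

    def test_pgd_coefficient_stable_without_covariate_effects(self):
        """When no covariate influences age, the PGD estimate should not
        drift systematically across the ladder."""
        drifts = []
        for k in range(40):
            cohort = simulate_cohort(SimulationConfig(seed=4000 + k))
            ladder = sequential_models(cohort.samples,
                                       cohort.truth.epigenetic_age)
            # compare donor-age-adjusted model vs fully adjusted model
            drifts.append(ladder.fits[3].coef("pgd")
                          - ladder.fits[1].coef("pgd"))
        assert abs(np.mean(drifts)) < 0.8

    def test_donor_age_confounding_attenuates_pgd(self):
        """If PGD grafts come from older donors, adjusting for donor age
        must pull the PGD coefficient down — the study's own pattern."""
        rng = np.random.default_rng(1)
        n = 60
        pgd = np.repeat([False, True], n // 2)
        donor = np.where(pgd, rng.uniform(45, 65, n), rng.uniform(20, 40, n))
        age = donor + 5.0 * pgd + rng.normal(0, 3, n)
        df = pd.DataFrame({"pgd": pgd, "donor_age": donor})
        fit0 = fit_linear(age, df[["pgd"]])
        fit1 = fit_linear(age, df[["pgd", "donor_age"]])
        assert fit1.coef("pgd") < fit0.coef("pgd") - 5

    def test_missing_covariate_is_explicit_error(self, default_cohort):
        table = default_cohort.samples
        crippled = table.data.drop(columns=["donor_bmi"])
        from graftage.io import SampleTable
        with pytest.raises(ValidationError, match="donor_bmi"):
            sequential_models(SampleTable(crippled),
                              default_cohort.truth.epigenetic_age)


class TestCohortTable:
    def test_routing_calibration(self):
        """Normal draws go to the t-test in >= 90% of seeds; log-normal
        draws go to Mann-Whitney in most."""
        from graftage.io import SampleTable
        t_count = mw_count = 0
        n_seeds = 50
        for k in range(n_seeds):
            rng = np.random.default_rng(k)
            base = pd.DataFrame({
                "sample_id": [f"s{i}" for i in range(30)],
                "donor_age": np.full(30, 40.0),
                "recipient_age": np.full(30, 55.0),
                "pgd": np.repeat([False, True], 15),
                "batch": ["b1"] * 30,
                "entry_time": np.full(30, 365.0),
                "event_time": np.full(30, 900.0),
                "event": [False] * 30,
                "gauss": rng.normal(0, 1, 30),
                "skewed": np.exp(rng.normal(0, 1, 30)),
            })
            rows = cohort_table(SampleTable(base),
                                variables=["gauss", "skewed"]).to_frame()
            t_count += rows.set_index("variable").loc["gauss", "test"] == "t"
            mw_count += (rows.set_index("variable").loc["skewed", "test"]
                         == "mann_whitney")
        assert t_count >= 0.9 * n_seeds
        assert mw_count > 0.6 * n_seeds

    def test_chi_squared_on_printed_style_counts(self):
        table = [[6, 9], [9, 4]]
        res = stats.chi2_contingency(table, correction=True)
        assert res.pvalue > 0.05
        from graftage.io import SampleTable
        sex = ["F"] * 6 + ["M"] * 9 + ["F"] * 9 + ["M"] * 4
        df = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(28)],
            "donor_age": np.full(28, 40.0),
            "recipient_age": np.full(28, 55.0),
            "pgd": [False] * 15 + [True] * 13,
            "batch": ["b1"] * 28,
            "entry_time": np.full(28, 365.0),
            "event_time": np.full(28, 900.0),
            "event": [False] * 28,
            "recipient_sex": sex,
        })
        rows = cohort_table(SampleTable(df),
                            variables=["recipient_sex"]).to_frame()
        assert rows.iloc[0]["p"] == pytest.approx(res.pvalue, abs=1e-12)

    def test_single_level_categorical_reported_without_test(self, default_cohort):
        table = default_cohort.samples
        df = table.data.copy()
        df["double_lung"] = "yes"
        from graftage.io import SampleTable
        rows = cohort_table(SampleTable(df),
                            variables=["double_lung"]).to_frame()
        assert np.isnan(rows.iloc[0]["p"])


class TestRatioSummary:
    def test_identity_ratio(self):
        ages = np.array([10.0, 20, 30])
        med, (q1, q3) = ratio_summary(ages, ages)
        assert med == 1.0
        assert q3 - q1 == 0.0

    def test_odd_n_median(self):
        med, _ = ratio_summary(np.array([0.2, 0.4, 0.6]),
                               np.array([1.0, 1.0, 1.0]))
        assert med == pytest.approx(0.4)

    def test_zero_graft_age_rejected(self):
        with pytest.raises(ValidationError):
            ratio_summary([1.0, 2.0], [1.0, 0.0])
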