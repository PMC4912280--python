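"""Statistical operations vs brute-force oracles and known conventions."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import neckquant as nq
from neckquant import ObserverPairSet
from neckquant.cohort_stats import logrank_statistic, cox_partial_loglik, simulate_survival
from neckquant.errors import (
    DegenerateDataError,
    InputError,
    SampleError,
    SchemaError,
)


# --------------------------------------------------------------------------
# brute-force oracles (pure-python, loop-based; independent of the package)
# --------------------------------------------------------------------------

def icc_a1_bruteforce(o1, o2):
    data = [[float(a), float(b)] for a, b in zip(o1, o2)]
    n, k = len(data), 2
    grand = sum(sum(r) for r in data) / (n * k)
    row_means = [sum(r) / k for r in data]
    col_means = [sum(r[j] for r in data) / n for j in range(k)]
    msr = k * sum((m - grand) ** 2 for m in row_means) / (n - 1)
    msc = n * sum((m - grand) ** 2 for m in col_means) / (k - 1)
    mse = sum(
        (data[i][j] - row_means[i] - col_means[j] + grand) ** 2
        for i in range(n)
        for j in range(k)
    ) / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))


def midranks(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for idx in order[i : j + 1]:
            ranks[idx] = avg
        i = j + 1
    return ranks


def spearman_bruteforce(x, y):
    rx, ry = midranks(list(x)), midranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


def mannwhitney_u_bruteforce(x, y):
    u = 0.0
    for a in x:
        for b in y:
            u += 1.0 if a > b else (0.5 if a == b else 0.0)
    return u


def kruskal_bruteforce(samples):
    pooled = [v for s in samples for v in s]
    ranks = midranks(pooled)
    big_n = len(pooled)
    idx = 0
    h = 0.0
    for s in samples:
        r = sum(ranks[idx : idx + len(s)])
        idx += len(s)
        h += r * r / len(s)
    h = 12.0 / (big_n * (big_n + 1)) * h - 3.0 * (big_n + 1)
    # tie correction
    seen = {}
    for v in pooled:
        seen[v] = seen.get(v, 0) + 1
    correction = 1.0 - sum(t**3 - t for t in seen.values()) / (big_n**3 - big_n)
    return h / correction


def logrank_bruteforce(times, events, groups):
    levels = sorted(set(groups), key=str)
    o_minus_e, var = 0.0, 0.0
    for t in sorted({times[i] for i in range(len(times)) if events[i] == 1}):
        risk = [i for i in range(len(times)) if times[i] >= t]
        dead = [i for i in risk if times[i] == t and events[i] == 1]
        n, d = len(risk), len(dead)
        n1 = sum(1 for i in risk if groups[i] == levels[0])
        d1 = sum(1 for i in dead if groups[i] == levels[0])
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (o_minus_e**2 / var) if var > 0 else 0.0


# --------------------------------------------------------------------------
# agreement
# --------------------------------------------------------------------------

def _pairs(o1, o2):
    return ObserverPairSet(tuple(range(len(o1))), np.asarray(o1), np.asarray(o2))


class TestICC:
    def test_perfect_agreement(self):
        o = np.array([10.0, 12.0, 15.0, 20.0, 7.0])
        res = nq.icc_absolute_agreement(_pairs(o, o.copy()))
        assert res.icc == pytest.approx(1.0)

    def test_independent_raters_near_zero(self):
        rng = np.random.default_rng(99)
        o1, o2 = rng.normal(size=10_000), rng.normal(size=10_000)
        res = nq.icc_absolute_agreement(_pairs(o1, o2))
        assert abs(res.icc) <= 0.05

    def test_six_subject_anova_oracle(self):
        o1 = [10.0, 12.0, 9.0, 14.0, 11.0, 13.0]
        o2 = [10.5, 11.0, 9.5, 15.0, 10.0, 13.5]
        res = nq.icc_absolute_agreement(_pairs(o1, o2))
        assert res.icc == pytest.approx(icc_a1_bruteforce(o1, o2), rel=1e-12)

    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(3)
        o1 = rng.normal(100, 20, 30)
        o2 = o1 + rng.normal(0, 5, 30)
        res = nq.icc_absolute_agreement(_pairs(o1, o2))
        assert res.icc_ci[0] <= res.icc <= res.icc_ci[1]

    def test_degenerate_identical_table(self):
        with pytest.warns(UserWarning):
            res = nq.icc_absolute_agreement(_pairs([5.0] * 4, [5.0] * 4))
        assert res.icc == 1.0

    def test_too_few_subjects(self):
        with pytest.raises(SampleError):
            nq.icc_absolute_agreement(_pairs([1.0, 2.0], [1.0, 2.0]))

    def test_matches_pingouin_icc_a1(self):
        import pingouin as pg

        rng = np.random.default_rng(55)
        o1 = rng.normal(660, 266, 15)
        o2 = o1 + rng.normal(4, 13, 15)
        res = nq.icc_absolute_agreement(_pairs(o1, o2))
        df = pd.DataFrame({
            "subj": np.repeat(np.arange(15), 2),
            "rater": ["a", "b"] * 15,
            "y": np.column_stack([o1, o2]).ravel(),
        })
        row = pg.intraclass_corr(df, "subj", "rater", "y").set_index("Type").loc["ICC(A,1)"]
        assert res.icc == pytest.approx(row.ICC, rel=1e-12)
        assert res.icc_p == pytest.approx(row.pval, rel=1e-9)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        n=st.integers(min_value=5, max_value=10),
        seed=st.integers(min_value=0, max_value=10_000),
    )
    def test_matches_bruteforce_on_random_tables(self, n, seed):
        rng = np.random.default_rng(seed)
        o1 = rng.normal(50, 10, n)
        o2 = o1 + rng.normal(1, 4, n)
        res = nq.icc_absolute_agreement(_pairs(o1, o2))
        assert res.icc == pytest.approx(icc_a1_bruteforce(o1, o2), rel=1e-10)


class TestBlandAltman:
    def test_identical_observers(self):
        res = nq.bland_altman(_pairs([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]))
        assert res.bias == 0.0
        assert res.fixed_bias_p == 1.0

    def test_constant_offset(self):
        res = nq.bland_altman(_pairs([6.0, 7.0, 8.0], [1.0, 2.0, 3.0]))
        assert res.bias == 5.0
        assert res.loa == (5.0, 5.0)
        assert res.fixed_bias_p == 0.0

    def test_recovers_simulated_interobserver_bias(self):
        """d ~ N(4.17, 13.35) over 70 subjects: bias estimate within its t-CI."""
        rng = np.random.default_rng(20260927)
        base = rng.normal(660, 266, 70)
        d = rng.normal(4.17, 13.35, 70)
        res = nq.bland_altman(_pairs(base, base - d))
        half = stats.t.ppf(0.975, 69) * res.bias_sd / math.sqrt(70)
        assert abs(res.bias - 4.17) <= half

    def test_loa_cover_95pct_of_normal_differences(self):
        rng = np.random.default_rng(8)
        base = rng.normal(600, 100, 10_000)
        d = rng.normal(0, 10, 10_000)
        res = nq.bland_altman(_pairs(base, base - d))
        inside = np.mean((d >= res.loa[0]) & (d <= res.loa[1]))
        assert inside == pytest.approx(0.95, abs=0.01)


# --------------------------------------------------------------------------
# correlation / categorisation / groups / quartiles
# --------------------------------------------------------------------------

class TestSpearman:
    def test_monotone_up(self):
        rho, _ = nq.spearman_rho([1, 2, 3, 4], [10, 20, 25, 90])
        assert rho == 1.0

    def test_monotone_down(self):
        rho, _ = nq.spearman_rho([1, 2, 3, 4], [9, 7, 5, 2])
        assert rho == -1.0

    def test_midrank_oracle_with_tie(self):
        x = [3.0, 1.0, 4.0, 1.0, 5.0, 9.0, 2.0, 6.0]
        y = [2.0, 7.0, 1.0, 8.0, 2.0, 8.0, 1.0, 9.0]
        rho, _ = nq.spearman_rho(x, y)
        assert rho == pytest.approx(spearman_bruteforce(x, y), rel=1e-12)

    def test_zero_variance(self):
        with pytest.raises(DegenerateDataError):
            nq.spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestBMI:
    @pytest.mark.parametrize(
        "bmi,cat",
        [(24.9, "normal_or_under"), (25.0, "overweight"), (29.9, "overweight"),
         (30.0, "obese"), (18.0, "normal_or_under"), (45.0, "obese")],
    )
    def test_who_cutoffs(self, bmi, cat):
        assert nq.bmi_category(bmi) == cat

    def test_nonpositive(self):
        with pytest.raises(InputError):
            nq.bmi_category(0.0)


class TestGroupCompare:
    def test_all_identical_values_convention(self):
        res = nq.group_compare([5.0] * 6, ["a", "a", "a", "b", "b", "b"])
        assert res["statistic"] == 0.0 and res["p"] == 1.0

    def test_two_groups_no_overlap_exact(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [10.0, 11.0, 12.0, 13.0, 14.0]
        res = nq.group_compare(x + y, ["a"] * 5 + ["b"] * 5)
        assert res["test"] == "mann_whitney_u"
        assert res["statistic"] in (0.0, 25.0)
        assert res["p"] == pytest.approx(2.0 / 252.0, rel=1e-12)

    def test_mwu_statistic_matches_pair_count_oracle(self):
        rng = np.random.default_rng(4)
        x, y = rng.integers(0, 8, 9).astype(float), rng.integers(0, 8, 7).astype(float)
        res = nq.group_compare(np.concatenate([x, y]), ["a"] * 9 + ["b"] * 7)
        assert res["statistic"] == pytest.approx(mannwhitney_u_bruteforce(x, y), rel=1e-12)

    def test_kruskal_matches_ranksum_oracle(self):
        samples = [[1.0, 5.0, 8.0], [2.0, 2.0, 9.0], [3.0, 7.0, 4.0]]
        values = [v for s in samples for v in s]
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        res = nq.group_compare(values, groups)
        assert res["test"] == "kruskal_wallis"
        assert res["statistic"] == pytest.approx(kruskal_bruteforce(samples), rel=1e-10)

    def test_single_group_rejected(self):
        with pytest.raises(InputError):
            nq.group_compare([1.0, 2.0], ["a", "a"])


class TestQuartileSplit:
    def test_one_to_eight(self):
        labels, thr = nq.top_quartile_split(np.arange(1.0, 9.0))
        assert list(np.flatnonzero(labels == "upper_quartile")) == [6, 7]

    def test_all_equal_degenerate(self):
        with pytest.warns(UserWarning):
            labels, _ = nq.top_quartile_split([3.0] * 8)
        assert (labels == "upper_quartile").all()

    def test_cohort_sized_split(self):
        rng = np.random.default_rng(0)
        labels, _ = nq.top_quartile_split(rng.lognormal(math.log(29.6), 0.55, 519))
        assert (labels == "upper_quartile").sum() in (129, 130)

    def test_too_small(self):
        with pytest.raises(SampleError):
            nq.top_quartile_split([1.0, 2.0, 3.0])


# --------------------------------------------------------------------------
# survival
# --------------------------------------------------------------------------

class TestLogrank:
    def test_identical_groups_zero(self):
        t = np.array([5.0, 8.0, 12.0, 5.0, 8.0, 12.0])
        e = np.array([1, 0, 1, 1, 0, 1])
        g = np.array(["a", "a", "a", "b", "b", "b"])
        chi2, p = logrank_statistic(t, e, g)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_toy_table_matches_bruteforce(self):
        t = [6.0, 7.0, 10.0, 15.0, 19.0, 25.0]
        e = [1, 1, 0, 1, 1, 1]
        g = ["a", "b", "a", "b", "a", "b"]
        chi2, _ = logrank_statistic(t, e, g)
        assert chi2 == pytest.approx(logrank_bruteforce(t, e, g), rel=1e-12)

    def test_relabel_invariance(self):
        rng = np.random.default_rng(6)
        t = rng.exponential(50, 40).round(1)
        e = rng.integers(0, 2, 40)
        g = rng.choice(["x", "y"], 40)
        if e.sum() == 0:
            e[0] = 1
        a, _ = logrank_statistic(t, e, g)
        swapped = np.where(g == "x", "y", "x")
        b, _ = logrank_statistic(t, e, swapped)
        assert a == pytest.approx(b, rel=1e-12)

    def test_no_events_error(self):
        with pytest.raises(DegenerateDataError):
            logrank_statistic([1.0, 2.0], [0, 0], ["a", "b"])

    def test_km_all_censored_constant_one(self):
        rep = nq.km_logrank([10.0, 20.0, 30.0, 5.0], [0, 0, 0, 1],
                            ["a", "a", "a", "b"])
        assert all(s == 1.0 for s in rep["curves"]["a"]["s"])


class TestCox:
    def test_two_subject_closed_form_partial_likelihood(self):
        """One risk set: ll(beta) = beta*x1 - log(exp(beta*x1) + exp(beta*x2))."""
        t, e, x = [1.0, 2.0], [1, 0], [0.7, -0.3]
        for beta in (-0.5, 0.0, 0.3, 1.2):
            expected = beta * 0.7 - math.log(math.exp(beta * 0.7) + math.exp(beta * -0.3))
            assert cox_partial_loglik(t, e, x, beta) == pytest.approx(expected, rel=1e-12)

    def test_null_simulation_hr_near_one(self):
        rng = np.random.default_rng(2026)
        z = rng.integers(0, 2, 2000).astype(float)
        t, e = simulate_survival(z, 0.0, 0.4, rng)
        fit = nq.cox_univariate(t, e, z)
        assert 0.9 <= fit.hr <= 1.1

    def test_parameter_recovery(self):
        rng = np.random.default_rng(21)
        z = rng.integers(0, 2, 1000).astype(float)
        t, e = simulate_survival(z, 0.7, 0.4, rng)
        fit = nq.cox_univariate(t, e, z)
        assert abs(fit.beta - 0.7) <= 0.15
        assert fit.hr_ci[0] <= fit.hr <= fit.hr_ci[1]

    def test_covariate_scaling_invariance(self):
        rng = np.random.default_rng(31)
        z = rng.normal(size=400)
        t, e = simulate_survival(z, 0.5, 0.5, rng)
        fit1 = nq.cox_univariate(t, e, z)
        fit10 = nq.cox_univariate(t, e, 10.0 * z)
        assert fit10.beta == pytest.approx(fit1.beta / 10.0, rel=1e-6)

    def test_matches_lifelines_on_tie_free_data(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(41)
        z = rng.normal(size=300)
        age = rng.normal(60, 10, 300)
        t, e = simulate_survival(z, 0.4, 0.5, rng)
        fit = nq.cox_univariate(t, e, z, adjusters={"age": age})
        cph = CoxPHFitter().fit(
            pd.DataFrame({"t": t, "e": e, "z": z, "age": age}), "t", "e"
        )
        assert fit.beta == pytest.approx(cph.params_["z"], abs=1e-5)
        assert fit.se == pytest.approx(cph.standard_errors_["z"], abs=1e-5)

    def test_constant_covariate_rejected(self):
        with pytest.raises(InputError):
            nq.cox_univariate([1.0, 2.0, 3.0], [1, 1, 0], [2.0, 2.0, 2.0])


class TestIccSampleSize:
    def test_internal_consistency_of_search(self):
        """The returned n is the first whose expected CI width meets the target."""
        out = nq.icc_sample_size(0.9, 0.1, 2)
        n = out["n"]

        def width(m):
            f_exp = (1 + 0.9) / (1 - 0.9)
            q1 = stats.f.ppf(0.975, m - 1, m - 1)
            lo = (f_exp / q1 - 1) / (f_exp / q1 + 1)
            hi = (f_exp * q1 - 1) / (f_exp * q1 + 1)
            return hi - lo

        assert width(n) <= 0.1 < width(n - 1)

    def test_monotone_in_width(self):
        assert nq.icc_sample_size(0.9, 0.2, 2)["n"] <= nq.icc_sample_size(0.9, 0.1, 2)["n"]

    def test_more_raters_need_fewer_subjects(self):
        assert nq.icc_sample_size(0.9, 0.1, 3)["n"] <= nq.icc_sample_size(0.9, 0.1, 2)["n"]

    def test_domain_errors(self):
        with pytest.raises(InputError):
            nq.icc_sample_size(1.2, 0.1, 2)


# --------------------------------------------------------------------------
# cohort composition
# --------------------------------------------------------------------------

class TestDescribeCategorical:
    def test_counts_and_percentages(self):
        res = nq.describe_categorical(["f"] * 25 + ["m"] * 45)
        by = {r["level"]: r for r in res}
        assert by["f"]["pct"] == 35.7 and by["m"]["pct"] == 64.3


class TestSimulateCohort:
    def test_event_fraction_near_target(self):
        df = nq.simulate_cohort(n=2000, seed=1, target_event_frac=0.2)
        assert df["died"].mean() == pytest.approx(0.2, abs=0.03)

    def test_natv_bmi_correlated(self):
        df = nq.simulate_cohort(n=2000, seed=2)
        rho, p = nq.spearman_rho(df["natv_cc"], df["bmi"])
        assert 0.5 <= rho <= 0.8 and p < 1e-10

    def test_reproducible(self):
        a = nq.simulate_cohort(n=100, seed=3)
        b = nq.simulate_cohort(n=100, seed=3)
        pd.testing.assert_frame_equal(a, b)


class TestRunCohortAnalysis:
    def test_missing_columns_listed(self):
        df = nq.simulate_cohort(n=50, seed=4).drop(columns=["age", "bmi"])
        with pytest.raises(SchemaError) as err:
            nq.run_cohort_analysis(df)
        assert set(err.value.missing) == {"age", "bmi"}

    def test_duplicated_pairs_give_icc_one(self):
        df = nq.simulate_cohort(n=70, seed=5)
        pairs = _pairs(df["natv_cc"], df["natv_cc"].copy())
        report = nq.run_cohort_analysis(df, pairs)
        assert report["agreement"]["icc"] == pytest.approx(1.0)

    def test_planted_quartile_hazard_recovered(self):
        df = nq.simulate_cohort(n=519, seed=6, planted="quartile",
                                log_hr=math.log(2.0), target_event_frac=35 / 519)
        report = nq.run_cohort_analysis(df)
        fit = report["cox"]["upper_quartile_crude"]
        assert fit["hr_ci"][0] <= fit["hr"] <= fit["hr_ci"][1]
        assert fit["hr_ci"][0] <= 2.0 <= fit["hr_ci"][1]

    def test_report_blocks_present(self):
        df = nq.simulate_cohort(n=200, seed=7)
        report = nq.run_cohort_analysis(df)
        for key in ("descriptives", "correlations", "bmi_groups", "quartile",
                    "km_logrank", "cox"):
            assert key in report
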