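"""Cox/logrank adjacent-group comparisons, the correlated C-index test,
and the association measures."""

import numpy as np
import pandas as pd
import pytest

from eaccd.evaluation import (
    adjacent_cox,
    compare_c,
    comparison_table,
    cross_tabulate,
    risk_category_distribution,
    spearman_midrank,
    two_group_cox,
)
from eaccd.selection import harrell_c


def two_arm_sample(rng, n=300, hr=1.5, base=0.01, censor_at=120.0):
    t0 = rng.exponential(1 / base, n)
    t1 = rng.exponential(1 / (base * hr), n)
    times = np.concatenate([t0, t1]).clip(max=censor_at)
    events = (np.concatenate([t0, t1]) < censor_at).astype(int)
    x = np.repeat([0, 1], n)
    return times, events, x


class TestTwoGroupCox:
    def test_identical_groups_null(self):
        rng = np.random.default_rng(60)
        t = rng.exponential(50, 100).clip(max=100)
        e = (t < 100).astype(int)
        times = np.concatenate([t, t])
        events = np.concatenate([e, e])
        groups = np.repeat([1, 2], 100)
        (cmp,) = adjacent_cox(times, events, groups)
        assert cmp.hazard_ratio == pytest.approx(1.0, abs=1e-8)
        assert cmp.logrank_p == pytest.approx(1.0, abs=1e-12)

    def test_recovers_planted_hazard_ratio(self):
        rng = np.random.default_rng(61)
        times, events, x = two_arm_sample(rng, n=2000, hr=1.5)
        beta, se = two_group_cox(times, events, x)
        assert abs(np.exp(beta) - 1.5) < 0.1

    @pytest.mark.parametrize("ties", ["breslow", "efron"])
    def test_matches_independent_references(self, ties):
        import statsmodels.api as sm

        rng = np.random.default_rng(62)
        times, events, x = two_arm_sample(rng, n=150, hr=2.0)
        times = np.round(times)  # force heavy ties
        times[times == 0] = 0.5
        beta, se = two_group_cox(times, events, x, ties=ties)
        ref = sm.PHReg(times, x.reshape(-1, 1), status=events, ties=ties).fit()
        assert beta == pytest.approx(ref.params[0], abs=1e-6)
        assert se == pytest.approx(ref.bse[0], abs=1e-6)
        if ties == "efron":  # second, independent reference
            from lifelines import CoxPHFitter

            df = pd.DataFrame({"t": times, "e": events, "x": x})
            fitter = CoxPHFitter().fit(df, duration_col="t", event_col="e")
            assert beta == pytest.approx(fitter.params_["x"], abs=1e-6)
            assert se == pytest.approx(fitter.standard_errors_["x"], abs=1e-6)

    def test_label_swap_inverts_hazard_ratio(self):
        rng = np.random.default_rng(63)
        times, events, x = two_arm_sample(rng, n=200, hr=2.0)
        b1, _ = two_group_cox(times, events, x)
        b2, _ = two_group_cox(times, events, 1 - x)
        assert b1 == pytest.approx(-b2, abs=1e-10)

    def test_no_events_inestimable(self):
        with pytest.raises(ValueError):
            two_group_cox([1.0, 2.0], [0, 0], [0, 1])

    def test_monotone_likelihood_flagged(self):
        # all events in one arm
        times = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        events = np.array([1, 1, 1, 0, 0, 0])
        x = np.array([1, 1, 1, 0, 0, 0])
        with pytest.raises(ValueError):
            two_group_cox(times, events, x)
        cmps = adjacent_cox(times, events, x + 1)
        assert not cmps[0].estimable and np.isnan(cmps[0].hazard_ratio)

    def test_report_schema(self):
        rng = np.random.default_rng(64)
        times, events, x = two_arm_sample(rng, n=100)
        table = comparison_table(adjacent_cox(times, events, x + 1))
        assert list(table.columns) == ["groups_compared", "hr", "hr_lo", "hr_hi", "hr_p", "logrank_p"]
        assert table["groups_compared"].tolist() == ["2 vs 1"]


class TestCompareC:
    def test_identical_scores(self):
        rng = np.random.default_rng(70)
        t = rng.exponential(50, 80)
        e = rng.integers(0, 2, 80)
        e[:5] = 1
        s = rng.normal(size=80)
        res = compare_c(t, e, s, s)
        assert res.difference == 0.0 and res.p_value == 1.0

    def test_c_estimates_match_harrell_c(self):
        rng = np.random.default_rng(71)
        t = rng.exponential(50, 120)
        e = rng.integers(0, 2, 120)
        e[:5] = 1
        sa, sb = rng.normal(size=120), rng.normal(size=120)
        res = compare_c(t, e, sa, sb)
        assert res.c_a == pytest.approx(harrell_c(t, e, sa), abs=1e-12)
        assert res.c_b == pytest.approx(harrell_c(t, e, sb), abs=1e-12)
        assert res.ci_low <= res.difference <= res.ci_high

    def test_jackknife_agrees_with_ustat(self):
        rng = np.random.default_rng(72)
        t = rng.exponential(50, 200)
        e = rng.integers(0, 2, 200)
        e[:5] = 1
        sa = -t + rng.normal(scale=20, size=200)
        sb = -t + rng.normal(scale=40, size=200)
        r1 = compare_c(t, e, sa, sb, method="ustat")
        r2 = compare_c(t, e, sa, sb, method="jackknife")
        assert r1.difference == r2.difference
        assert abs(r1.se - r2.se) / r2.se < 0.10

    def test_variance_close_to_bootstrap(self):
        rng = np.random.default_rng(73)
        n = 250
        t = rng.exponential(50, n)
        e = (rng.random(n) < 0.8).astype(int)
        e[:3] = 1
        sa = -t + rng.normal(scale=25, size=n)
        sb = rng.normal(size=n)
        res = compare_c(t, e, sa, sb)
        boots = []
        for _ in range(400):
            idx = rng.integers(0, n, n)
            try:
                boots.append(
                    harrell_c(t[idx], e[idx], sa[idx]) - harrell_c(t[idx], e[idx], sb[idx])
                )
            except Exception:
                continue
        boot_se = np.std(boots, ddof=1)
        assert abs(res.se - boot_se) / boot_se < 0.15

    def test_detects_real_difference(self):
        rng = np.random.default_rng(74)
        n = 400
        t = rng.exponential(50, n)
        e = np.ones(n, dtype=int)
        informative = -t + rng.normal(scale=10, size=n)
        noise = rng.normal(size=n)
        res = compare_c(t, e, informative, noise)
        assert res.difference > 0.2 and res.p_value < 1e-6


class TestAssociation:
    def test_identical_assignments_diagonal(self):
        g = [1, 1, 2, 2, 3]
        tab = cross_tabulate(g, g, margins=False)
        assert np.array_equal(np.diag(tab.to_numpy()), [2, 2, 1])
        assert tab.to_numpy().sum() == 5

    def test_totals_conserved(self):
        rng = np.random.default_rng(80)
        a = rng.integers(1, 5, 100)
        b = rng.integers(1, 4, 100)
        tab = cross_tabulate(a, b)
        assert tab.loc["Total", "Total"] == 100
        inner = tab.drop(index="Total").drop(columns="Total").to_numpy()
        assert inner.sum() == 100

    def test_known_confusion_counts(self):
        a = [1, 1, 1, 2, 2]
        b = [1, 1, 2, 2, 2]
        tab = cross_tabulate(a, b, margins=False)
        assert tab.loc[1, 1] == 2 and tab.loc[1, 2] == 1 and tab.loc[2, 2] == 2

    def test_spearman_perfect_and_independent(self):
        assert spearman_midrank([1, 1, 2, 2], [1, 1, 2, 2]) == pytest.approx(1.0)
        assert spearman_midrank([1, 1, 2, 2], [1, 2, 1, 2]) == pytest.approx(0.0, abs=1e-12)

    def test_spearman_matches_midrank_pearson(self):
        rng = np.random.default_rng(81)
        for _ in range(10):
            a = rng.integers(1, 11, 200).astype(float)
            b = (a + rng.integers(-3, 4, 200)).clip(1, 10)
            # manual mid-rank Pearson
            ra = pd.Series(a).rank().to_numpy()
            rb = pd.Series(b).rank().to_numpy()
            manual = np.corrcoef(ra, rb)[0, 1]
            assert spearman_midrank(a, b) == pytest.approx(manual, abs=1e-12)

    def test_constant_assignment_flagged(self):
        with pytest.raises(ValueError):
            spearman_midrank([1, 1, 1], [1, 2, 3])


class TestRiskCategories:
    def test_all_low(self):
        frame = pd.DataFrame({"T": ["T1", "T1", "T2"]})
        out = risk_category_distribution([1, 1, 1], frame, {"low": [1]})
        assert (out["low"] == 1.0).all()

    def test_rows_sum_to_one_and_exact_mixture(self):
        frame = pd.DataFrame({"T": ["T1"] * 4 + ["T2"] * 4})
        groups = [1, 1, 2, 3, 3, 3, 3, 2]
        cmap = {"low": [1], "medium": [2], "high": [3]}
        out = risk_category_distribution(groups, frame, cmap)
        assert np.allclose(out.sum(axis=1), 1.0, atol=1e-12)
        assert out.loc[("T", "T1")].tolist() == [0.5, 0.25, 0.25]
        assert out.loc[("T", "T2")].tolist() == [0.0, 0.25, 0.75]

    def test_non_partition_fatal(self):
        frame = pd.DataFrame({"T": ["T1", "T2"]})
        with pytest.raises(ValueError):
            risk_category_distribution([1, 2], frame, {"low": [1]})  # group 2 uncovered
        with pytest.raises(ValueError):
            risk_category_distribution([1, 2], frame, {"low": [1, 2], "high": [2]})  # overlap
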