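"""Patient-years, tabulation margins, trend fits and exact tests.

Each statistical routine is checked against an independent oracle written
here: closed-form normal equations for OLS, hypergeometric enumeration for
Fisher's exact test, an exhaustive ECDF-breakpoint scan for the KS
statistic, and iteratively reweighted least squares for the two-level
reduction of the proportional-odds model.
"""
import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest

from ndtrials.registry_io import TrialRecord
from ndtrials.stats import (annualized_counts, fisher_enrichment, ks_compare,
                            linear_trend, ordinal_stage_trend, patient_years,
                            share, tabulate, yearly_mean_ci)


def record(**kw):
    defaults = dict(nct_id="NCT00000001", start_date=dt.date(2010, 1, 1),
                    completion_date=dt.date(2012, 1, 1),
                    enrollment_count=100, enrollment_type="actual")
    defaults.update(kw)
    return TrialRecord(**defaults)


class TestPatientYears:
    def test_two_year_trial_of_100(self):
        # 730 days / 365.25 * 100, i.e. almost exactly 200 patient-years
        assert patient_years(record()) == pytest.approx(730 / 365.25 * 100)

    def test_anticipated_enrollment_is_missing(self):
        assert patient_years(record(enrollment_type="anticipated",
                                    enrollment_count=500)) is None

    def test_missing_completion_date_is_missing(self):
        assert patient_years(record(completion_date=None)) is None

    def test_negative_duration_is_missing(self):
        bad = record(start_date=dt.date(2012, 1, 1),
                     completion_date=dt.date(2010, 1, 1))
        assert patient_years(bad) is None


def toy_frame(n=60, seed=5):
    rng = np.random.default_rng(seed)
    frame = pd.DataFrame({
        "nct_id": [f"NCT{i:08d}" for i in range(n)],
        "included": 1,
        "year": rng.integers(2000, 2021, n),
        "sector": rng.choice(["industry", "other"], n),
        "trial_class": rng.choice(["drug", "device", "behavioral"], n),
        "diseases": rng.choice(["AD", "PD", "AD;PD"], n),
        "patient_years": rng.exponential(100, n),
    })
    frame.loc[frame.index[:10], "patient_years"] = np.nan
    return frame


class TestTabulate:
    def test_two_equal_levels(self):
        frame = toy_frame(10)
        frame["sector"] = ["industry"] * 5 + ["other"] * 5
        counts = tabulate(frame, ["sector"]).table.set_index("sector")
        assert counts.loc["industry", "n_trials"] == 5
        assert counts.loc["other", "n_trials"] == 5

    def test_bivariate_margins_match_groupby_oracle(self):
        frame = toy_frame()
        ct = tabulate(frame, ["trial_class", "sector"])
        oracle = frame.groupby("sector").size()
        margin = ct.margin("sector")
        assert margin.sort_index().equals(oracle.sort_index())

    def test_disease_dimension_counts_once_per_disease(self):
        frame = toy_frame()
        counts = tabulate(frame, ["disease"]).margin("disease")
        expected_ad = frame["diseases"].str.contains("AD").sum()
        assert counts["AD"] == expected_ad

    def test_all_missing_patient_years_cell(self):
        frame = toy_frame(8)
        frame["patient_years"] = np.nan
        frame["sector"] = "other"
        table = tabulate(frame, ["sector"]).table
        assert table.loc[0, "n_trials"] == 8
        assert np.isnan(table.loc[0, "patient_years"])

    def test_unknown_dimension_rejected(self):
        with pytest.raises(ValueError, match="dimension"):
            tabulate(toy_frame(), ["sponsor_species"])

    def test_row_order_invariance(self):
        frame = toy_frame()
        shuffled = frame.sample(frac=1, random_state=3)
        a = tabulate(frame, ["trial_class"]).table
        b = tabulate(shuffled, ["trial_class"]).table
        pd.testing.assert_frame_equal(a, b)


class TestAnnualizedCounts:
    def _frame(self):
        frame = toy_frame(40)
        frame["year"] = [2019] * 35 + [2020] * 5
        return frame

    def test_partial_year_scaled_by_factor(self):
        out = annualized_counts(self._frame(), factor=4.0, partial_year=2020)
        assert out.set_index("year").loc[2020, "trials_per_year"] == 20

    def test_identity_factor(self):
        out = annualized_counts(self._frame(), factor=1.0, partial_year=2020)
        assert out.set_index("year").loc[2020, "trials_per_year"] == 5

    def test_full_years_unaffected(self):
        out = annualized_counts(self._frame(), factor=4.0, partial_year=2020)
        assert out.set_index("year").loc[2019, "trials_per_year"] == 35


class TestLinearTrend:
    def test_constant_outcome(self):
        fit = linear_trend(np.arange(50), np.full(50, 7.0))
        assert fit.slope == 0.0 and fit.p_value == 1.0

    def test_perfect_line(self):
        x = np.arange(10, dtype=float)
        fit = linear_trend(x, 2 * x)
        assert fit.slope == pytest.approx(2.0, abs=1e-12)
        assert fit.p_value < 1e-12
        assert fit.pred_start == pytest.approx(0.0, abs=1e-9)
        assert fit.pred_end == pytest.approx(18.0, abs=1e-9)

    def test_matches_normal_equations_oracle(self):
        """Slope/intercept agree with the closed-form normal equations and
        the p-value with the textbook t statistic, to 1e-10."""
        rng = np.random.default_rng(123)
        for _ in range(20):
            n = int(rng.integers(5, 30))
            x = rng.normal(size=n)
            y = 1.5 * x + rng.normal(size=n)
            fit = linear_trend(x, y)
            sxx = ((x - x.mean()) ** 2).sum()
            sxy = ((x - x.mean()) * (y - y.mean())).sum()
            slope = sxy / sxx
            intercept = y.mean() - slope * x.mean()
            resid = y - intercept - slope * x
            se = math.sqrt((resid ** 2).sum() / (n - 2) / sxx)
            import scipy.stats
            p = 2 * scipy.stats.t.sf(abs(slope / se), n - 2)
            assert fit.slope == pytest.approx(slope, abs=1e-10)
            assert fit.intercept == pytest.approx(intercept, abs=1e-10)
            assert fit.p_value == pytest.approx(p, abs=1e-10)

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError):
            linear_trend([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def fisher_p_oracle(table):
    """Two-sided exact p by exhaustive enumeration of all tables with the
    observed margins, summing hypergeometric probabilities <= observed."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return (math.comb(r1, x) * math.comb(r2, c1 - x)
                / math.comb(n, c1))

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return total


class TestFisher:
    def test_symmetric_table_odds_ratio_one(self):
        res = fisher_enrichment([[10, 10], [10, 10]])
        assert res.statistic == pytest.approx(1.0, abs=1e-6)
        assert res.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("table", [
        [[20, 10], [10, 20]],
        [[5, 0], [0, 5]],
        [[1, 9], [11, 3]],
        [[0, 7], [3, 2]],
    ])
    def test_p_matches_enumeration_oracle(self, table):
        res = fisher_enrichment(table)
        assert res.p_value == pytest.approx(fisher_p_oracle(table),
                                            abs=1e-12)

    def test_zero_margin(self):
        res = fisher_enrichment([[0, 0], [3, 4]])
        assert res.statistic is None and res.p_value == 1.0

    def test_ci_brackets_estimate(self):
        res = fisher_enrichment([[20, 10], [10, 20]], compute_ci=True)
        assert res.ci[0] < res.statistic < res.ci[1]


def ks_oracle(a, b):
    """Brute-force max ECDF difference over every breakpoint."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    best = 0.0
    for x in np.concatenate([a, b]):
        fa = (a <= x).mean()
        fb = (b <= x).mean()
        best = max(best, abs(fa - fb))
    return best


class TestKS:
    def test_identical_samples(self):
        res = ks_compare([1, 2, 3], [1, 2, 3])
        assert res.statistic == 0.0

    def test_disjoint_support(self):
        res = ks_compare([1, 2, 3], [10, 11])
        assert res.statistic == 1.0

    def test_matches_breakpoint_oracle(self):
        rng = np.random.default_rng(77)
        for _ in range(40):
            a = rng.normal(size=int(rng.integers(2, 15)))
            b = rng.normal(0.5, 1.2, size=int(rng.integers(2, 15)))
            res = ks_compare(a, b)
            assert res.statistic == pytest.approx(ks_oracle(a, b), abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_compare([], [1.0])


def logistic_irls(x, y, iters=200):
    """Plain IRLS logistic regression oracle: returns (intercept, slope)."""
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    for _ in range(iters):
        eta = X @ beta
        mu = 1 / (1 + np.exp(-eta))
        W = mu * (1 - mu)
        z = eta + (y - mu) / np.clip(W, 1e-12, None)
        beta_new = np.linalg.solve(X.T @ (W[:, None] * X), X.T @ (W * z))
        if np.max(np.abs(beta_new - beta)) < 1e-12:
            beta = beta_new
            break
        beta = beta_new
    return beta


class TestOrdinalStageTrend:
    def test_stationary_distribution_near_zero_slope(self):
        rng = np.random.default_rng(5)
        years = np.repeat(np.arange(2000, 2020), 40)
        stages = rng.choice([3, 4], size=len(years), p=[0.2, 0.8])
        res = ordinal_stage_trend(years, stages)
        assert abs(res.statistic) < 0.05
        assert res.p_value > 0.01

    def test_two_level_collapse_equals_logistic_oracle(self):
        """With K=2 stages the proportional-odds slope equals (minus) the
        binary logistic slope for P(later stage)."""
        rng = np.random.default_rng(6)
        years = np.repeat(np.arange(2000, 2015), 30).astype(float)
        t = years - years.mean()
        p_late = 1 / (1 + np.exp(-(1.2 - 0.08 * t)))
        stages = (rng.random(len(years)) < p_late).astype(int) + 3
        res = ordinal_stage_trend(years, stages)
        _, slope = logistic_irls(t, (stages == 4).astype(float))
        assert res.statistic == pytest.approx(-slope, abs=1e-4)

    def test_sign_convention_positive_means_earlier(self):
        rng = np.random.default_rng(9)
        years = np.repeat(np.arange(2000, 2020), 50).astype(float)
        drift = 0.15  # strong shift toward the earlier stage over time
        p_early = 1 / (1 + np.exp(-(-2.0 + drift * (years - 2000))))
        stages = np.where(rng.random(len(years)) < p_early, 3, 4)
        res = ordinal_stage_trend(years, stages)
        assert res.statistic > 0
        assert res.p_value < 1e-6

    def test_single_level_rejected(self):
        with pytest.raises(ValueError):
            ordinal_stage_trend([2000, 2001, 2002], [4, 4, 4])


class TestYearlyMeanCI:
    def test_zero_width_for_constant_values(self):
        out = yearly_mean_ci([2005] * 3, [2, 2, 2])
        assert out.loc[0, "mean"] == 2
        assert out.loc[0, "ci_lo"] == pytest.approx(2)
        assert out.loc[0, "ci_hi"] == pytest.approx(2)

    def test_hand_computed_sem(self):
        # oracle: sd of {0,4} = 2.828..., SEM = 2, CI = 2 -+ 3.92
        out = yearly_mean_ci([2010, 2010], [0, 4])
        assert out.loc[0, "mean"] == pytest.approx(2.0)
        assert out.loc[0, "ci_lo"] == pytest.approx(-1.92)
        assert out.loc[0, "ci_hi"] == pytest.approx(5.92)

    def test_single_observation_has_missing_ci(self):
        out = yearly_mean_ci([2010], [3.0])
        assert np.isnan(out.loc[0, "ci_lo"])

    def test_empty_input(self):
        assert yearly_mean_ci([], []).empty


class TestShare:
    @pytest.mark.parametrize("num,den,expected", [
        (2041, 4010, 51.0),
        (89, 3238, 2.7),
        (0, 50, 0.0),
        (1239, 3238, 38.0),
        (272, 729, 37.0),
    ])
    def test_mixed_precision_rounding(self, num, den, expected):
        assert share(num, den) == expected

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            share(1, 0)
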