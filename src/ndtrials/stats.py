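"""Patient-years, tabulations, shares and the trend/test statistics.

Conventions, fixed across the package:

* trial duration in years = (completion - start) in days / 365.25;
  patient-years = duration x enrollment, defined only for "Actual"
  enrollment figures (anticipated enrollment gives a missing value, as
  does a missing or negative duration);
* temporal trend regressions are ordinary least squares on trial-level
  observations (yearly means are display-only);
* the disease-stage trend is a proportional-odds (ordinal logistic) model
  with the sign convention that a positive slope means a shift toward
  earlier disease stages over calendar time;
* enrichment tests are Fisher's exact test with the conditional
  maximum-likelihood odds ratio; distribution comparisons are two-sample
  Kolmogorov-Smirnov with the asymptotic two-sided p-value;
* reported shares follow the mixed rounding convention of the source
  tables: nearest integer percent at >= 10%, one decimal below 10%.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from scipy.stats.contingency import odds_ratio as _cond_odds_ratio

from .config import DISEASES

__all__ = [
    "TrendFit", "TestResult", "CrossTab", "duration_years", "patient_years",
    "tabulate", "annualized_counts", "linear_trend", "ordinal_stage_trend",
    "fisher_enrichment", "ks_compare", "yearly_mean_ci", "share",
    "format_share", "collapse_phase",
]

DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class TrendFit:
    """An OLS temporal trend with endpoint predictions."""
    slope: float
    intercept: float
    p_value: float
    n: int
    slope_se: float
    slope_ci: tuple[float, float]
    x_start: float
    x_end: float

    @property
    def pred_start(self) -> float:
        return self.intercept + self.slope * self.x_start

    @property
    def pred_end(self) -> float:
        return self.intercept + self.slope * self.x_end


@dataclass(frozen=True)
class TestResult:
    """A hypothesis-test outcome (Fisher, KS or ordinal trend)."""
    kind: str                       # {fisher, ks, ordinal_trend}
    statistic: Optional[float]      # OR, D, or ordinal log-odds slope
    p_value: float
    ci: Optional[tuple[float, float]] = None
    n: Optional[int] = None


def duration_years(start, completion) -> Optional[float]:
    """Trial duration in years; missing when either date is absent."""
    if start is None or completion is None:
        return None
    return (completion - start).days / DAYS_PER_YEAR


def patient_years(record) -> Optional[float]:
    """Patient-years of enrollment = duration x actual enrollment.

    Missing when enrollment is anticipated (not yet realized), when either
    date is absent, or when the duration is negative (a flagged data
    error). An imperfect investment proxy: participants actually accrue and
    withdraw gradually.
    """
    if record.enrollment_type != "actual" or record.enrollment_count is None:
        return None
    dur = duration_years(record.start_date, record.completion_date)
    if dur is None or dur < 0:
        return None
    return dur * record.enrollment_count


@dataclass(frozen=True)
class CrossTab:
    """Counts, patient-year sums and intensity per cell of a tabulation.

    ``table`` has one row per cell: the dimension columns, ``n_trials``,
    ``patient_years`` (NaN when every trial in the cell is missing) and
    ``intensity`` = patient_years / n_trials.
    """
    dims: tuple[str, ...]
    table: pd.DataFrame

    def margin(self, dim: str) -> pd.Series:
        return self.table.groupby(dim, observed=True)["n_trials"].sum()


_KNOWN_DIMS = ("disease", "sector", "trial_class", "phase",
               "placebo_soc_controlled", "stage_min", "year",
               "drug_category", "severity_scale")


def tabulate(frame: pd.DataFrame, dims: Sequence[str]) -> CrossTab:
    """Cross-tabulate included trials along one or more dimensions.

    ``disease`` explodes multi-disease trials so that a trial spanning two
    diseases is counted once per disease (disease margins sum over trials,
    not unique trials). Unknown dimension names raise a config error.
    """
    for dim in dims:
        if dim not in _KNOWN_DIMS:
            raise ValueError(f"unknown tabulation dimension {dim!r}")
    data = frame[frame["included"] == 1].copy()
    if "disease" in dims:
        data = data.assign(disease=data["diseases"].astype(str).str.split(";"))
        data = data.explode("disease")
    grouped = data.groupby(list(dims), dropna=False, observed=True)
    table = grouped.agg(
        n_trials=("nct_id", "size"),
        patient_years=("patient_years", lambda s: (s.sum() if s.notna().any()
                                                   else np.nan)),
    ).reset_index()
    table["intensity"] = table["patient_years"] / table["n_trials"]
    return CrossTab(tuple(dims), table)


def annualized_counts(frame: pd.DataFrame, by: Optional[str] = None,
                      factor: float = 4.0,
                      partial_year: Optional[int] = None) -> pd.DataFrame:
    """Trials per launch year, with the final partial year annualized.

    When a registry window ends part-way through a calendar year the raw
    count for that year is multiplied by ``factor`` (4 for a three-month
    slice) to yield a trials/year rate; all other years pass through.
    """
    dims = ["year"] + ([by] if by else [])
    ct = tabulate(frame, dims)
    out = ct.table.copy()
    out["year"] = out["year"].astype(int)
    out["trials_per_year"] = out["n_trials"].astype(float)
    if partial_year is not None:
        mask = out["year"] == partial_year
        out.loc[mask, "trials_per_year"] = out.loc[mask, "n_trials"] * factor
    return out[dims + ["n_trials", "trials_per_year"]]


def linear_trend(x: Sequence[float], y: Sequence[float]) -> TrendFit:
    """OLS trend of a trial-level outcome on launch year.

    Requires n >= 3 with at least two distinct x values. The two-sided
    slope p-value comes from the usual t statistic; endpoint predictions
    are the fitted values at the first and last year observed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3 or np.unique(x).size < 2:
        raise ValueError("linear_trend needs >= 3 points and >= 2 distinct x")
    if np.ptp(y) == 0:  # constant outcome: no trend, no evidence against H0
        return TrendFit(slope=0.0, intercept=float(y[0]), p_value=1.0,
                        n=int(len(x)), slope_se=0.0, slope_ci=(0.0, 0.0),
                        x_start=float(x.min()), x_end=float(x.max()))
    fit = scipy.stats.linregress(x, y)
    tcrit = scipy.stats.t.ppf(0.975, len(x) - 2)
    ci = (fit.slope - tcrit * fit.stderr, fit.slope + tcrit * fit.stderr)
    return TrendFit(slope=float(fit.slope), intercept=float(fit.intercept),
                    p_value=float(fit.pvalue), n=int(len(x)),
                    slope_se=float(fit.stderr), slope_ci=ci,
                    x_start=float(x.min()), x_end=float(x.max()))


def ordinal_stage_trend(years: Sequence[float],
                        stages: Sequence[int]) -> TestResult:
    """Proportional-odds model of disease stage on launch year.

    Stage (0-4) is treated as ordinal with a logit link, fitted by maximum
    likelihood. The reported statistic is the per-year log-odds of
    enrolling *earlier* stages, so a positive slope means trials shifted
    toward less-affected participants over time. Requires at least two
    observed stage levels.
    """
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    years = np.asarray(years, dtype=float)
    stages = np.asarray(stages)
    keep = ~(np.isnan(years) | pd.isna(stages))
    years, stages = years[keep], stages[keep].astype(int)
    levels = np.unique(stages)
    if levels.size < 2:
        raise ValueError("ordinal_stage_trend needs >= 2 observed stage levels")
    codes = np.searchsorted(levels, stages)
    x = years - years.mean()        # centering stabilizes the thresholds
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = OrderedModel(codes, x[:, None], distr="logit")
        res = model.fit(method="bfgs", disp=False, gtol=1e-8, maxiter=200)
    beta = float(res.params[0])     # latent scale: positive = later stages
    se = float(res.bse[0])
    p = float(res.pvalues[0])
    lo, hi = -(beta + 1.96 * se), -(beta - 1.96 * se)
    return TestResult(kind="ordinal_trend", statistic=-beta, p_value=p,
                      ci=(lo, hi), n=int(len(codes)))


def fisher_enrichment(table: Sequence[Sequence[int]],
                      compute_ci: bool = False) -> TestResult:
    """Fisher's exact test on a 2x2 table.

    Two-sided p by summing hypergeometric probabilities no larger than the
    observed table's; the statistic is the conditional maximum-likelihood
    odds ratio. A zero margin makes the odds ratio undefined (reported
    missing) with p = 1.
    """
    arr = np.asarray(table, dtype=int)
    if arr.shape != (2, 2) or (arr < 0).any():
        raise ValueError("fisher_enrichment needs a non-negative 2x2 table")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        return TestResult(kind="fisher", statistic=None, p_value=1.0,
                          n=int(arr.sum()))
    _, p = scipy.stats.fisher_exact(arr, alternative="two-sided")
    result = _cond_odds_ratio(arr, kind="conditional")
    ci = None
    if compute_ci:
        interval = result.confidence_interval(0.95)
        ci = (float(interval.low), float(interval.high))
    return TestResult(kind="fisher", statistic=float(result.statistic),
                      p_value=float(p), ci=ci, n=int(arr.sum()))


def ks_compare(sample_a: Sequence[float],
               sample_b: Sequence[float]) -> TestResult:
    """Two-sample Kolmogorov-Smirnov comparison (no normality assumed)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("ks_compare needs two non-empty samples")
    res = scipy.stats.ks_2samp(a, b, method="asymp")
    return TestResult(kind="ks", statistic=float(res.statistic),
                      p_value=float(res.pvalue), n=int(len(a) + len(b)))


def yearly_mean_ci(years: Sequence[float],
                   values: Sequence[float]) -> pd.DataFrame:
    """Per-year mean with a 95% CI of the mean (+- 1.96 SEM).

    Single-observation years report a missing CI; empty years are absent.
    """
    df = pd.DataFrame({"year": years, "value": values}).dropna()
    if not len(df):
        return pd.DataFrame(columns=["year", "n", "mean", "ci_lo", "ci_hi"])
    grouped = df.groupby("year")["value"]
    out = grouped.agg(n="size", mean="mean", sd="std").reset_index()
    sem = out["sd"] / np.sqrt(out["n"])
    out["ci_lo"] = out["mean"] - 1.96 * sem
    out["ci_hi"] = out["mean"] + 1.96 * sem
    return out[["year", "n", "mean", "ci_lo", "ci_hi"]]


def share(numerator: float, denominator: float) -> float:
    """Percentage with the mixed reporting precision of the source tables.

    Shares of at least 10% round to the nearest integer percent; smaller
    shares keep one decimal place (half-up in both cases), so that
    replication tables can be compared by string match.
    """
    if denominator <= 0:
        raise ValueError("share needs a positive denominator")
    pct = 100 * Decimal(str(numerator)) / Decimal(str(denominator))
    if pct >= 10:
        return float(pct.quantize(Decimal("1"), rounding=ROUND_HALF_UP))
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def format_share(numerator: float, denominator: float) -> str:
    value = share(numerator, denominator)
    return f"{value:g}%"


def collapse_phase(phase: str) -> str:
    """Map combined phases to the lower phase for stratified analyses."""
    return {"1/2": "1", "2/3": "2"}.get(phase, phase)
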