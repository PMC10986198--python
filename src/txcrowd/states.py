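"""State x race panel analysis: rates per 100k, slopes, and group summaries.

The panel has one row per state, year, and race/ethnicity category with
waiting-list additions (WLAs), the uninsurance rate (a proportion in [0,1]),
the race-specific population, and Medicaid-expansion status.  Campaign data
run through March 2019, so 25% of 2019's WLAs are attributed to the study
window by linear interpolation.  State-race cells with too small a
population to estimate an uninsurance rate are excluded (KFF-style
suppression).  Activity/need relationships are summarized by OLS slopes of
campaigns per 100k on WLAs per 100k and on the uninsurance rate.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .constants import STUDY_2019_FRACTION

PANEL_COLUMNS = [
    "state", "year", "race", "wla", "uninsured_rate", "population",
    "medicaid_expansion", "sufficient_population",
]


def read_panel(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["medicaid_expansion"] = df["medicaid_expansion"].astype(bool)
    df["sufficient_population"] = df["sufficient_population"].astype(bool)
    return df


def write_panel(panel: pd.DataFrame, path: str) -> None:
    panel[PANEL_COLUMNS].to_csv(path, index=False)


def interpolate_study_period(
    panel: pd.DataFrame, fraction_2019: float = STUDY_2019_FRACTION
) -> pd.DataFrame:
    """Attribute ``fraction_2019`` of 2019's WLAs to the study period."""
    out = panel.copy()
    out["wla"] = out["wla"].astype(float)
    is_2019 = out["year"] == 2019
    if not is_2019.any():
        warnings.warn("panel has no 2019 rows; interpolation skipped", stacklevel=2)
        return out
    out.loc[is_2019, "wla"] = out.loc[is_2019, "wla"] * fraction_2019
    return out


def per_100k(count, population):
    """Rate per 100 000 population; population must be positive."""
    count = np.asarray(count, dtype=float)
    population = np.asarray(population, dtype=float)
    if np.any(population <= 0):
        raise ValueError("population must be positive (insufficient cells are excluded upstream)")
    return 100_000.0 * count / population


def filter_sufficient(
    panel: pd.DataFrame,
    min_population: int = 10_000,
    exclude: list[tuple[str, str]] | None = None,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Drop state-race cells flagged insufficient or below ``min_population``.

    ``exclude`` adds explicit (state, race) pairs, mirroring externally
    published suppression lists.  Returns the subset and the sorted list of
    dropped (state, race) pairs.
    """
    drop = ~panel["sufficient_population"] | (panel["population"] < min_population)
    if exclude:
        excl = set(exclude)
        drop |= np.array(
            [(s, r) in excl
             for s, r in panel[["state", "race"]].itertuples(index=False, name=None)]
        )
    dropped = sorted(
        set(panel.loc[drop, ["state", "race"]].itertuples(index=False, name=None))
    )
    return panel.loc[~drop].reset_index(drop=True), dropped


@dataclass(frozen=True)
class SlopeFit:
    """OLS slope of campaign activity on a need measure, with inference."""

    slope: float
    intercept: float
    stderr: float
    conf_int: tuple[float, float]
    pvalue: float
    n: int
    race: str | None = None
    x_name: str | None = None

    def __post_init__(self) -> None:
        lo, hi = self.conf_int
        assert lo <= self.slope <= hi

    def summary(self) -> str:
        lo, hi = self.conf_int
        label = f" [{self.race}]" if self.race else ""
        return (
            f"slope{label} = {self.slope:.4f} (SE {self.stderr:.4f}, "
            f"95% CI {lo:.4f} to {hi:.4f}, p = {self.pvalue:.3g}, n = {self.n})"
        )


def fit_slope(x, y, race: str | None = None, x_name: str | None = None) -> SlopeFit:
    """Ordinary least squares of y on x with t-based inference."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("fit_slope requires at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance; slope is not identified")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    ci = res.conf_int(alpha=0.05)
    return SlopeFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        stderr=float(res.bse[1]),
        conf_int=(float(ci[1][0]), float(ci[1][1])),
        pvalue=float(res.pvalues[1]),
        n=len(x),
        race=race,
        x_name=x_name,
    )


def activity_slopes(
    rates: pd.DataFrame,
    y_col: str = "campaigns_per_100k",
    x_cols: tuple[str, ...] = ("wla_per_100k", "uninsured_rate"),
    race_col: str = "race",
) -> list[SlopeFit]:
    """Per-race OLS slopes of campaign activity on each need measure."""
    fits = []
    for race, grp in rates.groupby(race_col, sort=True):
        for x_col in x_cols:
            sub = grp.dropna(subset=[x_col, y_col])
            fits.append(fit_slope(sub[x_col], sub[y_col], race=race, x_name=x_col))
    return fits


def slopes_to_frame(fits: list[SlopeFit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "race": f.race, "x": f.x_name, "slope": f.slope, "intercept": f.intercept,
                "stderr": f.stderr, "ci_low": f.conf_int[0], "ci_high": f.conf_int[1],
                "pvalue": f.pvalue, "n": f.n,
            }
            for f in fits
        ]
    )


def group_summaries(
    data: pd.DataFrame,
    outcome_cols: list[str],
    race_col: str = "race",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Medians/IQRs by race plus a mean-equality test per outcome.

    Quartiles use inclusive linear interpolation.  The across-group test is
    one-way mean equality, reported both as the ANOVA F statistic and its
    large-sample chi-square (Wald) equivalent, (k-1) x F on k-1 degrees of
    freedom, so either reading of a "chi-square t-test for the difference in
    means" is checkable.
    """
    groups = {race: grp for race, grp in data.groupby(race_col, sort=True)}
    if len(groups) < 2:
        raise ValueError("group_summaries requires at least two race groups")
    summary_rows, test_rows = [], []
    for col in outcome_cols:
        samples = []
        for race, grp in groups.items():
            vals = grp[col].dropna().to_numpy(dtype=float)
            if len(vals) == 0:
                raise ValueError(f"empty group {race!r} for outcome {col!r}")
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            summary_rows.append(
                {
                    "outcome": col, "race": race, "n": len(vals),
                    "mean": float(vals.mean()), "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                    "median": float(med), "q1": float(q1), "q3": float(q3),
                }
            )
            samples.append(vals)
        f_stat, p_f = stats.f_oneway(*samples)
        k = len(samples)
        chi2 = float(f_stat) * (k - 1)
        p_chi2 = float(stats.chi2.sf(chi2, df=k - 1))
        test_rows.append(
            {
                "outcome": col, "F": float(f_stat), "p_F": float(p_f),
                "chi2": chi2, "df": k - 1, "p_chi2": p_chi2,
            }
        )
    return pd.DataFrame(summary_rows), pd.DataFrame(test_rows)
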