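"""Environmental preprocessing and lagged climate-growth correlations.

Seasonal means follow the austral convention used throughout the package:
DJF for year y averages December of y-1 with January and February of y;
MAM, JJA and SON average the labelled year's own months.  A seasonal (or
annual) mean is only produced when every constituent month is present.

The chronology window is correlated with each environmental variable at two
lags: "current" (environment year = growth year) and "previous"
(environment lagged one year behind growth).  Significance uses the exact
t-transform of the Pearson coefficient, two-sided, with no multiplicity
correction by default (an optional Benjamini-Hochberg adjustment is
available for modern use).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import Chronology, EnvSeries, MonthlyEnvSeries, ValidationError

SEASON_MONTHS = {
    "DJF": ((-1, 12), (0, 1), (0, 2)),
    "MAM": ((0, 3), (0, 4), (0, 5)),
    "JJA": ((0, 6), (0, 7), (0, 8)),
    "SON": ((0, 9), (0, 10), (0, 11)),
    "annual": tuple((0, m) for m in range(1, 13)),
}


@dataclass(frozen=True)
class CorrelationResult:
    variable: str
    season: str
    lag: str  # "current" or "previous"
    r: float
    p: float
    n: int

    @property
    def significant(self) -> bool:
        return self.p < 0.05


def seasonal_means(monthly: MonthlyEnvSeries, season: str) -> EnvSeries:
    """Seasonal (or annual) mean series from monthly values.

    Years missing any required month are omitted.
    """
    if season not in SEASON_MONTHS:
        raise ValidationError(f"unknown season {season!r}")
    lookup = {
        (int(y), int(m)): v
        for y, m, v in zip(monthly.years, monthly.months, monthly.values)
    }
    offsets = SEASON_MONTHS[season]
    years, values = [], []
    for y in range(int(monthly.years.min()), int(monthly.years.max()) + 2):
        vals = [lookup.get((y + dy, m)) for dy, m in offsets]
        if any(v is None for v in vals):
            continue
        years.append(y)
        values.append(float(np.mean(vals)))
    if not years:
        raise ValidationError(
            f"{monthly.name}: no complete {season} seasons in input"
        )
    return EnvSeries(
        name=monthly.name, years=np.array(years), values=np.array(values),
        season=season, preprocessing=(f"{season}_mean",),
    )


def annual_mean(monthly: MonthlyEnvSeries) -> EnvSeries:
    """Calendar-year mean of a monthly series (12 complete months required)."""
    return seasonal_means(monthly, "annual")


def linear_detrend(env: EnvSeries) -> EnvSeries:
    """Remove the OLS line on calendar year, returning residuals."""
    if len(env.years) < 3:
        raise ValidationError("linear detrend needs at least 3 years")
    x = env.years.astype(float)
    if np.ptp(x) == 0:
        raise ValidationError("years are constant; cannot detrend")
    coefs = np.polyfit(x, env.values, 1)
    resid = env.values - np.polyval(coefs, x)
    return replace(env, values=resid,
                   preprocessing=env.preprocessing + ("linear_detrended",))


def pearson_p(r: float, n: int) -> float:
    """Two-sided p-value for a Pearson coefficient from n paired values,
    via t = r*sqrt(n-2)/sqrt(1-r^2) on n-2 degrees of freedom."""
    if n < 3:
        raise ValidationError("need n >= 3")
    if abs(r) > 1:
        raise ValidationError("|r| > 1")
    if abs(r) == 1:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1 - r * r)
    return float(2 * sps.t.sf(abs(t), n - 2))


def lagged_correlations(chron: Chronology, window: tuple[int, int],
                        env_set: Iterable[EnvSeries],
                        bh_adjust: bool = False) -> list[CorrelationResult]:
    """Correlate the windowed chronology against each environmental series
    at current-year and previous-year lags.

    For window (y0, y1): "current" pairs MIC(y0..y1) with env(y0..y1);
    "previous" pairs MIC(y0..y1) with env(y0-1..y1-1).  Variables with
    fewer than 3 overlapping years are omitted with a warning.
    """
    y0, y1 = window
    mic = chron.window(y0, y1)
    growth_years = np.arange(y0, y1 + 1)
    results: list[CorrelationResult] = []
    for env in env_set:
        for lag_name, shift in (("current", 0), ("previous", 1)):
            ev = env.value_for(growth_years - shift)
            ok = np.isfinite(ev) & np.isfinite(mic)
            n = int(ok.sum())
            if n < 3:
                warnings.warn(
                    f"{env.name} [{env.season}, {lag_name}]: only {n} "
                    "overlapping years; omitted"
                )
                continue
            r = float(np.corrcoef(mic[ok], ev[ok])[0, 1])
            results.append(
                CorrelationResult(variable=env.name, season=env.season,
                                  lag=lag_name, r=r, p=pearson_p(r, n), n=n)
            )
    if bh_adjust and results:
        from statsmodels.stats.multitest import multipletests

        _, p_adj, *_ = multipletests([c.p for c in results], method="fdr_bh")
        results = [replace(c, p=float(q)) for c, q in zip(results, p_adj)]
    return results


def correlation_table(results: Sequence[CorrelationResult]) -> pd.DataFrame:
    """Wide report: one row per variable/season with current and previous
    year r and p, and significance stars at p < 0.05."""
    df = pd.DataFrame(
        [
            {"variable": c.variable, "season": c.season, "lag": c.lag,
             "r": c.r, "p": c.p, "n": c.n}
            for c in results
        ]
    )
    if df.empty:
        return df
    wide = df.pivot_table(index=["variable", "season"], columns="lag",
                          values=["r", "p"], sort=False)
    wide.columns = [f"{lag}_{stat}" for stat, lag in wide.columns]
    wide = wide.reset_index()
    for lag in ("current", "previous"):
        pcol = f"{lag}_p"
        if pcol in wide:
            wide[f"{lag}_sig"] = np.where(wide[pcol] < 0.05, "*", "")
    order = [c for c in ["variable", "season", "current_r", "current_p",
                         "current_sig", "previous_r", "previous_p",
                         "previous_sig"] if c in wide.columns]
    return wide[order]
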