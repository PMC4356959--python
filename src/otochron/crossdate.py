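"""Dating quality control by lagged segment correlation.

Each candidate series is compared against a leave-one-out master chronology
built from all other series.  Before comparison every series is high-pass
filtered (ratio against a flexible smoothing spline), optionally AR(1)
prewhitened, and z-scored, so that segment correlations respond to shared
high-frequency variation rather than residual trend.  Each fixed-length
segment (default 15 years, 50% overlap) is correlated with the master at
integer lags; a segment whose best-correlating lag is not zero, or whose
lag-0 correlation falls below a one-tailed critical value, is flagged for
inspection.  Flag-only: no automatic re-dating is performed.

Lag sign convention: ``best_lag = +1`` means the series appears dated one
year too old — shifting its year labels forward by one (t -> t + 1) aligns
it with the master.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .detrend import fit_spline, SplineFitError
from .io import IndexSeries, ValidationError


@dataclass(frozen=True)
class SegmentRecord:
    start_year: int
    length: int
    best_lag: int
    r_at_lag0: float
    r_best: float
    low_corr: bool
    off_zero_lag: bool


@dataclass(frozen=True)
class CrossdateResult:
    series_id: str
    segments: tuple
    interseries_r: float

    @property
    def flagged(self) -> bool:
        return any(s.low_corr or s.off_zero_lag for s in self.segments)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "series_id": self.series_id,
                    "start_year": s.start_year,
                    "length": s.length,
                    "best_lag": s.best_lag,
                    "r_at_lag0": s.r_at_lag0,
                    "r_best": s.r_best,
                    "low_corr": s.low_corr,
                    "off_zero_lag": s.off_zero_lag,
                }
                for s in self.segments
            ]
        )


@dataclass(frozen=True)
class MasterSeries:
    first_year: int
    values: np.ndarray
    depth: np.ndarray

    @property
    def years(self) -> np.ndarray:
        return self.first_year + np.arange(len(self.values))

    def at(self, year: int) -> float:
        i = year - self.first_year
        if 0 <= i < len(self.values):
            return self.values[i]
        return np.nan


def critical_r(n: int, alpha: float = 0.01) -> float:
    """One-tailed critical Pearson r for segment length n (t-based)."""
    if n < 3:
        raise ValidationError("need n >= 3")
    t = sps.t.ppf(1 - alpha, n - 2)
    return float(t / np.sqrt(t * t + n - 2))


@dataclass(frozen=True)
class _Prepared:
    owner_id: str
    first_year: int
    values: np.ndarray

    @property
    def last_year(self) -> int:
        return self.first_year + len(self.values) - 1

    def at_years(self, years: np.ndarray) -> np.ndarray:
        idx = years - self.first_year
        out = np.full(len(years), np.nan)
        ok = (idx >= 0) & (idx < len(self.values))
        out[ok] = self.values[idx[ok]]
        return out


def prepare_series(s: IndexSeries, highpass_cutoff: float = 15.0,
                   prewhiten: bool = True) -> _Prepared:
    """High-pass filter, optionally AR(1)-prewhiten, and z-score a series."""
    x = np.asarray(s.indices, dtype=float)
    first = s.first_year
    if len(x) >= 4:
        try:
            x = x / fit_spline(x, highpass_cutoff)
        except SplineFitError:
            x = x / x.mean()
    if prewhiten and len(x) >= 8:
        xm = x - x.mean()
        denom = float(np.dot(xm[:-1], xm[:-1]))
        phi = float(np.dot(xm[1:], xm[:-1]) / denom) if denom > 0 else 0.0
        phi = np.clip(phi, -0.99, 0.99)
        x = xm[1:] - phi * xm[:-1]
        first += 1
    sd = x.std(ddof=1)
    if sd > 0:
        x = (x - x.mean()) / sd
    else:
        x = x - x.mean()
    return _Prepared(owner_id=s.owner_id, first_year=first, values=x)


def build_master(index_series_set: Sequence[IndexSeries], exclude_id: str,
                 highpass_cutoff: float = 15.0, prewhiten: bool = True,
                 _prepared: Sequence[_Prepared] | None = None) -> MasterSeries:
    """Leave-one-out master: year-wise mean of all prepared series except
    ``exclude_id``, with per-year depth."""
    if _prepared is None:
        _prepared = [prepare_series(s, highpass_cutoff, prewhiten)
                     for s in index_series_set]
    others = [p for p in _prepared if p.owner_id != exclude_id]
    if len(others) < 2:
        raise ValidationError("need at least 2 series besides the excluded one")
    first = min(p.first_year for p in others)
    last = max(p.last_year for p in others)
    mat = np.full((last - first + 1, len(others)), np.nan)
    for j, p in enumerate(others):
        i0 = p.first_year - first
        mat[i0 : i0 + len(p.values), j] = p.values
    depth = np.sum(np.isfinite(mat), axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        values = np.nanmean(mat, axis=1)
    return MasterSeries(first_year=first, values=values, depth=depth)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        return np.nan
    a, b = a[ok], b[ok]
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def segment_correlations(series, master: MasterSeries, seg_length: int = 15,
                         seg_overlap: float = 0.5, max_lag: int = 2,
                         alpha: float = 0.01,
                         highpass_cutoff: float = 15.0,
                         prewhiten: bool = True) -> CrossdateResult:
    """Lagged correlations of one series against a master, per segment.

    ``series`` may be an IndexSeries (prepared internally with the same
    filtering as the master) or an already-prepared series.
    """
    if isinstance(series, IndexSeries):
        series = prepare_series(series, highpass_cutoff, prewhiten)
    step = max(int(round(seg_length * (1 - seg_overlap))), 1)
    lo = max(series.first_year, master.first_year)
    hi = min(series.last_year, int(master.years[-1]))
    if hi - lo + 1 < seg_length:
        raise ValidationError(
            f"series {series.owner_id}: overlap with master "
            f"({hi - lo + 1} yr) shorter than segment length {seg_length}"
        )
    rc = critical_r(seg_length, alpha)
    starts = list(range(lo, hi - seg_length + 2, step))
    if starts and starts[-1] + seg_length - 1 < hi:
        starts.append(hi - seg_length + 1)  # terminal segment flush with end
    segments = []
    lags = np.arange(-max_lag, max_lag + 1)
    for s0 in starts:
        years = np.arange(s0, s0 + seg_length)
        sv = series.at_years(years)
        r_by_lag = {}
        for lag in lags:
            mv = np.array([master.at(int(y) + int(lag)) for y in years])
            # a lag is only assessed over the full segment: truncated
            # overlaps at the master's edges give unstable correlations
            if np.all(np.isfinite(mv) & np.isfinite(sv)):
                r_by_lag[int(lag)] = _pearson(sv, mv)
            else:
                r_by_lag[int(lag)] = np.nan
        finite = {L: r for L, r in r_by_lag.items() if np.isfinite(r)}
        if not finite:
            continue
        # ties: prefer smaller |lag|, then the negative lag
        best_lag = max(finite, key=lambda L: (finite[L], -abs(L), -L))
        r0 = r_by_lag.get(0, np.nan)
        segments.append(
            SegmentRecord(
                start_year=int(s0), length=seg_length, best_lag=best_lag,
                r_at_lag0=r0, r_best=finite[best_lag],
                low_corr=bool(not np.isfinite(r0) or r0 < rc),
                off_zero_lag=bool(best_lag != 0),
            )
        )
    years = np.arange(lo, hi + 1)
    inter_r = _pearson(series.at_years(years),
                       np.array([master.at(int(y)) for y in years]))
    return CrossdateResult(series_id=series.owner_id, segments=tuple(segments),
                           interseries_r=inter_r)


def crossdate_all(index_series_set: Sequence[IndexSeries],
                  seg_length: int = 15, seg_overlap: float = 0.5,
                  max_lag: int = 2, alpha: float = 0.01,
                  highpass_cutoff: float = 15.0,
                  prewhiten: bool = True) -> list[CrossdateResult]:
    """Leave-one-out crossdating QC of every series in the set."""
    prepared = [prepare_series(s, highpass_cutoff, prewhiten)
                for s in index_series_set]
    out = []
    for p in prepared:
        master = build_master(index_series_set, p.owner_id,
                              _prepared=prepared)
        try:
            out.append(segment_correlations(p, master, seg_length,
                                            seg_overlap, max_lag, alpha))
        except ValidationError:
            out.append(CrossdateResult(series_id=p.owner_id, segments=(),
                                       interseries_r=np.nan))
    return out


def interseries_correlation(ims_set: Sequence[IndexSeries],
                            min_overlap: int = 5) -> tuple[pd.DataFrame, float]:
    """Pearson r between each series and the mean of all others.

    The summary interseries correlation is the mean of the per-series r
    over series with at least ``min_overlap`` years in common with the
    leave-one-out mean; shorter-overlap series are flagged and excluded
    from the mean.
    """
    ims_set = list(ims_set)
    if len(ims_set) < 3:
        raise ValidationError("need at least 3 series")
    first = min(s.first_year for s in ims_set)
    last = max(s.last_year for s in ims_set)
    mat = np.full((last - first + 1, len(ims_set)), np.nan)
    for j, s in enumerate(ims_set):
        i0 = s.first_year - first
        mat[i0 : i0 + len(s.indices), j] = s.indices
    rows = []
    for j, s in enumerate(ims_set):
        others = np.delete(mat, j, axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            loo_mean = np.nanmean(others, axis=1)
        ok = np.isfinite(mat[:, j]) & np.isfinite(loo_mean)
        r = _pearson(mat[:, j], loo_mean)
        rows.append({"owner_id": s.owner_id, "r": r,
                     "n_overlap": int(ok.sum()),
                     "flagged": bool(ok.sum() < min_overlap)})
    df = pd.DataFrame(rows)
    usable = df.loc[~df["flagged"], "r"].dropna()
    return df, float(usable.mean()) if len(usable) else np.nan
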