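"""Mean index chronology and signal-strength statistics.

The population growth signal is summarised by the mean index chronology
(MIC): the year-wise mean of all fish's individual mean series (IMS).  How
well a finite sample expresses the (hypothetical) population chronology is
quantified per window by

* rbar — the mean of all pairwise Pearson correlations between IMS fully
  covering the window, excluding self-correlations;
* EPS  — the expressed population signal, n*rbar / (1 + (n-1)*rbar), with n
  the number of covering series;
* mean sensitivity — mean of 2|x_{t+1} - x_t| / (x_{t+1} + x_t), a relative
  year-to-year variability statistic.

An analysis window is selected by requiring rbar - 2*s.e.(rbar) > 0 over a
fixed-length (default 15-year) segment; among qualifying windows the one
containing the most pairwise correlations wins, ties going to the earliest
start year.  The s.e. treats the pairwise correlations as independent, which
they are not exactly (pairs share series); this matches the simplicity of
the selection criterion and is noted as a caveat in the docs.

Autocorrelation is handled ARSTAN-style: each IMS is prewhitened with an
AIC-selected AR(p) model, the residual chronology is the mean of the
prewhitened series, and the "arstan" variant reintroduces the pooled AR
structure into that residual chronology.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.tsa.ar_model import AutoReg, ar_select_order

from .io import Chronology, IndexSeries, ValidationError


@dataclass(frozen=True)
class ChronStats:
    """Signal statistics for one chronology window."""

    window_start: int
    window_end: int
    rbar: float
    rbar_se: float
    n_pairs: int
    sample_depth: int
    eps: float
    mean_sensitivity: float

    def qualifies(self) -> bool:
        """Signal-adequacy criterion: rbar - 2*s.e. strictly positive."""
        return self.rbar - 2.0 * self.rbar_se > 0


def tukey_biweight_mean(x: np.ndarray, c: float = 9.0) -> float:
    """Tukey's biweight robust mean (the chronology-building convention)."""
    x = np.asarray(x, dtype=float)
    med = np.median(x)
    s = np.median(np.abs(x - med))
    if s == 0:
        return float(med)
    u = (x - med) / (c * s)
    w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
    return float(np.sum(w * x) / np.sum(w))


def _stack(series: Sequence[IndexSeries]) -> tuple[int, np.ndarray]:
    """Stack index series into a (years x series) matrix, NaN-padded."""
    series = list(series)
    first = min(s.first_year for s in series)
    last = max(s.last_year for s in series)
    mat = np.full((last - first + 1, len(series)), np.nan)
    for j, s in enumerate(series):
        i0 = s.first_year - first
        mat[i0 : i0 + len(s.indices), j] = s.indices
    return first, mat


def mean_chronology(ims_set: Sequence[IndexSeries], robust: bool = False,
                    variant: str = "standard") -> Chronology:
    """Year-wise mean of the IMS present each year, with sample depth.

    robust=True uses the Tukey biweight mean instead of the arithmetic mean
    wherever at least 6 series are present (the biweight is unstable at
    smaller depths).
    """
    if not ims_set:
        raise ValidationError("no series to average")
    first, mat = _stack(ims_set)
    depth = np.sum(np.isfinite(mat), axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN years
        values = np.nanmean(mat, axis=1)
    if robust:
        for i in np.nonzero(depth >= 6)[0]:
            row = mat[i][np.isfinite(mat[i])]
            values[i] = tukey_biweight_mean(row)
    return Chronology(first_year=first, values=values, sample_depth=depth,
                      variant=variant)


def mean_sensitivity(series) -> float:
    """Mean of 2|x_{t+1} - x_t| / (x_{t+1} + x_t) over successive years."""
    x = np.asarray(series, dtype=float)
    if len(x) < 2:
        raise ValidationError("mean sensitivity needs at least 2 values")
    if np.any(x <= 0):
        raise ValidationError("mean sensitivity requires positive values")
    return float(np.mean(2.0 * np.abs(np.diff(x)) / (x[1:] + x[:-1])))


def eps(rbar: float, n: int) -> float:
    """Expressed population signal n*rbar / (1 + (n-1)*rbar)."""
    if n < 1:
        raise ValidationError("sample depth must be >= 1")
    denom = 1.0 + (n - 1) * rbar
    if denom <= 0:
        raise ValidationError(
            f"EPS undefined: 1 + (n-1)*rbar = {denom:.4g} <= 0"
        )
    return n * rbar / denom


def rbar_windowed(ims_set: Sequence[IndexSeries], window_length: int = 15,
                  step: int = 1) -> list[ChronStats]:
    """Signal statistics for every sliding window of ``window_length`` years.

    Only series fully covering a window contribute to it; windows with fewer
    than two covering series yield no entry (undefined, not zero).  Pairwise
    correlations that are undefined (a series constant within the window)
    are dropped from the mean.
    """
    if window_length < 5:
        raise ValidationError("window_length must be >= 5")
    first, mat = _stack(ims_set)
    n_years = mat.shape[0]
    out: list[ChronStats] = []
    for i0 in range(0, n_years - window_length + 1, step):
        sub = mat[i0 : i0 + window_length]
        covering = np.all(np.isfinite(sub), axis=0)
        depth = int(covering.sum())
        if depth < 2:
            continue
        block = sub[:, covering]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            corr = np.corrcoef(block, rowvar=False)
        iu = np.triu_indices(depth, k=1)
        pairs = corr[iu]
        pairs = pairs[np.isfinite(pairs)]
        if pairs.size == 0:
            continue
        rbar = float(pairs.mean())
        se = float(pairs.std(ddof=1) / np.sqrt(pairs.size)) if pairs.size > 1 else 0.0
        ms = float(np.mean([mean_sensitivity(block[:, j])
                            for j in range(depth)]))
        out.append(
            ChronStats(
                window_start=first + i0,
                window_end=first + i0 + window_length - 1,
                rbar=rbar,
                rbar_se=se,
                n_pairs=int(pairs.size),
                sample_depth=depth,
                eps=eps(rbar, depth) if rbar > -1.0 / max(depth - 1, 1) else np.nan,
                mean_sensitivity=ms,
            )
        )
    return out


def select_window(stats: Sequence[ChronStats]) -> ChronStats | None:
    """Pick the analysis window: rbar - 2*s.e. > 0, then most pairwise
    correlations, ties broken by earliest start year.

    Returns None when no window qualifies ("no adequate signal") — a
    legitimate scientific outcome, not an error.
    """
    qualifiers = [s for s in stats if s.qualifies()]
    if not qualifiers:
        return None
    return max(qualifiers, key=lambda s: (s.n_pairs, -s.window_start))


def stats_frame(stats: Sequence[ChronStats]) -> pd.DataFrame:
    return pd.DataFrame([dataclass_to_row(s) for s in stats])


def dataclass_to_row(s: ChronStats) -> dict:
    return {
        "window_start": s.window_start, "window_end": s.window_end,
        "rbar": s.rbar, "rbar_se": s.rbar_se, "n_pairs": s.n_pairs,
        "sample_depth": s.sample_depth, "eps": s.eps,
        "mean_sensitivity": s.mean_sensitivity,
    }


# ---------------------------------------------------------------------------
# autoregressive standardization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _RawSeries:
    """A yearly series with no positivity constraint (prewhitened residuals)."""

    owner_id: str
    first_year: int
    indices: np.ndarray

    @property
    def last_year(self) -> int:
        return self.first_year + len(self.indices) - 1


@dataclass(frozen=True)
class ARStandardization:
    """Residual and AR-reintroduced ("arstan") chronology variants plus the
    per-series AR modelling report."""

    residual: Chronology
    ar_standardized: Chronology
    orders: pd.DataFrame
    pooled_order: int
    pooled_coefs: np.ndarray


def _fit_ar(x: np.ndarray, max_order: int) -> tuple[int, np.ndarray, np.ndarray, bool]:
    """AIC-selected AR(p) fit; returns (order, coefs, residuals, fallback)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sel = ar_select_order(x, maxlag=max_order, ic="aic", trend="c",
                              old_names=False)
        order = max(sel.ar_lags) if sel.ar_lags else 0
        res = AutoReg(x, lags=order, trend="c", old_names=False).fit()
    fallback = False
    if order > 0:
        roots = res.roots
        if np.any(np.abs(roots) <= 1.0 + 1e-10):
            # non-stationary fit: keep the series unwhitened
            order, fallback = 0, True
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = AutoReg(x, lags=0, trend="c", old_names=False).fit()
    coefs = res.params[1:] if order > 0 else np.empty(0)
    return order, np.asarray(coefs, dtype=float), np.asarray(res.resid), fallback


def ar_standardize(ims_set: Sequence[IndexSeries], max_order: int = 3
                   ) -> ARStandardization:
    """ARSTAN-style autocorrelation handling for a set of index series.

    Each series is prewhitened with an AR(p) model (p chosen by AIC,
    0 <= p <= max_order); its residuals, recentred to mean 1, form the
    prewhitened series (losing the first p years).  The residual chronology
    is the year-wise mean of those series.  The "arstan" variant feeds the
    residual chronology through the pooled AR recursion (coefficients
    averaged across series, weighted by series length) to reintroduce the
    common persistence structure.
    """
    if not ims_set:
        raise ValidationError("no series to standardize")
    prewhitened: list[_RawSeries] = []
    rows = []
    all_coefs, weights = [], []
    for s in ims_set:
        x = np.asarray(s.indices, dtype=float)
        if len(x) <= max_order + 5:
            raise ValidationError(
                f"series {s.owner_id} too short for AR order {max_order}"
            )
        order, coefs, resid, fallback = _fit_ar(x, max_order)
        # prewhitened residuals may legitimately dip <= 0, so they live in a
        # plain container rather than an IndexSeries
        prewhitened.append(
            _RawSeries(s.owner_id, s.first_year + order, resid - resid.mean() + 1.0)
        )
        rows.append({"owner_id": s.owner_id, "order": order,
                     "fallback": fallback,
                     "coefs": coefs.tolist()})
        all_coefs.append(coefs)
        weights.append(len(x))
    residual = _mean_any(prewhitened, variant="residual")
    pooled_order = max((len(c) for c in all_coefs), default=0)
    if pooled_order == 0:
        pooled = np.empty(0)
        arstan = Chronology(residual.first_year, residual.values.copy(),
                            residual.sample_depth.copy(),
                            variant="ar_standardized")
    else:
        padded = np.array([np.pad(c, (0, pooled_order - len(c))) for c in all_coefs])
        wts = np.asarray(weights, dtype=float)
        pooled = (padded * wts[:, None]).sum(axis=0) / wts.sum()
        v = residual.values.copy()
        out = v.copy()
        for t in range(len(v)):
            if not np.isfinite(v[t]):
                continue
            acc = v[t]
            for k in range(1, pooled_order + 1):
                if t - k >= 0 and np.isfinite(out[t - k]):
                    acc += pooled[k - 1] * (out[t - k] - 1.0)
            out[t] = acc
        arstan = Chronology(residual.first_year, out,
                            residual.sample_depth.copy(),
                            variant="ar_standardized")
    return ARStandardization(residual=residual, ar_standardized=arstan,
                             orders=pd.DataFrame(rows),
                             pooled_order=pooled_order, pooled_coefs=pooled)


def _mean_any(series_list: Sequence[IndexSeries], variant: str) -> Chronology:
    """Year-wise mean that tolerates non-positive values (residual series)."""
    first = min(s.first_year for s in series_list)
    last = max(s.last_year for s in series_list)
    mat = np.full((last - first + 1, len(series_list)), np.nan)
    for j, s in enumerate(series_list):
        i0 = s.first_year - first
        mat[i0 : i0 + len(s.indices), j] = s.indices
    depth = np.sum(np.isfinite(mat), axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        values = np.nanmean(mat, axis=1)
    return Chronology(first_year=first, values=values, sample_depth=depth,
                      variant=variant)
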