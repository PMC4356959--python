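"""High-level modelling interface: fit a growth chronology to a dataset.

``OtolithChronology`` is constructed from fish records (or a long-format
DataFrame) and fixed analysis settings; ``fit()`` runs detrending,
crossdating quality control, chronology building, AR standardization and
window selection, returning a ``ChronologyResults`` object that carries the
estimates, diagnostics and a ``summary()`` table, and from which
environmental correlations and plots hang.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import chronology as chron_mod
from . import crossdate as cross_mod
from . import detrend as detrend_mod
from . import envcorr as env_mod
from .io import Chronology, FishRecord, IndexSeries, ValidationError, records_from_frame


class OtolithChronology:
    """Growth-increment chronology model for a set of measured fish.

    Parameters
    ----------
    records : iterable of FishRecord
        The measured fish; each carries 3-5 transect series.
    cutoff_years : float
        50% frequency cutoff (years) of the detrending spline.
    window_length : int
        Length of the candidate analysis windows (years).
    robust : bool
        Use the Tukey biweight instead of the arithmetic mean when
        averaging index series into the chronology.
    ar_max_order : int
        Maximum AR order considered in autoregressive standardization.
    crossdate_kwargs : dict, optional
        Overrides for the crossdating QC settings (seg_length, max_lag,
        alpha, highpass_cutoff, prewhiten).
    """

    def __init__(self, records: Iterable[FishRecord], cutoff_years: float = 9.0,
                 window_length: int = 15, robust: bool = False,
                 ar_max_order: int = 3, min_transects: int = 3,
                 max_transects: int = 5,
                 crossdate_kwargs: dict | None = None):
        self.records = [r.validate_counts(min_transects, max_transects)
                        for r in records]
        if not self.records:
            raise ValidationError("no fish records")
        self.cutoff_years = float(cutoff_years)
        self.window_length = int(window_length)
        self.robust = bool(robust)
        self.ar_max_order = int(ar_max_order)
        self.crossdate_kwargs = dict(crossdate_kwargs or {})

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "OtolithChronology":
        """Build from a long table with columns fish_id, transect_id, year,
        width_mm (and optionally capture_year, age_at_capture)."""
        return cls(records_from_frame(df), **kwargs)

    def fit(self, crossdate: bool = True) -> "ChronologyResults":
        ims, detrend_report = detrend_mod.detrend_dataset(
            self.records, self.cutoff_years
        )
        inter_df, inter_mean = cross_mod.interseries_correlation(ims)
        crossdating = (
            cross_mod.crossdate_all(
                ims, seg_length=self.crossdate_kwargs.get(
                    "seg_length", self.window_length),
                **{k: v for k, v in self.crossdate_kwargs.items()
                   if k != "seg_length"},
            )
            if crossdate and len(ims) >= 3
            else []
        )
        standard = chron_mod.mean_chronology(ims, robust=self.robust)
        ar = chron_mod.ar_standardize(ims, max_order=self.ar_max_order)
        stats = chron_mod.rbar_windowed(ims, window_length=self.window_length)
        selected = chron_mod.select_window(stats)
        ms = pd.Series(
            {s.owner_id: chron_mod.mean_sensitivity(s.indices) for s in ims},
            name="mean_sensitivity",
        )
        return ChronologyResults(
            model=self, ims_=ims, detrend_report_=detrend_report,
            interseries_=inter_df, interseries_r_=inter_mean,
            crossdating_=crossdating, chronology_=standard,
            residual_chronology_=ar.residual,
            arstan_chronology_=ar.ar_standardized, ar_report_=ar.orders,
            window_stats_=stats, selected_window_=selected,
            mean_sensitivity_=ms,
        )


@dataclass
class ChronologyResults:
    """Fitted chronology, its signal diagnostics and downstream analyses."""

    model: OtolithChronology
    ims_: list
    detrend_report_: pd.DataFrame
    interseries_: pd.DataFrame
    interseries_r_: float
    crossdating_: list
    chronology_: Chronology
    residual_chronology_: Chronology
    arstan_chronology_: Chronology
    ar_report_: pd.DataFrame
    window_stats_: list
    selected_window_: object  # ChronStats or None
    mean_sensitivity_: pd.Series

    # -- convenience accessors -------------------------------------------
    @property
    def has_adequate_signal(self) -> bool:
        return self.selected_window_ is not None

    @property
    def window(self) -> tuple[int, int] | None:
        s = self.selected_window_
        return None if s is None else (s.window_start, s.window_end)

    def chronology(self, variant: str = "ar_standardized") -> Chronology:
        return {
            "standard": self.chronology_,
            "residual": self.residual_chronology_,
            "ar_standardized": self.arstan_chronology_,
        }[variant]

    def window_stats_frame(self) -> pd.DataFrame:
        return chron_mod.stats_frame(self.window_stats_)

    def crossdating_frame(self) -> pd.DataFrame:
        frames = [c.to_frame() for c in self.crossdating_ if len(c.segments)]
        return (pd.concat(frames, ignore_index=True)
                if frames else pd.DataFrame())

    def flagged_series(self) -> list[str]:
        return [c.series_id for c in self.crossdating_ if c.flagged]

    # -- downstream analyses ---------------------------------------------
    def correlate(self, env_set, window: tuple[int, int] | None = None,
                  variant: str = "ar_standardized", bh_adjust: bool = False):
        """Lagged environmental correlations of the windowed chronology."""
        window = window or self.window
        if window is None:
            raise ValidationError(
                "no adequate-signal window selected; pass window= explicitly"
            )
        return env_mod.lagged_correlations(
            self.chronology(variant), window, env_set, bh_adjust=bh_adjust
        )

    def correlation_table(self, env_set, **kwargs) -> pd.DataFrame:
        return env_mod.correlation_table(self.correlate(env_set, **kwargs))

    def summary(self) -> str:
        """Plain-text summary in the spirit of a model-results table."""
        m = self.model
        lines = [
            "Otolith growth-increment chronology",
            "=" * 51,
            f"{'No. fish (IMS):':<34}{len(self.ims_):>17d}",
            f"{'No. transect series:':<34}{len(self.detrend_report_):>17d}",
            f"{'Spline cutoff (50% response, yr):':<34}{m.cutoff_years:>17.1f}",
            f"{'Span (years):':<34}"
            f"{str(self.chronology_.first_year) + '-' + str(int(self.chronology_.years[-1])):>17}",
            f"{'Interseries correlation:':<34}{self.interseries_r_:>17.3f}",
            f"{'Mean sensitivity (IMS mean):':<34}{self.mean_sensitivity_.mean():>17.3f}",
            f"{'Crossdating flags:':<34}{len(self.flagged_series()):>17d}",
            "-" * 51,
        ]
        s = self.selected_window_
        if s is None:
            lines.append("Selected window: none (no adequate signal; no "
                         f"{m.window_length}-yr segment with rbar - 2 s.e. > 0)")
        else:
            lines += [
                f"{'Selected window:':<34}"
                f"{str(s.window_start) + '-' + str(s.window_end):>17}",
                f"{'  rbar (mean pairwise r):':<34}{s.rbar:>17.3f}",
                f"{'  s.e. of rbar:':<34}{s.rbar_se:>17.3f}",
                f"{'  pairwise correlations:':<34}{s.n_pairs:>17d}",
                f"{'  sample depth:':<34}{s.sample_depth:>17d}",
                f"{'  EPS:':<34}{s.eps:>17.2f}",
            ]
        lines.append("=" * 51)
        return "\n".join(lines)

    def plot(self, ax=None):
        """IMS spaghetti, mean chronology and sample depth."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        for s in self.ims_:
            ax.plot(s.years, s.indices, color="0.8", lw=0.6, zorder=1)
        c = self.chronology_
        ax.plot(c.years, c.values, color="k", lw=1.5, zorder=3,
                label="mean index chronology")
        if self.window is not None:
            ax.axvspan(*self.window, color="tab:blue", alpha=0.12,
                       label="selected window")
        ax.set_xlabel("year")
        ax.set_ylabel("growth index")
        ax2 = ax.twinx()
        ax2.fill_between(c.years, c.sample_depth, color="tab:grey",
                         alpha=0.2, step="mid")
        ax2.set_ylabel("sample depth")
        ax.legend(loc="upper left", frameon=False, fontsize=8)
        return ax
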