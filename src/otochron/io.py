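"""Data model and readers/writers for increment series and chronologies.

Widths are stored internally in millimetres as floats.  The Tucson (RWL)
writer emits the most common dialect: integer widths in units of 0.001 mm
with a ``-9999`` end-of-series sentinel; the reader additionally accepts the
0.01 mm dialect with a ``999`` sentinel.

Calendar convention: an annual increment forms over a "growth year" running
from about November of one calendar year through October of the next, and is
labelled with the calendar year that contains most of that growth (the later
one).  The outermost, partial increment at the otolith edge is never
assigned a year.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class ParseError(ValueError):
    """A file did not conform to its declared format."""


class ValidationError(ValueError):
    """Data violated a structural invariant (gaps, non-positive widths...)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

def _as_float_array(x) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim != 1:
        raise ValidationError("expected a 1-d sequence")
    return a


@dataclass(frozen=True)
class TransectSeries:
    """Increment widths (mm) measured along one transect of one otolith.

    Years are contiguous from ``first_year``; all widths must be positive.
    """

    fish_id: str
    transect_id: str
    first_year: int
    widths: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "widths", _as_float_array(self.widths))
        if len(self.widths) < 2:
            raise ValidationError(
                f"series {self.fish_id}/{self.transect_id}: length must be >= 2"
            )
        if np.any(~np.isfinite(self.widths)) or np.any(self.widths <= 0):
            bad = int(self.first_year + np.argmax(~(self.widths > 0)))
            raise ValidationError(
                f"series {self.fish_id}/{self.transect_id}: non-positive or "
                f"missing width at year {bad}"
            )

    @property
    def years(self) -> np.ndarray:
        return self.first_year + np.arange(len(self.widths))

    @property
    def last_year(self) -> int:
        return self.first_year + len(self.widths) - 1

    @property
    def series_id(self) -> str:
        return f"{self.fish_id}_{self.transect_id}"


@dataclass(frozen=True)
class FishRecord:
    """One fish: its capture metadata and 3-5 measured transects."""

    fish_id: str
    capture_year: int
    transects: tuple
    age_at_capture: int | None = None
    sex: str | None = None
    length_cm: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "transects", tuple(self.transects))
        for t in self.transects:
            if t.last_year > self.capture_year:
                raise ValidationError(
                    f"fish {self.fish_id}: transect {t.transect_id} extends to "
                    f"{t.last_year}, after capture year {self.capture_year}"
                )

    def validate_counts(self, min_transects: int = 3, max_transects: int = 5):
        k = len(self.transects)
        if not min_transects <= k <= max_transects:
            raise ValidationError(
                f"fish {self.fish_id}: {k} transects outside "
                f"[{min_transects}, {max_transects}]"
            )
        return self


#: level tags for IndexSeries
TRANSECT, IMS, MIC = "transect", "ims", "mic"


@dataclass(frozen=True)
class IndexSeries:
    """A detrended, dimensionless index series (per transect, per fish, or
    the population mean)."""

    owner_id: str
    level: str
    first_year: int
    indices: np.ndarray

    def __post_init__(self):
        if self.level not in (TRANSECT, IMS, MIC):
            raise ValidationError(f"unknown level {self.level!r}")
        object.__setattr__(self, "indices", _as_float_array(self.indices))
        if np.any(self.indices <= 0):
            raise ValidationError(f"series {self.owner_id}: non-positive index")

    @property
    def years(self) -> np.ndarray:
        return self.first_year + np.arange(len(self.indices))

    @property
    def last_year(self) -> int:
        return self.first_year + len(self.indices) - 1


@dataclass(frozen=True)
class Chronology:
    """Yearly mean index values with per-year sample depth."""

    first_year: int
    values: np.ndarray
    sample_depth: np.ndarray
    variant: str = "standard"

    def __post_init__(self):
        object.__setattr__(self, "values", _as_float_array(self.values))
        object.__setattr__(
            self, "sample_depth", np.asarray(self.sample_depth, dtype=int)
        )
        if len(self.values) != len(self.sample_depth):
            raise ValidationError("values and sample_depth lengths differ")
        defined = np.isfinite(self.values)
        if np.any(self.sample_depth[defined] < 1):
            raise ValidationError("value defined in a year with sample depth 0")

    @property
    def years(self) -> np.ndarray:
        return self.first_year + np.arange(len(self.values))

    def window(self, start: int, end: int) -> np.ndarray:
        """Values for calendar years ``start..end`` inclusive."""
        i0, i1 = start - self.first_year, end - self.first_year
        if i0 < 0 or i1 >= len(self.values):
            raise ValidationError(
                f"window {start}-{end} outside chronology span "
                f"{self.first_year}-{int(self.years[-1])}"
            )
        return self.values[i0 : i1 + 1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.years,
                "value": self.values,
                "sample_depth": self.sample_depth,
                "variant": self.variant,
            }
        )


SEASONS = ("annual", "DJF", "MAM", "JJA", "SON")


@dataclass(frozen=True)
class EnvSeries:
    """An annual environmental variable, possibly a seasonal mean."""

    name: str
    years: np.ndarray
    values: np.ndarray
    season: str = "annual"
    preprocessing: tuple = ()

    def __post_init__(self):
        if self.season not in SEASONS:
            raise ValidationError(f"unknown season {self.season!r}")
        object.__setattr__(self, "years", np.asarray(self.years, dtype=int))
        object.__setattr__(self, "values", _as_float_array(self.values))
        object.__setattr__(self, "preprocessing", tuple(self.preprocessing))
        if len(self.years) != len(self.values):
            raise ValidationError("years and values lengths differ")
        if np.any(np.diff(self.years) <= 0):
            raise ValidationError(f"{self.name}: years not strictly increasing")

    def value_for(self, years: Sequence[int]) -> np.ndarray:
        """Values for the requested years; NaN where absent."""
        lookup = dict(zip(self.years.tolist(), self.values.tolist()))
        return np.array([lookup.get(int(y), np.nan) for y in years])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.years, "value": self.values})


@dataclass(frozen=True)
class MonthlyEnvSeries:
    """A monthly environmental variable (input to seasonal averaging)."""

    name: str
    years: np.ndarray
    months: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "years", np.asarray(self.years, dtype=int))
        object.__setattr__(self, "months", np.asarray(self.months, dtype=int))
        object.__setattr__(self, "values", _as_float_array(self.values))
        if not (len(self.years) == len(self.months) == len(self.values)):
            raise ValidationError("years/months/values lengths differ")
        if np.any((self.months < 1) | (self.months > 12)):
            raise ValidationError("month outside 1..12")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"year": self.years, "month": self.months, "value": self.values}
        )


# ---------------------------------------------------------------------------
# Tucson (RWL) ring-width exchange format
# ---------------------------------------------------------------------------

def write_rwl(series: Iterable[TransectSeries], path, units: float = 0.001):
    """Write series in Tucson decadal-row layout.

    Values are rounded to integer multiples of ``units`` mm (default
    0.001 mm, sentinel -9999).
    """
    if units not in (0.001, 0.01):
        raise ValueError("units must be 0.001 or 0.01 mm")
    sentinel = -9999 if units == 0.001 else 999
    lines = []
    for s in series:
        sid = s.series_id[:8]
        vals = {int(y): int(round(w / units)) for y, w in zip(s.years, s.widths)}
        vals[s.last_year + 1] = sentinel
        year = s.first_year
        while year <= s.last_year + 1:
            decade_end = (year // 10) * 10 + 9
            row_years = range(year, min(decade_end, s.last_year + 1) + 1)
            cells = "".join(f"{vals[y]:6d}" for y in row_years)
            lines.append(f"{sid:<8s}{year:4d}{cells}")
            year = decade_end + 1
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_rwl(path) -> list[TransectSeries]:
    """Read a Tucson RWL file into TransectSeries (widths in mm).

    Accepts the 0.001 mm (-9999 sentinel) and 0.01 mm (999 sentinel)
    dialects; the dialect is inferred per series from its sentinel.
    """
    raw: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    for lineno, line in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not line.strip():
            continue
        sid = line[:8].strip()
        try:
            decade_year = int(line[8:12])
        except ValueError as exc:
            raise ParseError(f"line {lineno}: malformed decade year") from exc
        body = line[12:]
        cells = [body[i : i + 6] for i in range(0, len(body), 6)]
        values = []
        for c in cells:
            c = c.strip()
            if not c:
                continue
            try:
                values.append(int(c))
            except ValueError as exc:
                raise ParseError(f"line {lineno}: malformed value {c!r}") from exc
        if sid not in raw:
            raw[sid] = []
            order.append(sid)
        for k, v in enumerate(values):
            raw[sid].append((decade_year + k, v))

    out = []
    for sid in order:
        pairs = raw[sid]
        years = [y for y, _ in pairs]
        if years != list(range(years[0], years[0] + len(years))):
            raise ParseError(f"series {sid}: non-contiguous decade rows")
        vals = [v for _, v in pairs]
        if vals and vals[-1] == -9999:
            units, vals = 0.001, vals[:-1]
        elif vals and vals[-1] == 999:
            units, vals = 0.01, vals[:-1]
        else:
            units = 0.001  # sentinel absent: assume default dialect
        if not vals:
            raise ParseError(f"series {sid}: no data values")
        widths = np.array(vals, dtype=float) * units
        if np.any(widths <= 0):
            bad = years[int(np.argmax(widths <= 0))]
            raise ValidationError(f"series {sid}: non-positive width at {bad}")
        fish_id, _, transect_id = sid.partition("_")
        out.append(
            TransectSeries(
                fish_id=fish_id,
                transect_id=transect_id or "1",
                first_year=years[0],
                widths=widths,
            )
        )
    return out


# ---------------------------------------------------------------------------
# long CSV
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["fish_id", "transect_id", "year", "width_mm"]


def write_increment_csv(records: Iterable[FishRecord], path):
    rows = []
    for r in records:
        for t in r.transects:
            for y, w in zip(t.years, t.widths):
                rows.append(
                    {
                        "fish_id": r.fish_id,
                        "transect_id": t.transect_id,
                        "year": int(y),
                        "width_mm": w,
                        "capture_year": r.capture_year,
                        "age_at_capture": r.age_at_capture,
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def records_from_frame(df: pd.DataFrame) -> list[FishRecord]:
    """Group a long (fish_id, transect_id, year, width_mm) table into
    FishRecords, validating contiguity and uniqueness."""
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"missing required columns: {missing}")
    dup = df.duplicated(subset=["fish_id", "transect_id", "year"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValidationError(
            f"duplicate measurement for fish {row.fish_id} transect "
            f"{row.transect_id} year {int(row.year)}"
        )
    records = []
    for fish_id, fish_df in df.groupby("fish_id", sort=True):
        transects = []
        for transect_id, tdf in fish_df.groupby("transect_id", sort=True):
            tdf = tdf.sort_values("year")
            years = tdf["year"].to_numpy(dtype=int)
            gaps = np.nonzero(np.diff(years) != 1)[0]
            if gaps.size:
                raise ValidationError(
                    f"fish {fish_id} transect {transect_id}: gap at year "
                    f"{int(years[gaps[0]] + 1)}"
                )
            transects.append(
                TransectSeries(
                    fish_id=str(fish_id),
                    transect_id=str(transect_id),
                    first_year=int(years[0]),
                    widths=tdf["width_mm"].to_numpy(dtype=float),
                )
            )
        last = max(t.last_year for t in transects)
        if "capture_year" in fish_df.columns and fish_df["capture_year"].notna().all():
            capture_year = int(fish_df["capture_year"].iloc[0])
        else:
            capture_year = last + 1  # outermost partial year was dropped
        age = None
        if "age_at_capture" in fish_df.columns and fish_df["age_at_capture"].notna().all():
            age = int(fish_df["age_at_capture"].iloc[0])
        records.append(
            FishRecord(
                fish_id=str(fish_id),
                capture_year=capture_year,
                age_at_capture=age,
                transects=tuple(transects),
            )
        )
    return records


def read_increment_csv(path) -> list[FishRecord]:
    """Read a long-format increment table (one row per fish/transect/year)."""
    return records_from_frame(pd.read_csv(path))


def read_env_csv(path, name: str | None = None):
    """Read an environmental CSV keyed by year (annual) or year,month
    (monthly).  Returns EnvSeries or MonthlyEnvSeries accordingly."""
    df = pd.read_csv(path)
    if "year" not in df.columns or "value" not in df.columns:
        raise ParseError("environmental CSV needs 'year' and 'value' columns")
    name = name or Path(path).stem
    if "month" in df.columns:
        return MonthlyEnvSeries(
            name=name,
            years=df["year"].to_numpy(dtype=int),
            months=df["month"].to_numpy(dtype=int),
            values=df["value"].to_numpy(dtype=float),
        )
    df = df.sort_values("year")
    return EnvSeries(
        name=name,
        years=df["year"].to_numpy(dtype=int),
        values=df["value"].to_numpy(dtype=float),
    )


def write_env_csv(env, path):
    env.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# growth-year assignment
# ---------------------------------------------------------------------------

def assign_growth_years(
    increment_ordinal_ages: Sequence[int],
    capture_year: int,
    capture_month: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Label increments with calendar years, dropping the outer partial one.

    A growth year runs from about November of year ``y - 1`` through October
    of year ``y`` and is labelled ``y`` (the year containing most of the
    growth).  The outermost increment listed — the one still forming at
    capture — is excluded.  If the fish was captured in November or December
    the increment that ended the previous October is complete, so the last
    labelled year equals the capture year; for any earlier capture month it
    is the year before.

    Returns ``(retained_ages, years)``, oldest first.
    """
    ages = np.asarray(increment_ordinal_ages, dtype=int)
    if len(ages) < 2:
        raise ValidationError("need at least two increments (one is partial)")
    if np.any(np.diff(ages) <= 0):
        raise ValidationError("increment ages must be strictly increasing")
    if not 1 <= capture_month <= 12:
        raise ValidationError("capture_month outside 1..12")
    last_complete = capture_year if capture_month >= 11 else capture_year - 1
    retained = ages[:-1]
    years = last_complete - np.arange(len(retained))[::-1]
    if years[-1] > capture_year:
        raise ValidationError("labelled year exceeds capture year")
    return retained, years
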