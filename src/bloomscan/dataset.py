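"""Weekly modelling grid, sliding windows, normalization and year splits.

The forecasting grid is weekly because the target (algae counts) is a
weekly lab quantity.  Mixed-cadence observations are reconciled onto
that grid: sensor factors are averaged within each week's +-3.5 day bin,
lab factors enter as the week's point value.  Windows of ``W`` (default
7) consecutive weeks of date fields + algae + a chosen factor subset are
flattened lag-major into model inputs, with the subset's factors plus
algae one week ahead (horizon ``h`` = 1) as the multi-output target.

Normalization is min-max to [0, 1] fitted on the training years only;
validation and application values may leave [0, 1] and are deliberately
not clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, MissingFactorError
from .series import WEEKLY, ObservationSeries

__all__ = [
    "DATE_FIELDS",
    "SplitSpec",
    "WeeklyTable",
    "WindowedDataset",
    "Normalizer",
    "to_weekly",
    "build_windows",
    "fit_normalizer",
]

DATE_FIELDS = ("year", "month", "day")

_WEEK = pd.Timedelta(days=7)


@dataclass(frozen=True)
class SplitSpec:
    """Disjoint year sets for training / validation / application."""

    training_years: tuple[int, ...] = (2015, 2016, 2017, 2018, 2019)
    validation_years: tuple[int, ...] = (2020,)
    application_years: tuple[int, ...] = (2022,)

    def __post_init__(self):
        sets = [set(self.training_years), set(self.validation_years),
                set(self.application_years)]
        total = sum(len(s) for s in sets)
        if len(set().union(*sets)) != total:
            raise ConfigError("split year sets must be disjoint")

    def periods(self) -> dict[str, tuple[int, ...]]:
        return {
            "training": self.training_years,
            "validation": self.validation_years,
            "application": self.application_years,
        }


@dataclass
class WeeklyTable:
    """One row per modelling week.

    ``frame`` columns: ``date`` (representative timestamp), the numeric
    date fields ``year``/``month``/``day``, ``week_index`` (position on
    the 7-day lattice; jumps mark data gaps), then one column per factor.
    """

    frame: pd.DataFrame
    aggregation: dict[str, str] = field(default_factory=dict)
    policy: str = "drop"

    @property
    def factors(self) -> list[str]:
        reserved = {"date", "week_index", *DATE_FIELDS}
        return [c for c in self.frame.columns if c not in reserved]

    def rows_in_years(self, years: Iterable[int]) -> pd.DataFrame:
        return self.frame[self.frame["year"].isin(list(years))]

    def __len__(self) -> int:
        return len(self.frame)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def to_weekly(
    series: ObservationSeries,
    policy: str = "interpolate",
    max_interp_weeks: int = 2,
) -> WeeklyTable:
    """Collapse a mixed-cadence observation series onto the weekly grid.

    The grid rows are the weeks at which any weekly-cadence (lab or
    derived-weekly) factor was observed; sensor observations are averaged
    into the +-3.5 day bin around each row.  Rows missing a factor are
    linearly interpolated across at most ``max_interp_weeks`` consecutive
    missing weeks (``policy="interpolate"``) or dropped
    (``policy="drop"``); the policy is recorded on the result.
    """
    if policy not in ("interpolate", "drop"):
        raise ConfigError(f"unknown missing-week policy {policy!r}")
    data = series.data
    if data.empty:
        raise DataError("cannot build a weekly table from an empty series")
    weekly_mask = data["cadence"] == WEEKLY
    if not weekly_mask.any():
        raise DataError("series has no weekly-cadence factor to anchor the grid")
    lab = data.loc[weekly_mask]
    t0 = lab["timestamp"].min()

    def to_index(ts: pd.Series) -> np.ndarray:
        return np.rint((ts - t0) / _WEEK).astype(int)

    lab_idx = to_index(lab["timestamp"])
    rows = (
        pd.DataFrame({"week_index": lab_idx, "timestamp": lab["timestamp"]})
        .groupby("week_index", as_index=False)["timestamp"].min()
        .rename(columns={"timestamp": "date"})
    )
    table = rows.set_index("week_index")

    aggregation: dict[str, str] = {}
    for factor in series.factors():
        rows_f = data[data["factor"] == factor]
        cadence = rows_f["cadence"].iloc[0]
        idx = to_index(rows_f["timestamp"])
        grouped = pd.Series(rows_f["value"].to_numpy(), index=idx)
        if cadence == WEEKLY:
            vals = grouped.groupby(level=0).mean()
            aggregation[factor] = "lab-point"
        else:
            vals = grouped.groupby(level=0).mean()
            aggregation[factor] = "sensor-mean"
        table[factor] = vals.reindex(table.index)

    factors = [c for c in table.columns if c != "date"]
    if policy == "interpolate":
        # Interpolate short runs of missing weeks on the lattice; the
        # lattice spacing (not the row count) bounds the run length.
        for factor in factors:
            col = table[factor]
            missing = col.isna()
            if not missing.any():
                continue
            filled = col.copy()
            interp = col.interpolate(method="index", limit_area="inside")
            run_start = None
            index = table.index.to_numpy()
            vals = missing.to_numpy()
            for i, is_na in enumerate(np.append(vals, False)):
                if is_na and run_start is None:
                    run_start = i
                elif not is_na and run_start is not None:
                    span = index[i - 1] - index[run_start] + 1 if i > run_start else 0
                    if span <= max_interp_weeks and i < len(index) + 1:
                        sl = table.index[run_start:i]
                        filled.loc[sl] = interp.loc[sl]
                    run_start = None
            table[factor] = filled
    complete = table[factors].notna().all(axis=1)
    table = table.loc[complete]
    if table.empty:
        raise DataError("no complete weekly rows after applying the policy")

    out = table.reset_index()
    out["year"] = out["date"].dt.year
    out["month"] = out["date"].dt.month
    out["day"] = out["date"].dt.day
    ordered = ["date", "year", "month", "day", "week_index"] + factors
    return WeeklyTable(out[ordered].copy(), aggregation, policy)


@dataclass
class WindowedDataset:
    """Flattened sliding-window samples for one factor subset.

    ``x`` rows follow ``layout``: lag-major (oldest week first),
    factor-minor within each lag.  ``y`` columns are ``target_factors``
    at the week ``horizon`` steps after the last input week.
    """

    x: np.ndarray
    y: np.ndarray
    input_factors: tuple[str, ...]
    target_factors: tuple[str, ...]
    layout: tuple[tuple[int, str], ...]
    target_years: np.ndarray
    target_dates: pd.DatetimeIndex
    subset: tuple[str, ...]
    window: int
    horizon: int

    def __len__(self) -> int:
        return len(self.x)

    def in_years(self, years: Iterable[int]) -> "WindowedDataset":
        mask = np.isin(self.target_years, list(years))
        return WindowedDataset(
            self.x[mask], self.y[mask], self.input_factors,
            self.target_factors, self.layout, self.target_years[mask],
            self.target_dates[mask], self.subset, self.window, self.horizon,
        )

    def split_by_period(self, split: SplitSpec) -> dict[str, "WindowedDataset"]:
        return {name: self.in_years(years)
                for name, years in split.periods().items()}


def build_windows(
    table: WeeklyTable,
    subset: Sequence[str],
    window: int = 7,
    horizon: int = 1,
) -> WindowedDataset:
    """Build all valid sliding-window samples for ``subset``.

    Inputs are the date fields + algae + the subset factors over
    ``window`` strictly consecutive weeks; the target holds algae + the
    subset factors one ``horizon`` later.  Samples spanning a lattice
    gap are excluded.  For ``n`` contiguous rows the sample count is
    ``n - window - horizon + 1``.
    """
    subset = tuple(dict.fromkeys(subset))  # dedupe, keep order
    for f in subset:
        if f in DATE_FIELDS or f == "algae":
            raise ConfigError(f"{f!r} is a fixed input, not a subset factor")
        if f not in table.frame.columns:
            raise MissingFactorError(f, "weekly table")
    input_factors = (*DATE_FIELDS, "algae", *subset)
    target_factors = ("algae", *subset)
    n = len(table.frame)
    if n < window + horizon:
        raise DataError(
            f"need at least {window + horizon} weekly rows, have {n}"
        )
    frame = table.frame.reset_index(drop=True)
    wi = frame["week_index"].to_numpy()
    values = frame[list(input_factors)].to_numpy(dtype=float)
    targets = frame[list(target_factors)].to_numpy(dtype=float)

    pos = {int(w): i for i, w in enumerate(wi)}
    xs, ys, t_years, t_dates = [], [], [], []
    for s in range(n):
        base = int(wi[s])
        rows = [pos.get(base + k) for k in range(window)]
        tgt = pos.get(base + window + horizon - 1)
        if any(r is None for r in rows) or tgt is None:
            continue
        xs.append(values[rows].reshape(-1))
        ys.append(targets[tgt])
        # period assignment must survive normalization of the numeric
        # date fields, so read the calendar year off the raw date column
        t_years.append(int(frame["date"].iloc[tgt].year))
        t_dates.append(frame["date"].iloc[tgt])
    if not xs:
        raise DataError("no valid window positions (data too gappy)")
    layout = tuple(
        (lag, f) for lag in range(window) for f in input_factors
    )
    return WindowedDataset(
        np.asarray(xs), np.asarray(ys), input_factors, target_factors,
        layout, np.asarray(t_years), pd.DatetimeIndex(t_dates),
        subset, window, horizon,
    )


@dataclass(frozen=True)
class Normalizer:
    """Per-factor min-max scaling fitted on the training years only."""

    bounds: dict[str, tuple[float, float]]

    def _check(self, factor: str) -> tuple[float, float]:
        if factor not in self.bounds:
            raise MissingFactorError(factor, "normalizer")
        return self.bounds[factor]

    def apply_value(self, values, factor: str):
        lo, hi = self._check(factor)
        return (np.asarray(values, dtype=float) - lo) / (hi - lo)

    def invert_value(self, values, factor: str):
        lo, hi = self._check(factor)
        return np.asarray(values, dtype=float) * (hi - lo) + lo

    def scale(self, factor: str) -> float:
        lo, hi = self._check(factor)
        return hi - lo

    def apply_table(self, table: WeeklyTable) -> WeeklyTable:
        frame = table.frame.copy()
        for factor in self.bounds:
            if factor in frame.columns:
                frame[factor] = self.apply_value(frame[factor], factor)
        return WeeklyTable(frame, dict(table.aggregation), table.policy)

    def to_dict(self) -> dict:
        return {k: list(v) for k, v in self.bounds.items()}

    @classmethod
    def from_dict(cls, raw: dict) -> "Normalizer":
        return cls({k: (float(v[0]), float(v[1])) for k, v in raw.items()})


def fit_normalizer(
    table: WeeklyTable,
    split: SplitSpec,
    factors: Sequence[str] | None = None,
) -> Normalizer:
    """Min-max bounds per factor (and date field) from training years.

    Raises if the training rows are empty or a factor is constant there.
    """
    train = table.rows_in_years(split.training_years)
    if train.empty:
        raise DataError("no weekly rows fall in the training years")
    if factors is None:
        factors = list(DATE_FIELDS) + table.factors
    bounds = {}
    for factor in factors:
        if factor not in train.columns:
            raise MissingFactorError(factor, "weekly table")
        lo = float(train[factor].min())
        hi = float(train[factor].max())
        if not hi > lo:
            raise DataError(
                f"factor {factor!r} is constant over the training years; "
                "cannot min-max normalize"
            )
        bounds[factor] = (lo, hi)
    return Normalizer(bounds)
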