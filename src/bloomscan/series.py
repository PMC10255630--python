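"""Long-format observation tables.

Every data stream in the pipeline — synthetic or real — travels as an
:class:`ObservationSeries`: a tidy table with one row per (timestamp,
factor) pair, carrying the measured value, its unit and a cadence tag
(``"sensor"`` for sub-daily online probes, ``"weekly"`` for lab samples
and derived weekly quantities).  Timestamps are strictly increasing per
factor.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import DataError, MissingFactorError

SENSOR = "sensor"
WEEKLY = "weekly"

COLUMNS = ["timestamp", "factor", "value", "unit", "cadence"]


class ObservationSeries:
    """Tidy (timestamp, factor, value, unit, cadence) measurement table."""

    def __init__(self, data: pd.DataFrame, validate: bool = True):
        missing = [c for c in COLUMNS if c not in data.columns]
        if missing:
            raise DataError(f"observation table lacks columns {missing}")
        data = data.loc[:, COLUMNS].copy()
        data["timestamp"] = pd.to_datetime(data["timestamp"])
        data = data.sort_values(["factor", "timestamp"], kind="stable")
        data = data.reset_index(drop=True)
        if validate:
            # weekly and sensor rows of one factor may legally coincide
            dup = data.duplicated(subset=["factor", "cadence", "timestamp"])
            if dup.any():
                row = data.loc[dup.idxmax()]
                raise DataError(
                    f"duplicate timestamp {row['timestamp']} for factor "
                    f"{row['factor']!r}"
                )
        self.data = data

    # -- construction -------------------------------------------------

    @classmethod
    def from_factors(
        cls,
        frames: Mapping[str, pd.Series],
        units: Mapping[str, str],
        cadences: Mapping[str, str],
    ) -> "ObservationSeries":
        """Build from per-factor time-indexed value series."""
        parts = []
        for name, values in frames.items():
            parts.append(
                pd.DataFrame(
                    {
                        "timestamp": values.index,
                        "factor": name,
                        "value": values.to_numpy(),
                        "unit": units.get(name, ""),
                        "cadence": cadences.get(name, WEEKLY),
                    }
                )
            )
        return cls(pd.concat(parts, ignore_index=True))

    # -- access -------------------------------------------------------

    def factors(self) -> list[str]:
        return sorted(self.data["factor"].unique())

    def has(self, factor: str) -> bool:
        return bool((self.data["factor"] == factor).any())

    def get(self, factor: str) -> pd.Series:
        """Values of one factor as a timestamp-indexed series."""
        rows = self.data[self.data["factor"] == factor]
        if rows.empty:
            raise MissingFactorError(factor, "observation series")
        out = pd.Series(
            rows["value"].to_numpy(), index=pd.DatetimeIndex(rows["timestamp"])
        )
        out.name = factor
        return out

    def unit(self, factor: str) -> str:
        rows = self.data[self.data["factor"] == factor]
        if rows.empty:
            raise MissingFactorError(factor, "observation series")
        return str(rows["unit"].iloc[0])

    def cadence(self, factor: str) -> str:
        rows = self.data[self.data["factor"] == factor]
        if rows.empty:
            raise MissingFactorError(factor, "observation series")
        return str(rows["cadence"].iloc[0])

    def wide(self, factors: Iterable[str] | None = None) -> pd.DataFrame:
        """Pivot selected factors onto a shared timestamp index.

        Only timestamps at which *all* requested factors were observed
        are retained (inner join), which is the alignment the pointwise
        chemistry needs.
        """
        names = list(factors) if factors is not None else self.factors()
        cols = {}
        for name in names:
            cols[name] = self.get(name)
        frame = pd.concat(cols, axis=1, join="inner")
        frame.index.name = "timestamp"
        return frame

    def span(self) -> tuple[pd.Timestamp, pd.Timestamp]:
        ts = self.data["timestamp"]
        return ts.min(), ts.max()

    def __len__(self) -> int:
        return len(self.data)

    # -- set operations ----------------------------------------------

    def subset(self, mask) -> "ObservationSeries":
        return ObservationSeries(self.data.loc[mask], validate=False)

    def merge(self, other: "ObservationSeries") -> "ObservationSeries":
        return ObservationSeries(
            pd.concat([self.data, other.data], ignore_index=True)
        )

    # -- I/O ----------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        out = self.data.copy()
        out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ObservationSeries":
        return cls(pd.read_csv(path))
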