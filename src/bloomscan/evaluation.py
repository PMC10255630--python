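"""Per-factor evaluation reports and chlorophyll risk banding.

The evaluation report mirrors the standard way these forecasting
studies are summarized: one R^2/RMSE cell per (method, factor, period),
with RMSE in the factor's native units, across training / validation /
application periods.  Cells for factors a method does not model are
present but explicitly marked not applicable, never silently missing.

Risk banding converts algal cell counts to a chlorophyll-a equivalent
(linear factor, default 35 ug/L per 4e6 cells/L) and assigns the
recreational-water guidance bands: < 10 ug/L safe, 10-50 ug/L moderate
probability of adverse health effects, >= 50 ug/L high.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .dataset import SplitSpec, WeeklyTable, build_windows
from .errors import ConfigError, DataError
from .fnn import TrainedModel, predict
from .scanning import integrated_score

__all__ = [
    "RiskBand",
    "EvaluationReport",
    "DEFAULT_CELLS_TO_CHL",
    "cells_to_chlorophyll",
    "classify_risk",
    "evaluate",
]

# Midpoint of the observed 30-40 ug/L chlorophyll per 4e6 cells/L band.
DEFAULT_CELLS_TO_CHL = 35.0 / 4.0e6  # ug/L per cell/L

PERIODS = ("training", "validation", "application")

RISK_BOUNDARIES = (10.0, 50.0)  # ug/L chlorophyll-a equivalent


@dataclass(frozen=True)
class RiskBand:
    chlorophyll_eq: float  # ug/L
    band: str  # safe | moderate | high


def cells_to_chlorophyll(
    cells_per_l: float, factor: float = DEFAULT_CELLS_TO_CHL
) -> float:
    """Linear cell-count -> chlorophyll-a equivalent conversion (ug/L)."""
    arr = np.asarray(cells_per_l, dtype=float)
    if np.any(arr < 0):
        raise ConfigError("cell counts must be non-negative")
    out = arr * factor
    return float(out) if np.ndim(cells_per_l) == 0 else out


def classify_risk(chlorophyll_eq: float) -> RiskBand:
    """Band a chlorophyll-a equivalent concentration.

    [0, 10) safe; [10, 50) moderate; [50, inf) high.  The guidance's
    separate "low with cyanobacteria dominance" band needs taxonomic
    composition, which is not an available input, so it is folded into
    the moderate band.
    """
    if chlorophyll_eq < 0:
        raise ConfigError("chlorophyll equivalent must be non-negative")
    low, high = RISK_BOUNDARIES
    if chlorophyll_eq < low:
        band = "safe"
    elif chlorophyll_eq < high:
        band = "moderate"
    else:
        band = "high"
    return RiskBand(float(chlorophyll_eq), band)


@dataclass
class EvaluationReport:
    """R^2 / native-unit RMSE per (method, factor, period)."""

    table: pd.DataFrame  # method, factor, period, r2, rmse, n_samples, applicable
    metadata: dict = field(default_factory=dict)

    def cell(self, method: str, factor: str, period: str) -> pd.Series:
        rows = self.table[
            (self.table["method"] == method)
            & (self.table["factor"] == factor)
            & (self.table["period"] == period)
        ]
        if rows.empty:
            raise DataError(f"no report cell ({method}, {factor}, {period})")
        return rows.iloc[0]

    def render(self, period: str) -> str:
        """Human-readable table for one period."""
        rows = self.table[
            (self.table["period"] == period) & self.table["applicable"]
        ]
        if rows.empty:
            return f"(no applicable cells in the {period} period)"
        wide = rows.pivot(index="method", columns="factor", values=["r2", "rmse"])
        return wide.round(4).to_string()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def evaluate(
    models: Mapping[str, TrainedModel],
    weekly: WeeklyTable,
    split: SplitSpec,
    metadata: dict | None = None,
) -> EvaluationReport:
    """Score every model on every period, de-normalized.

    Each model carries its own normalizer (fitted on the training years
    during the scan); inputs are normalized with it, predictions are
    scored per factor, and RMSE is reported back in native units.
    The application period exercises whatever temporal gap the weekly
    table carries between training and application years.
    """
    if not models:
        raise ConfigError("no models supplied to evaluate")
    all_factors = sorted(
        {f for m in models.values() for f in m.target_factors}
    )
    records = []
    for method, model in models.items():
        if model.normalizer is None:
            raise DataError(
                f"model {method!r} lacks a normalizer; cannot de-normalize"
            )
        missing = [
            f for f in model.condition.subset
            if f not in weekly.frame.columns
        ]
        if missing:
            raise DataError(
                f"model {method!r} needs factors {missing} absent from table"
            )
        norm_table = model.normalizer.apply_table(weekly)
        windows = build_windows(
            norm_table, model.condition.subset,
            window=model.layout[-1][0] + 1, horizon=1,
        )
        periods = windows.split_by_period(split)
        for period in PERIODS:
            sub = periods[period]
            scored = None
            if len(sub) > 0:
                scored = integrated_score(
                    predict(model, sub), sub.y, sub.target_factors,
                    model.normalizer,
                )
            for factor in all_factors:
                applicable = (
                    factor in model.target_factors and scored is not None
                )
                if applicable:
                    cellstats = scored["per_factor"][factor]
                    r2, rmse = cellstats["r2"], cellstats["rmse"]
                else:
                    r2, rmse = np.nan, np.nan
                records.append(
                    {
                        "method": method,
                        "factor": factor,
                        "period": period,
                        "r2": r2,
                        "rmse": rmse,
                        "n_samples": len(sub),
                        "applicable": applicable,
                    }
                )
    table = pd.DataFrame.from_records(records)
    meta = {
        "methods": list(models),
        "splits": {k: list(v) for k, v in split.periods().items()},
    }
    if metadata:
        meta.update(metadata)
    return EvaluationReport(table, meta)
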