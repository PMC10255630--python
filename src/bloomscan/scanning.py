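"""Exhaustive scanning-focusing model selection.

The selection idea: train the same small forecasting network on every
non-empty subset of the candidate factors (63 subsets for 6 candidates),
at every hidden-layer width in a range (default 1-10, hence 630
conditions), with several seeded replicates per condition (default 10)
to average out initialization luck.  Subsets are then ranked by mean
validation performance, and a subset qualifies as a *closed system* when
every member factor's removal costs measurable performance while no
outside factor's addition buys any — a Granger-style retention rule
applied to whole subsets using the scan's own neighbouring results.

Two baselines fall out of the same grid: the empty subset (date + target
only, the "simple process" SP) and the full subset (everything, the
"blind process" BP).
"""

from __future__ import annotations

import hashlib
import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .dataset import (
    DATE_FIELDS,
    Normalizer,
    SplitSpec,
    WeeklyTable,
    build_windows,
    fit_normalizer,
)
from .errors import ConfigError, DataError, TrainingDivergedError
from .fnn import ModelCondition, TrainConfig, TrainedModel, predict, train

__all__ = [
    "DEFAULT_CANDIDATES",
    "ScanGrid",
    "ScanResult",
    "ClosedSystem",
    "enumerate_subsets",
    "condition_seed",
    "run_scan",
    "integrated_score",
    "select_closed_systems",
    "best_neurons_per_subset",
    "train_selected",
]

DEFAULT_CANDIDATES = (
    "temperature", "ph", "conductivity", "turbidity", "dom_uv254", "co2",
)

SP_KEY = "SP"  # ledger key of the empty (date + algae only) baseline


def subset_key(subset: Sequence[str]) -> str:
    return "+".join(subset) if subset else SP_KEY


def enumerate_subsets(candidates: Sequence[str]) -> list[tuple[str, ...]]:
    """All non-empty subsets, ordered by size then lexicographically.

    Factor order inside each subset follows the candidate order, which
    fixes the window layout for every downstream training.
    """
    candidates = tuple(candidates)
    if len(set(candidates)) != len(candidates):
        raise ConfigError(f"duplicate candidate names in {candidates}")
    if not 1 <= len(candidates) <= 12:
        raise ConfigError("need between 1 and 12 candidate factors")
    subsets = []
    for size in range(1, len(candidates) + 1):
        combos = sorted(itertools.combinations(candidates, size))
        subsets.extend(combos)
    return subsets


def condition_seed(
    base_seed: int, subset: Sequence[str], n_hidden: int, replicate: int
) -> int:
    """Stable per-condition seed: hash of (base seed, subset, width, rep)."""
    text = f"{base_seed}|{subset_key(subset)}|{n_hidden}|{replicate}"
    digest = hashlib.sha256(text.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class ScanGrid:
    """The full condition grid of the scanning stage."""

    candidates: tuple[str, ...] = DEFAULT_CANDIDATES
    neuron_range: tuple[int, ...] = tuple(range(1, 11))
    replicates: int = 10
    base_seed: int = 0

    @property
    def subsets(self) -> list[tuple[str, ...]]:
        return enumerate_subsets(self.candidates)

    @property
    def n_subsets(self) -> int:
        return 2 ** len(self.candidates) - 1

    @property
    def n_conditions(self) -> int:
        return self.n_subsets * len(self.neuron_range)


def integrated_score(
    predictions: np.ndarray,
    targets: np.ndarray,
    factors: Sequence[str],
    normalizer: Normalizer | None = None,
) -> dict:
    """Per-factor and pooled goodness of fit on normalized outputs.

    Per-factor R^2 is 1 - SSE/SST; per-factor RMSE is reported on the
    de-normalized (native-unit) scale when a normalizer is supplied.
    The integrated R^2/MSE pool the (prediction, target) pairs of all
    factors: integrated R^2 = 1 - sum_f SSE_f / sum_f SST_f, so a factor
    the model cannot predict at all drags the whole subset down.
    Zero-variance target factors are flagged and left out of the pool.
    """
    predictions = np.asarray(predictions, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if predictions.shape != targets.shape:
        raise DataError(
            f"shape mismatch: predictions {predictions.shape} vs "
            f"targets {targets.shape}"
        )
    if predictions.shape[1] != len(factors):
        raise DataError("factor list length does not match output width")
    per_factor: dict[str, dict] = {}
    sse_pool = 0.0
    sst_pool = 0.0
    n_pool = 0
    degenerate: list[str] = []
    for j, factor in enumerate(factors):
        p, t = predictions[:, j], targets[:, j]
        sse = float(np.sum((p - t) ** 2))
        sst = float(np.sum((t - t.mean()) ** 2))
        rmse_norm = float(np.sqrt(sse / len(t)))
        rmse = rmse_norm * (normalizer.scale(factor) if normalizer else 1.0)
        if sst == 0.0:
            degenerate.append(factor)
            per_factor[factor] = {"r2": float("nan"), "rmse": rmse}
            continue
        per_factor[factor] = {"r2": 1.0 - sse / sst, "rmse": rmse}
        sse_pool += sse
        sst_pool += sst
        n_pool += len(t)
    if degenerate:
        warnings.warn(
            f"zero-variance target factor(s) {degenerate} excluded from "
            "the integrated pool",
            stacklevel=2,
        )
    if sst_pool == 0.0:
        raise DataError("every target factor has zero variance")
    return {
        "integrated_r2": 1.0 - sse_pool / sst_pool,
        "integrated_mse": sse_pool / n_pool,
        "per_factor": per_factor,
        "degenerate_factors": degenerate,
    }


LEDGER_COLUMNS = [
    "subset", "subset_size", "n_hidden", "replicate", "seed",
    "train_r2", "train_mse", "val_r2", "val_mse", "per_factor_val",
    "diverged",
]


@dataclass
class ScanResult:
    """The run ledger (one row per training) plus grid metadata."""

    ledger: pd.DataFrame
    grid: ScanGrid
    split: SplitSpec
    window: int = 7
    horizon: int = 1
    include_sp: bool = True

    def summary(self) -> pd.DataFrame:
        """Mean/sd over replicates per (subset, n_hidden) condition."""
        ok = self.ledger[~self.ledger["diverged"]]
        agg = ok.groupby(["subset", "n_hidden"]).agg(
            val_r2_mean=("val_r2", "mean"),
            val_r2_sd=("val_r2", "std"),
            val_mse_mean=("val_mse", "mean"),
            train_r2_mean=("train_r2", "mean"),
            train_mse_mean=("train_mse", "mean"),
            n_replicates=("replicate", "count"),
        )
        return agg.reset_index()

    def best_replicate(self, subset: Sequence[str], n_hidden: int) -> pd.Series:
        key = subset_key(subset)
        rows = self.ledger[
            (self.ledger["subset"] == key)
            & (self.ledger["n_hidden"] == n_hidden)
            & (~self.ledger["diverged"])
        ]
        if rows.empty:
            raise DataError(f"no completed replicates for {key} @ {n_hidden}")
        return rows.loc[rows["val_r2"].idxmax()]

    def to_csv(self, path: str | Path) -> None:
        self.ledger.to_csv(path, index=False)


def _evaluate_condition(
    model: TrainedModel,
    periods: dict,
    normalizer: Normalizer,
) -> dict:
    out = {}
    for name in ("training", "validation"):
        windows = periods[name]
        score = integrated_score(
            predict(model, windows), windows.y, windows.target_factors,
            normalizer,
        )
        out[name] = score
    return out


def run_scan(
    grid: ScanGrid,
    weekly: WeeklyTable,
    split: SplitSpec,
    hyper: TrainConfig | None = None,
    window: int = 7,
    horizon: int = 1,
    include_sp: bool = True,
    ledger_path: str | Path | None = None,
    progress: Callable[[str], None] | None = None,
) -> ScanResult:
    """Train every (subset, width, replicate) condition and ledger it.

    Diverged trainings are recorded (flagged, NaN metrics) and never
    abort the scan.  When ``ledger_path`` is given the ledger is flushed
    after every subset and a re-run resumes from the completed rows;
    because condition seeds are content-derived the resumed result is
    identical to an uninterrupted run.
    """
    hyper = hyper or TrainConfig()
    for factor in grid.candidates:
        if factor not in weekly.frame.columns:
            raise DataError(f"candidate factor {factor!r} not in weekly table")
    normalizer = fit_normalizer(
        weekly, split, list(DATE_FIELDS) + ["algae"] + list(grid.candidates)
    )
    norm_table = normalizer.apply_table(weekly)

    done: set[tuple[str, int, int]] = set()
    rows: list[dict] = []
    if ledger_path is not None and Path(ledger_path).exists():
        previous = pd.read_csv(ledger_path)
        rows = previous.to_dict("records")
        done = {
            (r["subset"], int(r["n_hidden"]), int(r["replicate"]))
            for r in rows
        }

    subsets: list[tuple[str, ...]] = list(grid.subsets)
    if include_sp:
        subsets = [()] + subsets

    for subset in subsets:
        key = subset_key(subset)
        pending = [
            (n, rep)
            for n in grid.neuron_range
            for rep in range(grid.replicates)
            if (key, n, rep) not in done
        ]
        if not pending:
            continue
        windows = build_windows(norm_table, subset, window, horizon)
        periods = windows.split_by_period(split)
        train_w = periods["training"]
        for n_hidden, rep in pending:
            seed = condition_seed(grid.base_seed, subset, n_hidden, rep)
            condition = ModelCondition(subset, n_hidden, seed)
            row = {
                "subset": key,
                "subset_size": len(subset),
                "n_hidden": n_hidden,
                "replicate": rep,
                "seed": seed,
                "train_r2": np.nan,
                "train_mse": np.nan,
                "val_r2": np.nan,
                "val_mse": np.nan,
                "per_factor_val": "",
                "diverged": False,
            }
            try:
                model = train(condition, train_w, hyper)
                scores = _evaluate_condition(model, periods, normalizer)
                row.update(
                    train_r2=scores["training"]["integrated_r2"],
                    train_mse=scores["training"]["integrated_mse"],
                    val_r2=scores["validation"]["integrated_r2"],
                    val_mse=scores["validation"]["integrated_mse"],
                    per_factor_val=json.dumps(
                        scores["validation"]["per_factor"]
                    ),
                )
            except TrainingDivergedError:
                row["diverged"] = True
            rows.append(row)
        if progress is not None:
            progress(f"scanned subset {key} ({len(pending)} trainings)")
        if ledger_path is not None:
            pd.DataFrame(rows, columns=LEDGER_COLUMNS).to_csv(
                ledger_path, index=False
            )

    ledger = pd.DataFrame(rows, columns=LEDGER_COLUMNS)
    ledger = ledger.sort_values(
        ["subset_size", "subset", "n_hidden", "replicate"], kind="stable"
    ).reset_index(drop=True)
    return ScanResult(ledger, grid, split, window, horizon, include_sp)


def best_neurons_per_subset(result: ScanResult) -> pd.DataFrame:
    """Best hidden width per subset by mean validation integrated R^2.

    Ties break toward the smallest width.  The output-factor count is
    reported alongside so the empirical width ~ outputs pattern can be
    inspected without being assumed.
    """
    summary = result.summary()
    records = []
    for key, rows in summary.groupby("subset"):
        rows = rows.sort_values("n_hidden")
        best = rows.loc[rows["val_r2_mean"].idxmax()]  # idxmax -> first max
        size = 0 if key == SP_KEY else key.count("+") + 1
        records.append(
            {
                "subset": key,
                "best_n_hidden": int(best["n_hidden"]),
                "val_r2_mean": float(best["val_r2_mean"]),
                "val_r2_sd": float(best["val_r2_sd"]),
                "n_outputs": size + 1,  # subset factors + algae
            }
        )
    out = pd.DataFrame.from_records(records)
    return out.sort_values("val_r2_mean", ascending=False).reset_index(drop=True)


@dataclass
class ClosedSystem:
    """A selected subset with its Granger-style selection evidence."""

    subset: tuple[str, ...]
    n_hidden: int
    mean_val_r2: float
    member_drops: dict[str, float]  # score(S) - score(S \ {f}); want > tol
    nonmember_gains: dict[str, float]  # score(S + {f}) - score(S); want <= tol
    passes: bool
    best_replicate_seed: int
    best_replicate_val_r2: float
    rank: int

    def to_dict(self) -> dict:
        return {
            "subset": list(self.subset),
            "n_hidden": self.n_hidden,
            "mean_val_r2": self.mean_val_r2,
            "member_drops": self.member_drops,
            "nonmember_gains": self.nonmember_gains,
            "passes": self.passes,
            "best_replicate_seed": self.best_replicate_seed,
            "best_replicate_val_r2": self.best_replicate_val_r2,
            "rank": self.rank,
        }


def _subset_scores(result: ScanResult) -> tuple[dict, dict]:
    """(mean val R^2, best width) per subset at its best width."""
    best = best_neurons_per_subset(result)
    scores = {row["subset"]: row["val_r2_mean"] for _, row in best.iterrows()}
    widths = {row["subset"]: int(row["best_n_hidden"]) for _, row in best.iterrows()}
    return scores, widths


def select_closed_systems(
    result: ScanResult,
    top_k: int = 2,
    tolerance: float = 0.01,
) -> list[ClosedSystem]:
    """Rank subsets and verify the closed-system property on each.

    A subset passes when every member's removal costs more than
    ``tolerance`` of mean validation integrated R^2 and no non-member's
    addition gains more than ``tolerance`` — both measured from the
    scan's own results for the neighbouring subsets.  If no subset
    passes, the top ``top_k`` by rank are returned with their property
    flags set false rather than hidden.
    """
    scores, widths = _subset_scores(result)
    candidates = result.grid.candidates
    # An unbounded tolerance disables the property check entirely:
    # selection degenerates to the pure R^2 ranking.
    check_property = np.isfinite(tolerance)
    ranked = []
    for subset in result.grid.subsets:
        key = subset_key(subset)
        if key not in scores:
            continue
        ranked.append((subset, scores[key]))
    # Rank by score descending; ties toward smaller subsets, then name.
    ranked.sort(key=lambda it: (-it[1], len(it[0]), it[0]))

    systems: list[ClosedSystem] = []
    for rank, (subset, score) in enumerate(ranked, start=1):
        member_drops = {}
        ok = True
        for f in subset:
            reduced = tuple(c for c in subset if c != f)
            ref = scores.get(subset_key(reduced))
            drop = score - ref if ref is not None else float("nan")
            member_drops[f] = drop
            if check_property and not (drop > tolerance):
                ok = False
        nonmember_gains = {}
        for f in candidates:
            if f in subset:
                continue
            grown = tuple(c for c in candidates if c in subset or c == f)
            ref = scores.get(subset_key(grown))
            gain = ref - score if ref is not None else float("nan")
            nonmember_gains[f] = gain
            if check_property and not (gain <= tolerance):
                ok = False
        width = widths[subset_key(subset)]
        best = result.best_replicate(subset, width)
        systems.append(
            ClosedSystem(
                subset=subset,
                n_hidden=width,
                mean_val_r2=float(score),
                member_drops=member_drops,
                nonmember_gains=nonmember_gains,
                passes=ok,
                best_replicate_seed=int(best["seed"]),
                best_replicate_val_r2=float(best["val_r2"]),
                rank=rank,
            )
        )
    passing = [s for s in systems if s.passes]
    chosen = passing[:top_k] if passing else systems[:top_k]
    return chosen


def materialize_subset(
    result: ScanResult,
    weekly: WeeklyTable,
    subset: Sequence[str],
    hyper: TrainConfig | None = None,
) -> TrainedModel:
    """Re-train the best (width, replicate) of one subset from the ledger.

    Works for any scanned subset including the SP (empty) and BP (full)
    baselines.  Training is deterministic in the stored replicate seed,
    so the returned weights equal the ones scored during the scan.
    """
    subset = tuple(subset)
    summary = result.summary()
    key = subset_key(subset)
    rows = summary[summary["subset"] == key].sort_values("n_hidden")
    if rows.empty:
        raise DataError(f"subset {key} was not scanned")
    width = int(rows.loc[rows["val_r2_mean"].idxmax(), "n_hidden"])
    best = result.best_replicate(subset, width)
    normalizer = fit_normalizer(
        weekly, result.split,
        list(DATE_FIELDS) + ["algae"] + list(result.grid.candidates),
    )
    windows = build_windows(
        normalizer.apply_table(weekly), subset, result.window, result.horizon
    )
    train_w = windows.in_years(result.split.training_years)
    condition = ModelCondition(subset, width, int(best["seed"]))
    return train(condition, train_w, hyper, normalizer=normalizer)


def train_selected(
    system: ClosedSystem,
    result: ScanResult,
    weekly: WeeklyTable,
    hyper: TrainConfig | None = None,
) -> TrainedModel:
    """Re-materialize the best replicate model of a selected system."""
    normalizer = fit_normalizer(
        weekly, result.split,
        list(DATE_FIELDS) + ["algae"] + list(result.grid.candidates),
    )
    windows = build_windows(
        normalizer.apply_table(weekly), system.subset,
        result.window, result.horizon,
    )
    train_w = windows.in_years(result.split.training_years)
    condition = ModelCondition(
        system.subset, system.n_hidden, system.best_replicate_seed
    )
    return train(condition, train_w, hyper, normalizer=normalizer)
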