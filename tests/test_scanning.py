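"""Subset enumeration, integrated metrics, scan ledger, selection."""

import dataclasses
import itertools

import numpy as np
import pandas as pd
import pytest

from bloomscan.dataset import SplitSpec, to_weekly
from bloomscan.errors import ConfigError, DataError
from bloomscan.fnn import TrainConfig
from bloomscan.scanning import (
    ScanGrid,
    ScanResult,
    best_neurons_per_subset,
    condition_seed,
    enumerate_subsets,
    integrated_score,
    materialize_subset,
    run_scan,
    select_closed_systems,
    subset_key,
)
from bloomscan.synthetic import ScenarioConfig, generate_scenario

# -- enumeration ------------------------------------------------------


def test_subset_counts():
    assert len(enumerate_subsets(["a"])) == 1
    assert len(enumerate_subsets(list("abc"))) == 7
    assert len(enumerate_subsets(list("abcdef"))) == 63


def test_enumeration_matches_bitmask_bruteforce():
    names = ["x", "y", "z"]
    expected = set()
    for mask in range(1, 8):
        expected.add(tuple(n for i, n in enumerate(names) if mask >> i & 1))
    assert set(enumerate_subsets(names)) == expected


def test_enumeration_order_is_size_then_lexicographic():
    subsets = enumerate_subsets(["b", "a"])
    sizes = [len(s) for s in subsets]
    assert sizes == sorted(sizes)
    singles = [s for s in subsets if len(s) == 1]
    assert singles == sorted(singles)


def test_duplicate_candidates_rejected():
    with pytest.raises(ConfigError):
        enumerate_subsets(["a", "a"])


def test_grid_combinatorics():
    grid = ScanGrid()
    assert grid.n_subsets == 63
    assert grid.n_conditions == 630


def test_condition_seed_properties():
    seeds = {
        condition_seed(0, ("temperature",), n, rep)
        for n in range(1, 11)
        for rep in range(10)
    }
    assert len(seeds) == 100  # no collisions across the condition block
    assert all(0 <= s < 2**31 for s in seeds)
    assert condition_seed(1, ("ph",), 3, 2) == condition_seed(1, ("ph",), 3, 2)


# -- integrated metrics ----------------------------------------------


def test_perfect_predictions_score_one():
    y = np.array([[0.1, 0.5], [0.2, 0.6], [0.4, 0.9]])
    score = integrated_score(y.copy(), y, ["a", "b"])
    assert score["integrated_r2"] == pytest.approx(1.0)
    assert score["integrated_mse"] == pytest.approx(0.0)


def test_mean_predictions_score_zero():
    rng = np.random.default_rng(0)
    y = rng.uniform(size=(20, 2))
    preds = np.tile(y.mean(axis=0), (20, 1))
    score = integrated_score(preds, y, ["a", "b"])
    for f in ("a", "b"):
        assert score["per_factor"][f]["r2"] == pytest.approx(0.0)
    assert score["integrated_r2"] == pytest.approx(0.0)


def test_hand_computed_two_factor_oracle():
    """Four samples, two factors, checked against a by-hand evaluation."""
    targets = np.array([[1.0, 10.0], [2.0, 10.0], [3.0, 14.0], [4.0, 10.0]])
    preds = np.array([[1.5, 11.0], [2.0, 9.0], [2.5, 13.0], [3.0, 11.0]])
    # factor a: SSE = .25+0+.25+1 = 1.5, mean 2.5, SST = 2.25+.25+.25+2.25 = 5
    # factor b: SSE = 1+1+1+1 = 4, mean 11, SST = 1+1+9+1 = 12
    score = integrated_score(preds, targets, ["a", "b"])
    assert score["per_factor"]["a"]["r2"] == pytest.approx(1 - 1.5 / 5)
    assert score["per_factor"]["b"]["r2"] == pytest.approx(1 - 4 / 12)
    assert score["integrated_r2"] == pytest.approx(1 - 5.5 / 17)
    assert score["integrated_mse"] == pytest.approx(5.5 / 8)
    assert score["per_factor"]["a"]["rmse"] == pytest.approx(np.sqrt(1.5 / 4))


def test_zero_variance_factor_flagged_and_excluded():
    targets = np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
    preds = targets + 0.1
    with pytest.warns(UserWarning, match="zero-variance"):
        score = integrated_score(preds, targets, ["a", "flat"])
    assert score["degenerate_factors"] == ["flat"]
    assert np.isnan(score["per_factor"]["flat"]["r2"])
    assert np.isfinite(score["integrated_r2"])


# -- the scan ---------------------------------------------------------

SMALL_SPLIT = SplitSpec((2015, 2016), (2017,), (2022,))


@pytest.fixture(scope="module")
def small_scan():
    config = ScenarioConfig(
        seed=21, start_year=2015, end_year=2017, include_sensor_channels=False
    )
    weekly = to_weekly(generate_scenario(config))
    grid = ScanGrid(
        candidates=("temperature", "ph"), neuron_range=(1, 2),
        replicates=2, base_seed=5,
    )
    hyper = TrainConfig(max_iter=120)
    result = run_scan(grid, weekly, SMALL_SPLIT, hyper=hyper)
    return grid, weekly, hyper, result


def test_ledger_coverage(small_scan):
    """Exactly (subsets + SP) x widths x replicates rows, none missing,
    none duplicated."""
    grid, _, _, result = small_scan
    expected = (grid.n_subsets + 1) * len(grid.neuron_range) * grid.replicates
    assert len(result.ledger) == expected
    keys = result.ledger[["subset", "n_hidden", "replicate"]]
    assert not keys.duplicated().any()
    assert not result.ledger["diverged"].any()
    assert result.ledger["val_r2"].notna().all()


def test_scan_determinism(small_scan):
    grid, weekly, hyper, result = small_scan
    again = run_scan(grid, weekly, SMALL_SPLIT, hyper=hyper)
    pd.testing.assert_frame_equal(result.ledger, again.ledger)


def test_scan_resume_from_partial_ledger(small_scan, tmp_path):
    """A scan resumed from a truncated ledger reproduces the full one."""
    grid, weekly, hyper, result = small_scan
    path = tmp_path / "ledger.csv"
    partial = result.ledger[result.ledger["subset"] != "temperature+ph"]
    partial.to_csv(path, index=False)
    resumed = run_scan(
        grid, weekly, SMALL_SPLIT, hyper=hyper, ledger_path=path
    )
    a = result.ledger.sort_values(
        ["subset", "n_hidden", "replicate"]
    ).reset_index(drop=True)
    b = resumed.ledger.sort_values(
        ["subset", "n_hidden", "replicate"]
    ).reset_index(drop=True)
    pd.testing.assert_frame_equal(a, b, check_exact=False, rtol=1e-12)


def test_materialized_model_reproduces_ledger_score(small_scan):
    """Re-training the best replicate from its stored seed gives back a
    model whose validation score matches the ledger entry."""
    from bloomscan.dataset import build_windows
    from bloomscan.fnn import predict

    grid, weekly, hyper, result = small_scan
    model = materialize_subset(result, weekly, ("temperature",), hyper)
    best_width = model.condition.n_hidden
    row = result.best_replicate(("temperature",), best_width)
    windows = build_windows(
        model.normalizer.apply_table(weekly), ("temperature",)
    )
    val = windows.in_years(SMALL_SPLIT.validation_years)
    score = integrated_score(
        predict(model, val), val.y, val.target_factors, model.normalizer
    )
    assert score["integrated_r2"] == pytest.approx(row["val_r2"], abs=1e-9)


# -- selection on hand-built ledgers ---------------------------------


def fake_result(scores: dict[str, float], candidates=("a", "b", "c")) -> ScanResult:
    """ScanResult whose mean validation R^2 per subset is prescribed."""
    rows = []
    for key, r2 in scores.items():
        rows.append(
            {
                "subset": key,
                "subset_size": 0 if key == "SP" else key.count("+") + 1,
                "n_hidden": 1,
                "replicate": 0,
                "seed": 1,
                "train_r2": r2,
                "train_mse": 0.1,
                "val_r2": r2,
                "val_mse": 0.1,
                "per_factor_val": "",
                "diverged": False,
            }
        )
    grid = ScanGrid(candidates=candidates, neuron_range=(1,), replicates=1)
    return ScanResult(pd.DataFrame(rows), grid, SMALL_SPLIT)


def all_keys(candidates):
    return [subset_key(s) for s in enumerate_subsets(candidates)]


def test_planted_selection_on_prescribed_scores():
    """{a} members help, non-members don't: it passes; its supersets
    fail the non-gain condition or the member condition."""
    scores = {"SP": 0.30}
    for key in all_keys(("a", "b", "c")):
        has_a = "a" in key.split("+")
        scores[key] = 0.80 if has_a else 0.31
        if has_a and key != "a":
            scores[key] = 0.79  # adding b/c to {a} buys nothing
    result = fake_result(scores)
    systems = select_closed_systems(result, top_k=3, tolerance=0.01)
    assert systems[0].subset == ("a",)
    assert systems[0].passes
    assert systems[0].member_drops["a"] == pytest.approx(0.5)


def test_subset_dominated_by_supersets_fails():
    """A subset whose every superset scores higher cannot be closed."""
    scores = {"SP": 0.2, "a": 0.5, "b": 0.3, "c": 0.3,
              "a+b": 0.6, "a+c": 0.6, "b+c": 0.35, "a+b+c": 0.7}
    result = fake_result(scores)
    systems = select_closed_systems(result, top_k=8, tolerance=0.01)
    by_subset = {s.subset: s for s in systems}
    if ("a",) in by_subset:
        assert not by_subset[("a",)].passes


def test_infinite_tolerance_reduces_to_pure_ranking():
    scores = {"SP": 0.2, "a": 0.5, "b": 0.9, "c": 0.3,
              "a+b": 0.6, "a+c": 0.6, "b+c": 0.35, "a+b+c": 0.7}
    result = fake_result(scores)
    systems = select_closed_systems(result, top_k=7, tolerance=float("inf"))
    assert all(s.passes for s in systems)
    ordered = [s.subset for s in systems]
    assert ordered[0] == ("b",)
    assert ordered[1] == ("a", "b", "c")


def test_no_passing_subset_reported_not_hidden():
    """When nothing passes, top-ranked subsets come back flagged."""
    # flat landscape: no member's removal ever costs anything
    scores = {"SP": 0.5}
    for key in all_keys(("a", "b", "c")):
        scores[key] = 0.5
    result = fake_result(scores)
    systems = select_closed_systems(result, top_k=2, tolerance=0.01)
    assert len(systems) == 2
    assert not any(s.passes for s in systems)


def test_best_neuron_tie_breaks_small():
    rows = []
    for n in (1, 2, 3):
        rows.append(
            {
                "subset": "a", "subset_size": 1, "n_hidden": n,
                "replicate": 0, "seed": 1, "train_r2": 0.5,
                "train_mse": 0.1, "val_r2": 0.7, "val_mse": 0.1,
                "per_factor_val": "", "diverged": False,
            }
        )
    grid = ScanGrid(candidates=("a",), neuron_range=(1, 2, 3), replicates=1)
    result = ScanResult(pd.DataFrame(rows), grid, SMALL_SPLIT)
    best = best_neurons_per_subset(result)
    assert best["best_n_hidden"].iloc[0] == 1


def test_best_neurons_covers_all_subsets(small_scan):
    _, _, _, result = small_scan
    best = best_neurons_per_subset(result)
    # 3 subsets of 2 candidates + the SP baseline
    assert set(best["subset"]) == {"temperature", "ph", "temperature+ph", "SP"}
    assert (best["n_outputs"] >= 1).all()
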