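"""The scanning-focusing core on a small grid.

Scans every subset of three candidate factors (one of them a pure-noise
decoy) at hidden widths 1-3 with 2 replicates each, ranks subsets by
mean validation integrated R^2, and applies the Granger-style
closed-system test: members must earn their keep, outsiders must add
nothing.
"""

import time

from bloomscan import (
    ScanGrid,
    ScenarioConfig,
    SplitSpec,
    TrainConfig,
    best_neurons_per_subset,
    generate_scenario,
    run_scan,
    select_closed_systems,
    to_weekly,
)

weekly = to_weekly(
    generate_scenario(ScenarioConfig(seed=7, include_sensor_channels=False))
)
split = SplitSpec()
grid = ScanGrid(
    candidates=("temperature", "ph", "decoy_1"),
    neuron_range=(1, 2, 3),
    replicates=2,
    base_seed=42,
)

t0 = time.time()
result = run_scan(grid, weekly, split, hyper=TrainConfig(max_iter=150))
print(
    f"{grid.n_subsets} subsets x {len(grid.neuron_range)} widths x "
    f"{grid.replicates} replicates (+ SP baseline) -> "
    f"{len(result.ledger)} trainings in {time.time() - t0:.1f} s\n"
)

ranking = best_neurons_per_subset(result)
print("subsets ranked by mean validation integrated R^2:")
print(ranking.to_string(index=False))

systems = select_closed_systems(result, top_k=2, tolerance=0.01)
print("\nselected closed systems:")
for s in systems:
    print(
        f"  rank {s.rank}: {{{', '.join(s.subset)}}} width {s.n_hidden}, "
        f"val R^2 {s.mean_val_r2:.3f}, property "
        f"{'passes' if s.passes else 'FAILS'}"
    )
    for f, d in s.member_drops.items():
        print(f"    removing {f:<12} costs {d:+.3f}")
    for f, g in s.nonmember_gains.items():
        print(f"    adding   {f:<12} gains {g:+.3f}")
print(
    "\nThe decoy never survives selection: adding it to any subset buys"
    " less than the 0.01 tolerance while diluting the integrated score."
)
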