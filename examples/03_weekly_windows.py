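"""From raw observations to normalized sliding-window samples.

Resamples a mixed-cadence series onto the weekly grid, fits min-max
normalization on the training years only, and builds 7-week input /
1-week-ahead output samples for the {temperature, ph} factor subset.
"""

from bloomscan import (
    ScenarioConfig,
    SplitSpec,
    build_windows,
    fit_normalizer,
    generate_scenario,
    to_weekly,
)

series = generate_scenario(ScenarioConfig(seed=7, include_sensor_channels=False))
weekly = to_weekly(series)
print(f"weekly table: {len(weekly)} rows, factors {weekly.factors}")

split = SplitSpec()  # 2015-2019 train / 2020 validation / 2022 application
norm = fit_normalizer(weekly, split)
print(
    "normalization bounds come from the training years only, e.g. algae:"
    f" {norm.bounds['algae'][0]:.3g} .. {norm.bounds['algae'][1]:.3g} cells/L"
)

windows = build_windows(norm.apply_table(weekly), ("temperature", "ph"))
periods = windows.split_by_period(split)
print(f"\n{len(windows)} window samples, input width {windows.x.shape[1]}")
print(f"input factors per lag: {windows.input_factors}")
print(f"targets one week ahead: {windows.target_factors}")
for name, sub in periods.items():
    print(f"  {name:<12} {len(sub):>4} samples")
print(
    "\nEach sample flattens 7 consecutive weeks (lag-major) of date"
    " fields + algae + the subset; values outside the training range"
    " normalize beyond [0, 1] and are deliberately not clipped."
)
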