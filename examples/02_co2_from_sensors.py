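"""Upgrade weekly lab alkalinity to sensor-cadence dissolved CO2.

Fits the alkalinity-conductivity line on weekly lab values paired with
the nearest conductivity reading (6-hour rule), then solves the
carbonate system at every sensor timestamp and compares the recovered
CO2 with the values the generator planted.
"""

import dataclasses

import numpy as np

from bloomscan import (
    ScenarioConfig,
    co2_series,
    fit_alkalinity_conductivity,
    generate_scenario,
)

config = dataclasses.replace(
    ScenarioConfig(seed=4),
    start_year=2016, end_year=2016,
    include_sensor_channels=True, sensor_interval_minutes=60,
)
series = generate_scenario(config)

fit = fit_alkalinity_conductivity(
    series.get("alkalinity"), series.get("conductivity"), max_gap_hours=6.0
)
print(
    f"alkalinity = {fit.slope:.4f} * conductivity + {fit.intercept:.3f} mM"
    f"  (n = {fit.n_pairs} pairs, residual sd {fit.residual_sd:.4f} mM;"
    f" generator used slope {config.alk_cond_params.slope},"
    f" intercept {config.alk_cond_params.intercept})"
)

sensors = series.subset(series.data["cadence"] == "sensor")
result = co2_series(sensors.subset(sensors.data["factor"] != "co2"), fit)
recovered = result.series.get("co2")
planted = sensors.get("co2")
rel = np.abs(recovered.to_numpy() - planted.to_numpy()) / planted.to_numpy()
print(
    f"{len(recovered)} hourly CO2 values computed, "
    f"{result.n_infeasible} chemically infeasible points excluded"
)
print(
    f"median |relative error| vs planted CO2: {np.median(rel):.3%} "
    "(dominated by conductivity sensor noise propagating through the fit)"
)
print(
    f"CO2 range {recovered.min():.2e} .. {recovered.max():.2e} mol/L; the"
    " summer minimum marks photosynthetic drawdown during the bloom."
)
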