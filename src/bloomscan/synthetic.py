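"""Synthetic lake sensor / lab scenario generator.

The restricted nature of raw-water utility data means the pipeline must
be exercisable end to end without any download.  This module produces
multi-year observation series with the statistical structure the
analysis assumes:

* seasonal water temperature (sinusoid + AR(1) noise, clipped at 0 degC),
* summer algal blooms as Gaussian pulses in log cell space whose
  amplitude is gated on 3-week-lagged temperature exceeding a threshold
  and whose timing shifts with warm/cold springs — a genuinely lagged
  temperature -> algae dependency a 7-week input window can exploit,
* slow AR(1) alkalinity with conductivity linearly coupled to it,
* dissolved CO2 drawn down from a baseline in proportion to normalized
  algal biomass (photosynthetic uptake),
* pH solved from the carbonate equilibrium given (alkalinity, CO2,
  temperature) — so pH <-> CO2 <-> algae are mutually informative and
  {temperature, pH} / {temperature, CO2} are the recoverable "closed
  systems",
* decoy channels of pure AR(1) noise with no causal link to algae, which
  a correct scanner must reject.

Weekly lab quantities (algae counts, alkalinity) are point samples at a
fixed weekly clock time; sensor channels are emitted on a sub-daily grid
(default 5 min) by interpolating the weekly latent curves and adding
instrument noise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .carbonate import ph_from_alk_co2_vec
from .errors import ConfigError, DataError
from .series import SENSOR, WEEKLY, ObservationSeries

__all__ = [
    "TempParams",
    "BloomParams",
    "AlkCondParams",
    "ScenarioConfig",
    "generate_scenario",
    "inject_gap",
    "noise_free",
    "save_config",
    "load_config",
]

SENSOR_FACTORS = ("temperature", "ph", "conductivity", "turbidity", "dom_uv254", "co2")

UNITS = {
    "algae": "cells/L",
    "alkalinity": "mM",
    "temperature": "degC",
    "ph": "",
    "conductivity": "mS/m",
    "turbidity": "FTU",
    "dom_uv254": "1/m",
    "co2": "mol/L",
}


@dataclass(frozen=True)
class TempParams:
    """Seasonal water-temperature model (degC)."""

    mean: float = 6.0
    amplitude: float = 5.5
    noise_sd: float = 0.6  # stationary sd of the AR(1) anomaly


@dataclass(frozen=True)
class BloomParams:
    """Summer bloom pulses in log cell space."""

    blooms_per_year: int = 1
    peak_cells: float = 4.0e6  # cells/L at full amplitude
    width_weeks: float = 2.5  # Gaussian sd of a pulse
    temp_threshold: float = 8.0  # degC; gate on 3-week-lagged temperature
    lag_weeks: int = 3
    shift_per_degc: float = -1.5  # bloom-centre shift per degC spring anomaly


@dataclass(frozen=True)
class AlkCondParams:
    """Linear link alkalinity [mM] = slope * conductivity [mS/m] + intercept."""

    slope: float = 0.05
    intercept: float = -0.2
    cond_noise_sd: float = 0.4  # conductivity scatter about the line, mS/m


@dataclass(frozen=True)
class ScenarioConfig:
    """Full scenario description; equal configs + seeds give identical output."""

    start_year: int = 2015
    end_year: int = 2022
    weekly_points_per_year: int = 52
    sensor_interval_minutes: int = 5
    include_sensor_channels: bool = True
    temp_params: TempParams = field(default_factory=TempParams)
    bloom_params: BloomParams = field(default_factory=BloomParams)
    alk_cond_params: AlkCondParams = field(default_factory=AlkCondParams)
    alk_mean: float = 1.175  # mM
    alk_sd: float = 0.06
    alk_ar: float = 0.99
    baseline_cells: float = 2.0e5
    algae_noise_sd: float = 0.25  # lognormal sd, log space
    co2_baseline: float = 20.0e-6  # mol/L
    co2_drawdown: float = 12.0e-6  # mol/L per unit normalized algae
    co2_process_noise_sd: float = 0.8e-6
    co2_obs_noise_sd: float = 0.8e-6  # extra scatter on the reported CO2 channel
    co2_floor: float = 2.0e-6
    ph_obs_noise_sd: float = 0.02
    sensor_noise_temp: float = 0.05
    sensor_noise_cond: float = 0.3
    sensor_noise_turb: float = 0.1
    sensor_noise_dom: float = 0.1
    decoy_factors: int = 2
    couple_turbidity_dom: bool = False  # weak optional algae coupling
    ph_band: tuple[float, float] = (7.2, 9.3)
    cond_band: tuple[float, float] = (20.0, 35.0)
    turbidity_band: tuple[float, float] = (0.0, 30.0)
    temp_band: tuple[float, float] = (0.0, 12.5)
    seed: int = 0

    def validate(self) -> None:
        if self.end_year < self.start_year:
            raise ConfigError("end_year must be >= start_year")
        for name in (
            "algae_noise_sd", "co2_process_noise_sd", "co2_obs_noise_sd",
            "ph_obs_noise_sd", "alk_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.temp_params.noise_sd < 0 or self.alk_cond_params.cond_noise_sd < 0:
            raise ConfigError("noise standard deviations must be >= 0")
        if self.bloom_params.blooms_per_year < 0:
            raise ConfigError("blooms_per_year must be >= 0")


def noise_free(config: ScenarioConfig) -> ScenarioConfig:
    """Copy of ``config`` with every stochastic term silenced.

    Decoy channels keep their variability (they *are* noise) so that
    structure-recovery oracles can still regress against them.
    """
    return dataclasses.replace(
        config,
        temp_params=dataclasses.replace(config.temp_params, noise_sd=0.0),
        alk_cond_params=dataclasses.replace(
            config.alk_cond_params, cond_noise_sd=0.0
        ),
        alk_sd=0.0,
        algae_noise_sd=0.0,
        co2_process_noise_sd=0.0,
        co2_obs_noise_sd=0.0,
        ph_obs_noise_sd=0.0,
        sensor_noise_temp=0.0,
        sensor_noise_cond=0.0,
        sensor_noise_turb=0.0,
        sensor_noise_dom=0.0,
    )


def _ar1(rng: np.random.Generator, n: int, phi: float, sd: float) -> np.ndarray:
    """Stationary AR(1) with unconditional sd ``sd``."""
    if sd == 0.0:
        return np.zeros(n)
    innov_sd = sd * np.sqrt(1.0 - phi**2)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    eps = rng.normal(0.0, innov_sd, size=n)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + eps[i]
    return x


def _first_monday(year: int) -> pd.Timestamp:
    day = pd.Timestamp(year=year, month=1, day=1)
    return day + pd.Timedelta(days=(7 - day.dayofweek) % 7)


def _weekly_timestamps(config: ScenarioConfig) -> pd.DatetimeIndex:
    # Fixed convention: exactly `weekly_points_per_year` Mondays at 10:00
    # per calendar year, starting from each year's first Monday.  In a
    # year with 53 Mondays the last one is skipped, leaving a single
    # 14-day step at that year boundary.
    stamps = []
    for year in range(config.start_year, config.end_year + 1):
        base = _first_monday(year) + pd.Timedelta(hours=10)
        stamps.extend(
            base + pd.Timedelta(days=7 * w)
            for w in range(config.weekly_points_per_year)
        )
    return pd.DatetimeIndex(stamps)


def _bloom_centers(params: BloomParams) -> np.ndarray:
    m = params.blooms_per_year
    if m <= 0:
        return np.empty(0)
    if m == 1:
        return np.array([31.0])
    return np.linspace(26.0, 34.0, m)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_scenario(config: ScenarioConfig) -> ObservationSeries:
    """Generate one seeded scenario as a long-format observation series."""
    config.validate()
    wk = config.weekly_points_per_year
    n_years = config.end_year - config.start_year + 1
    n = n_years * wk
    times = _weekly_timestamps(config)

    ss = np.random.SeedSequence(config.seed)
    keys = [
        "temperature", "alkalinity", "conductivity", "algae", "co2",
        "co2_obs", "ph_obs", "turbidity", "dom", "decoys", "sensor",
    ]
    rngs = dict(zip(keys, (np.random.default_rng(c) for c in ss.spawn(len(keys)))))

    week_of_year = np.tile(np.arange(1, wk + 1, dtype=float), n_years)

    # Temperature: seasonal sinusoid (minimum late January) + AR(1) anomaly.
    tp = config.temp_params
    seasonal = tp.mean - tp.amplitude * np.cos(2.0 * np.pi * (week_of_year - 4.0) / wk)
    anomaly = _ar1(rngs["temperature"], n, 0.7, tp.noise_sd)
    temperature = np.clip(seasonal + anomaly, config.temp_band[0], None)

    # Alkalinity: slow AR(1) [mM]; conductivity scattered about the line.
    alk = config.alk_mean + _ar1(rngs["alkalinity"], n, config.alk_ar, config.alk_sd)
    ac = config.alk_cond_params
    cond = (alk - ac.intercept) / ac.slope + rngs["conductivity"].normal(
        0.0, ac.cond_noise_sd, size=n
    )

    # Algae: gated Gaussian pulses in log cell space.
    bp = config.bloom_params
    log_amp = np.log(bp.peak_cells / config.baseline_cells)
    lag_temp = np.concatenate(
        [np.full(bp.lag_weeks, temperature[0]), temperature[: n - bp.lag_weeks]]
    )
    gate = _sigmoid((lag_temp - bp.temp_threshold) / 0.75)
    pulse = np.zeros(n)
    centers = _bloom_centers(bp)
    for y in range(n_years):
        sl = slice(y * wk, (y + 1) * wk)
        # Warm springs pull the bloom earlier, cold springs delay it.
        spring = anomaly[sl][13:26]
        shift = bp.shift_per_degc * (spring.mean() if spring.size else 0.0)
        for c in centers:
            pulse[sl] += np.exp(
                -((week_of_year[sl] - (c + shift)) ** 2)
                / (2.0 * bp.width_weeks**2)
            )
    log_algae = (
        np.log(config.baseline_cells)
        + gate * log_amp * pulse
        + rngs["algae"].normal(0.0, config.algae_noise_sd, size=n)
    )
    algae = np.exp(log_algae)

    # Dissolved CO2: photosynthetic drawdown from baseline.
    algae_norm = algae / bp.peak_cells
    co2 = (
        config.co2_baseline
        - config.co2_drawdown * algae_norm
        + rngs["co2"].normal(0.0, config.co2_process_noise_sd, size=n)
    )
    co2 = np.clip(co2, config.co2_floor, None)

    # pH from the carbonate equilibrium (alkalinity mM -> mol/L).
    try:
        ph = ph_from_alk_co2_vec(temperature, alk * 1e-3, co2)
    except Exception as exc:  # pragma: no cover - guarded by config validation
        raise DataError(f"carbonate solve failed during generation: {exc}") from exc
    bad = ~np.isfinite(ph)
    if bad.any():
        raise DataError(
            f"infeasible chemistry at {times[int(np.argmax(bad))]}: "
            f"alk={alk[int(np.argmax(bad))]:.3f} mM, co2={co2[int(np.argmax(bad))]:.2e}"
        )
    ph_obs = ph + rngs["ph_obs"].normal(0.0, config.ph_obs_noise_sd, size=n)
    co2_obs = np.clip(
        co2 + rngs["co2_obs"].normal(0.0, config.co2_obs_noise_sd, size=n),
        1e-7, None,
    )

    # Turbidity / DOM: independent by default, weakly coupled on request.
    turb = np.exp(0.8 + _ar1(rngs["turbidity"], n, 0.8, 0.45))
    dom = np.clip(8.0 + _ar1(rngs["dom"], n, 0.9, 0.8), 0.1, None)
    if config.couple_turbidity_dom:
        turb = turb * (1.0 + 0.3 * algae_norm)
        dom = dom * (1.0 + 0.15 * algae_norm)

    weekly_values: dict[str, np.ndarray] = {
        "algae": algae,
        "alkalinity": alk,
        "temperature": temperature,
        "ph": ph_obs,
        "conductivity": cond,
        "turbidity": turb,
        "dom_uv254": dom,
        "co2": co2_obs,
    }
    decoy_rng = rngs["decoys"]
    for d in range(config.decoy_factors):
        weekly_values[f"decoy_{d + 1}"] = _ar1(decoy_rng, n, 0.8, 1.0)

    if config.include_sensor_channels:
        # sensor factors live on the sensor grid only; weekly rows are
        # reserved for genuine lab quantities (and the decoys)
        weekly_values = {
            name: vals for name, vals in weekly_values.items()
            if name not in SENSOR_FACTORS
        }
    units = dict(UNITS)
    cadences = {name: WEEKLY for name in weekly_values}
    frames = {
        name: pd.Series(vals, index=times) for name, vals in weekly_values.items()
    }
    out = ObservationSeries.from_factors(frames, units, cadences)

    if config.include_sensor_channels:
        out = out.merge(
            _sensor_channels(config, times, temperature, alk, co2, turb, dom,
                             rngs["sensor"])
        )
    return out


def _sensor_channels(
    config: ScenarioConfig,
    weekly_times: pd.DatetimeIndex,
    temperature: np.ndarray,
    alk: np.ndarray,
    co2: np.ndarray,
    turb: np.ndarray,
    dom: np.ndarray,
    rng: np.random.Generator,
) -> ObservationSeries:
    """Sub-daily sensor channels interpolated from the weekly latents.

    pH is re-solved from the carbonate system at sensor cadence so the
    high-resolution chain (conductivity -> alkalinity -> CO2 -> pH) is
    self-consistent; with noise terms at zero the CO2 recovered by
    :func:`bloomscan.carbonate.co2_series` reproduces the planted CO2
    exactly.
    """
    step = pd.Timedelta(minutes=config.sensor_interval_minutes)
    grid = pd.date_range(weekly_times[0], weekly_times[-1], freq=step)
    tw = weekly_times.asi8.astype(float)
    tg = grid.asi8.astype(float)

    def interp(values: np.ndarray) -> np.ndarray:
        return np.interp(tg, tw, values)

    m = len(grid)
    temp_s = np.clip(
        interp(temperature) + rng.normal(0.0, config.sensor_noise_temp, m),
        config.temp_band[0], None,
    )
    alk_s = interp(alk)
    ac = config.alk_cond_params
    cond_s = (alk_s - ac.intercept) / ac.slope + rng.normal(
        0.0, config.sensor_noise_cond, m
    )
    co2_s = interp(co2)
    ph_s = ph_from_alk_co2_vec(temp_s, alk_s * 1e-3, co2_s)
    turb_s = np.clip(
        interp(turb) + rng.normal(0.0, config.sensor_noise_turb, m), 0.0, None
    )
    dom_s = np.clip(
        interp(dom) + rng.normal(0.0, config.sensor_noise_dom, m), 0.0, None
    )

    frames = {
        "temperature": pd.Series(temp_s, index=grid),
        "ph": pd.Series(ph_s, index=grid),
        "conductivity": pd.Series(cond_s, index=grid),
        "turbidity": pd.Series(turb_s, index=grid),
        "dom_uv254": pd.Series(dom_s, index=grid),
        "co2": pd.Series(co2_s, index=grid),
    }
    return ObservationSeries.from_factors(
        frames, UNITS, {name: SENSOR for name in frames}
    )


def inject_gap(
    series: ObservationSeries,
    gap_years: Iterable[int],
    drift: Mapping[str, float] | None = None,
) -> ObservationSeries:
    """Remove all observations whose year falls in ``gap_years``.

    Emulates a monitoring interruption between training and real-world
    application.  ``drift`` optionally adds a constant per-factor offset
    to every observation *after* the gap (slow background change).
    """
    gap = set(int(y) for y in gap_years)
    if not gap:
        return series
    years = series.data["timestamp"].dt.year
    present = set(years.unique())
    if not gap & present:
        raise DataError(f"gap years {sorted(gap)} lie outside the series span")
    keep = ~years.isin(gap)
    if not keep.any():
        raise DataError("gap would remove the entire series")
    out = series.data.loc[keep].copy()
    if drift:
        after = out["timestamp"].dt.year > max(gap)
        for factor, offset in drift.items():
            mask = after & (out["factor"] == factor)
            out.loc[mask, "value"] = out.loc[mask, "value"] + offset
    return ObservationSeries(out, validate=False)


# -- config file I/O (flat YAML) -------------------------------------


def save_config(config: ScenarioConfig, path: str | Path) -> None:
    raw = dataclasses.asdict(config)
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


def load_config(path: str | Path) -> ScenarioConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    for key, cls in (
        ("temp_params", TempParams),
        ("bloom_params", BloomParams),
        ("alk_cond_params", AlkCondParams),
    ):
        if key in raw and isinstance(raw[key], dict):
            raw[key] = cls(**raw[key])
    for key in ("ph_band", "cond_band", "turbidity_band", "temp_band"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return ScenarioConfig(**raw)
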