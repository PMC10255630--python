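"""Carbonate speciation against an independent DIC root-finding oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import brentq

from bloomscan.carbonate import (
    co2_from_ph_alk,
    co2_series,
    equilibrium_constants,
    fit_alkalinity_conductivity,
    ph_from_alk_co2,
    ph_from_alk_co2_vec,
)
from bloomscan.errors import ChemistryInfeasibleError, DataError, MissingFactorError
from bloomscan.series import ObservationSeries

# Grid over which closed-form speciation must agree with the oracle.
GRID_T = (0.0, 5.0, 15.0, 25.0)
GRID_PH = np.arange(6.5, 9.5 + 1e-9, 0.1)
GRID_ALK = (0.3e-3, 0.5e-3, 1.2e-3, 1.5e-3)


def oracle_co2(temperature: float, ph: float, alkalinity: float) -> float:
    """Brute-force speciation: root-find total DIC so that the
    charge-balance alkalinity matches, then take the CO2 fraction.

    Independent route: works through ionization fractions of DIC and
    never touches the closed-form bicarbonate expression.
    """
    k = equilibrium_constants(temperature)
    h = 10.0 ** (-ph)
    a0 = 1.0 / (1.0 + k.k1 / h + k.k1 * k.k2 / h**2)  # CO2* fraction
    a1 = a0 * k.k1 / h
    a2 = a1 * k.k2 / h

    def residual(dic: float) -> float:
        return dic * (a1 + 2.0 * a2) + k.kw / h - h - alkalinity

    dic = brentq(residual, 1e-12, 1.0, xtol=1e-18, rtol=8.9e-16)
    return dic * a0


def test_reference_case_matches_oracle():
    """Reference parcel: 25 degC, pH 8.3, alkalinity 1.2 mM."""
    state = co2_from_ph_alk(25.0, 8.3, 1.2e-3)
    expected = oracle_co2(25.0, 8.3, 1.2e-3)
    assert state.co2_aq == pytest.approx(expected, rel=1e-9)
    # and the inverse recovers pH 8.3 from that CO2
    assert ph_from_alk_co2(25.0, 1.2e-3, state.co2_aq) == pytest.approx(
        8.3, abs=1e-6
    )


def test_oracle_equivalence_over_grid():
    """Closed form vs DIC root-finder to relative 1e-9 over the grid."""
    worst = 0.0
    for t in GRID_T:
        for alk in GRID_ALK:
            for ph in GRID_PH:
                state = co2_from_ph_alk(t, float(ph), alk)
                ref = oracle_co2(t, float(ph), alk)
                worst = max(worst, abs(state.co2_aq - ref) / ref)
    assert worst < 1e-9


def test_monotonicity_over_grid():
    """CO2 falls with pH and rises with alkalinity everywhere."""
    for t in GRID_T:
        for alk in GRID_ALK:
            co2s = [co2_from_ph_alk(t, float(p), alk).co2_aq for p in GRID_PH]
            assert all(a > b for a, b in zip(co2s, co2s[1:]))
        for ph in (6.5, 8.0, 9.5):
            by_alk = [co2_from_ph_alk(t, ph, a).co2_aq for a in GRID_ALK]
            assert all(a < b for a, b in zip(by_alk, by_alk[1:]))


def test_constants_ordering_and_smoothness():
    """K1 > K2 > 0 on 0-30 degC and each constant varies monotonically."""
    temps = np.linspace(0.0, 30.0, 61)
    k1 = np.array([equilibrium_constants(float(t)).k1 for t in temps])
    k2 = np.array([equilibrium_constants(float(t)).k2 for t in temps])
    assert np.all(k1 > k2) and np.all(k2 > 0)
    assert np.all(np.diff(k1) > 0) and np.all(np.diff(k2) > 0)


def test_alkalinity_identity():
    """Returned speciation satisfies the charge-balance identity."""
    state = co2_from_ph_alk(15.0, 8.0, 0.9e-3)
    assert abs(state.alkalinity_residual()) < 1e-12


@given(
    t=st.floats(0.0, 30.0),
    ph=st.floats(6.5, 9.4),
    alk=st.floats(0.3e-3, 1.5e-3),
)
def test_roundtrip_ph_co2(t, ph, alk):
    """pH -> CO2 -> pH is the identity to 1e-6 pH units."""
    state = co2_from_ph_alk(t, ph, alk)
    assert ph_from_alk_co2(t, alk, state.co2_aq) == pytest.approx(ph, abs=1e-6)
    # the vectorized inverse used by the generator agrees with brentq
    vec = float(ph_from_alk_co2_vec(t, alk, state.co2_aq))
    assert vec == pytest.approx(ph, abs=1e-6)


def test_co2_monotone_in_its_inverse():
    """More dissolved CO2 at fixed alkalinity means strictly lower pH."""
    ph_values = [
        ph_from_alk_co2(10.0, 1.0e-3, co2) for co2 in (5e-6, 10e-6, 20e-6)
    ]
    assert ph_values[0] > ph_values[1] > ph_values[2]


def test_infeasible_pairs_raise():
    with pytest.raises(ChemistryInfeasibleError):
        co2_from_ph_alk(25.0, 12.0, 1e-5)  # OH- excess exceeds alkalinity
    with pytest.raises(ChemistryInfeasibleError):
        co2_from_ph_alk(25.0, 8.0, -1.0)
    with pytest.raises(ChemistryInfeasibleError):
        ph_from_alk_co2(25.0, 1.2e-3, 10.0)  # CO2 out of any pH's reach


# -- alkalinity-conductivity pairing ---------------------------------


def _series(times, values, name="x") -> pd.Series:
    return pd.Series(values, index=pd.DatetimeIndex(times), name=name)


def test_pairing_gap_filter():
    """Gaps (1 h, 5 h, 7 h) with a 6 h cut keep exactly 2 pairs."""
    lab_times = pd.to_datetime(
        ["2020-01-06 10:00", "2020-01-13 10:00", "2020-01-20 10:00"]
    )
    sensor_times = pd.to_datetime(
        ["2020-01-06 11:00", "2020-01-13 15:00", "2020-01-20 17:00"]
    )
    alk = _series(lab_times, [1.0, 1.1, 1.2])
    cond = _series(sensor_times, [24.0, 26.0, 28.0])
    fit = fit_alkalinity_conductivity(alk, cond, max_gap_hours=6.0)
    assert fit.n_pairs == 2
    with pytest.raises(DataError):
        fit_alkalinity_conductivity(alk, cond, max_gap_hours=0.5)


def test_exact_slope_on_collinear_pairs():
    times = pd.date_range("2020-01-06", periods=10, freq="7D")
    cond = _series(times, np.linspace(20.0, 35.0, 10))
    alk = _series(times, 0.05 * cond.to_numpy() - 0.2)
    fit = fit_alkalinity_conductivity(alk, cond)
    assert fit.slope == pytest.approx(0.05, abs=1e-12)
    assert fit.intercept == pytest.approx(-0.2, abs=1e-10)
    assert fit.n_pairs == 10


def test_noisy_slope_within_ols_standard_error():
    """Recovered slope lies inside the closed-form OLS error band.

    The band comes from an independent normal-equations computation:
    Var(slope) = sigma^2 / sum((x - xbar)^2).
    """
    rng = np.random.default_rng(42)
    times = pd.date_range("2020-01-06", periods=100, freq="7D")
    x = rng.uniform(20.0, 35.0, 100)
    noise = rng.normal(0.0, 0.02, 100)
    alk = _series(times, 0.05 * x - 0.2 + noise)
    cond = _series(times, x)
    fit = fit_alkalinity_conductivity(alk, cond)
    se = 0.02 / np.sqrt(np.sum((x - x.mean()) ** 2))
    assert abs(fit.slope - 0.05) < 4 * se


# -- sensor-cadence CO2 series ---------------------------------------


def _sensor_series(ph, temp, cond, times) -> ObservationSeries:
    frames = {
        "ph": _series(times, ph),
        "temperature": _series(times, temp),
        "conductivity": _series(times, cond),
    }
    return ObservationSeries.from_factors(
        frames, {}, {k: "sensor" for k in frames}
    )


def test_constant_inputs_give_constant_co2():
    times = pd.date_range("2020-06-01", periods=20, freq="5min")
    series = _sensor_series([8.0] * 20, [15.0] * 20, [28.0] * 20, times)
    from bloomscan.carbonate import AlkConductivityFit

    fit = AlkConductivityFit(0.05, -0.2, 0.0, 10, 6.0)
    result = co2_series(series, fit)
    values = result.series.get("co2").to_numpy()
    assert len(values) == 20 and result.n_infeasible == 0
    assert np.allclose(values, values[0])


def test_infeasible_points_flagged_not_dropped():
    """N points with k infeasible -> N-k outputs plus k flags."""
    times = pd.date_range("2020-06-01", periods=10, freq="5min")
    ph = [8.0] * 7 + [11.9] * 3  # hydroxide excess beats predicted alk
    series = _sensor_series(ph, [15.0] * 10, [28.0] * 10, times)
    from bloomscan.carbonate import AlkConductivityFit

    fit = AlkConductivityFit(0.0, 0.1, 0.0, 10, 6.0)  # 0.1 mM alkalinity
    result = co2_series(series, fit)
    assert len(result.series) == 7
    assert result.n_infeasible == 3


def test_missing_factor_named():
    times = pd.date_range("2020-06-01", periods=5, freq="5min")
    frames = {"ph": _series(times, [8.0] * 5)}
    series = ObservationSeries.from_factors(frames, {}, {"ph": "sensor"})
    from bloomscan.carbonate import AlkConductivityFit

    with pytest.raises(MissingFactorError, match="temperature"):
        co2_series(series, AlkConductivityFit(0.05, -0.2, 0.0, 10, 6.0))


def test_generator_roundtrip_recovers_planted_co2():
    """With noise terms silenced the sensor-chain CO2 is recovered
    exactly from (pH, temperature, conductivity) via the generator's own
    alkalinity-conductivity line."""
    import dataclasses

    from bloomscan.synthetic import ScenarioConfig, generate_scenario, noise_free

    config = noise_free(
        dataclasses.replace(
            ScenarioConfig(seed=5),
            start_year=2016,
            end_year=2016,
            sensor_interval_minutes=240,
        )
    )
    series = generate_scenario(config)
    ac = config.alk_cond_params
    from bloomscan.carbonate import AlkConductivityFit

    fit = AlkConductivityFit(ac.slope, ac.intercept, 0.0, 52, 6.0)
    sensors = series.subset(series.data["cadence"] == "sensor")
    no_co2 = sensors.subset(sensors.data["factor"] != "co2")
    result = co2_series(no_co2, fit)
    planted = sensors.get("co2")
    recovered = result.series.get("co2")
    assert result.n_infeasible == 0
    joined = pd.concat([planted, recovered], axis=1, join="inner")
    assert len(joined) == len(planted)
    rel = np.abs(joined.iloc[:, 1] - joined.iloc[:, 0]) / joined.iloc[:, 0]
    assert rel.max() < 1e-6
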