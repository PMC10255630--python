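"""Dilute freshwater carbonate chemistry.

Dissolved CO2 cannot be measured directly at most intakes, but in
calcite-metastable surface water it is fixed by three routinely measured
quantities: pH, water temperature and alkalinity.  This module solves the
open carbonate system in both directions,

* ``co2_from_ph_alk`` — closed-form speciation given (T, pH, alkalinity),
* ``ph_from_alk_co2`` — the inverse root-find, used by the synthetic
  generator to turn a planted CO2 signal into a pH signal,

and upgrades weekly lab alkalinity to sensor cadence through the
alkalinity–conductivity regression with a configurable maximum pairing
gap (default 6 h).

Model
-----
Charge-balance alkalinity with carbonate species only::

    Alk = [HCO3-] + 2 [CO3--] + [OH-] - [H+]

Activity corrections are ignored: at 20–35 mS/m the ionic strength is a
few mmol/L and activity coefficients deviate from unity by far less than
the sensors' own precision.  Temperature-dependent dissociation constants
K1, K2 (carbonic acid) and Kw (water) use the freshwater expressions of
Plummer & Busenberg (1982) and the matching water ion-product fit, the
same parameterization family PHREEQC's standard database employs.
Alkalinity is in mol/L throughout this module; the regression interface
uses the field units mM and mS/m and converts explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import ChemistryInfeasibleError, DataError, MissingFactorError
from .series import SENSOR, ObservationSeries

__all__ = [
    "EquilibriumConstants",
    "CarbonateState",
    "AlkConductivityFit",
    "equilibrium_constants",
    "co2_from_ph_alk",
    "ph_from_alk_co2",
    "speciate",
    "fit_alkalinity_conductivity",
    "co2_series",
    "Co2SeriesResult",
]


@dataclass(frozen=True)
class EquilibriumConstants:
    """Temperature-resolved dissociation constants (molar scale)."""

    temperature: float  # degC
    k1: float  # H2CO3* <-> H+ + HCO3-
    k2: float  # HCO3- <-> H+ + CO3--
    kw: float  # H2O <-> H+ + OH-


def equilibrium_constants(temperature: float) -> EquilibriumConstants:
    """K1, K2, Kw at ``temperature`` (degC), dilute-solution molar scale.

    Valid for roughly 0–40 degC; raises for temperatures outside
    [-0.5, 40] where the fits are untrustworthy for lake water.
    """
    t = np.asarray(temperature, dtype=float)
    if np.any(t < -0.5) or np.any(t > 40.0):
        raise ChemistryInfeasibleError(
            f"temperature {temperature} degC outside supported [-0.5, 40]"
        )
    tk = t + 273.15
    log_tk = np.log10(tk)
    # Plummer & Busenberg (1982) carbonic acid constants.
    log_k1 = (
        -356.3094 - 0.06091964 * tk + 21834.37 / tk
        + 126.8339 * log_tk - 1684915.0 / tk**2
    )
    log_k2 = (
        -107.8871 - 0.03252849 * tk + 5151.79 / tk
        + 38.92561 * log_tk - 563713.9 / tk**2
    )
    # Water ion product fit used alongside the above in standard databases.
    log_kw = (
        -283.9710 - 0.05069842 * tk + 13323.00 / tk
        + 102.24447 * log_tk - 1119669.0 / tk**2
    )
    if np.ndim(temperature) == 0:
        return EquilibriumConstants(
            float(temperature), 10.0 ** float(log_k1),
            10.0 ** float(log_k2), 10.0 ** float(log_kw),
        )
    # Vector path used internally by speciate().
    return EquilibriumConstants(np.nan, 10.0**log_k1, 10.0**log_k2, 10.0**log_kw)  # type: ignore[arg-type]


@dataclass(frozen=True)
class CarbonateState:
    """Full speciation of one water parcel (concentrations in mol/L)."""

    temperature: float
    ph: float
    alkalinity: float
    co2_aq: float
    hco3: float
    co3: float

    def alkalinity_residual(self) -> float:
        """Charge-balance alkalinity identity residual (mol/L)."""
        k = equilibrium_constants(self.temperature)
        h = 10.0 ** (-self.ph)
        return (self.hco3 + 2.0 * self.co3 + k.kw / h - h) - self.alkalinity


def speciate(temperature, ph, alkalinity):
    """Vectorized closed-form speciation.

    Returns ``(co2_aq, hco3, co3, feasible)`` arrays; infeasible points
    (alkalinity too low for the given pH, i.e. negative bicarbonate) are
    flagged False and carry NaN concentrations.
    """
    t = np.asarray(temperature, dtype=float)
    ph = np.asarray(ph, dtype=float)
    alk = np.asarray(alkalinity, dtype=float)
    k = equilibrium_constants(t)
    h = 10.0 ** (-ph)
    with np.errstate(invalid="ignore"):
        hco3 = (alk - k.kw / h + h) / (1.0 + 2.0 * k.k2 / h)
        co3 = k.k2 * hco3 / h
        co2 = h * hco3 / k.k1
    feasible = (hco3 >= 0.0) & (alk > 0.0)
    hco3 = np.where(feasible, hco3, np.nan)
    co3 = np.where(feasible, co3, np.nan)
    co2 = np.where(feasible, co2, np.nan)
    return co2, hco3, co3, feasible


def co2_from_ph_alk(
    temperature: float, ph: float, alkalinity: float
) -> CarbonateState:
    """Solve the carbonate system for one (T degC, pH, Alk mol/L) triple.

    Raises :class:`ChemistryInfeasibleError` when the pair (pH,
    alkalinity) admits no non-negative bicarbonate concentration.
    """
    if not 4.0 <= ph <= 12.0:
        raise ChemistryInfeasibleError(f"pH {ph} outside supported [4, 12]")
    if not alkalinity > 0.0:
        raise ChemistryInfeasibleError(
            f"alkalinity must be positive, got {alkalinity}"
        )
    co2, hco3, co3, feasible = speciate(temperature, ph, alkalinity)
    if not feasible:
        raise ChemistryInfeasibleError(
            f"(pH={ph}, alkalinity={alkalinity} mol/L) at {temperature} degC "
            "implies negative bicarbonate"
        )
    return CarbonateState(
        float(temperature), float(ph), float(alkalinity),
        float(co2), float(hco3), float(co3),
    )


def ph_from_alk_co2(
    temperature: float, alkalinity: float, co2_aq: float
) -> float:
    """pH at which (T, alkalinity) yields the given dissolved CO2.

    The solution is unique because CO2 is strictly decreasing in pH at
    fixed alkalinity.  Raises when no root exists in pH [4, 12].
    """
    if alkalinity <= 0.0:
        raise ChemistryInfeasibleError("alkalinity must be positive")
    if co2_aq <= 0.0:
        raise ChemistryInfeasibleError("co2_aq must be positive")
    k = equilibrium_constants(temperature)

    # [H+] is the single positive root of the cubic below (one sign
    # change); solving in H avoids rounding trouble at the feasibility
    # edge where hco3 -> 0 and the pH-space objective turns NaN.
    def cubic(h: float) -> float:
        return (
            h**3 + alkalinity * h**2 - (k.kw + k.k1 * co2_aq) * h
            - 2.0 * k.k1 * k.k2 * co2_aq
        )

    lo, hi = 1e-14, 1e-2  # pH 14 .. 2
    if cubic(lo) > 0.0 or cubic(hi) < 0.0:
        raise ChemistryInfeasibleError(
            f"no pH in [4, 12] reproduces co2_aq={co2_aq} mol/L at "
            f"alkalinity={alkalinity} mol/L, T={temperature} degC"
        )
    h = brentq(cubic, lo, hi, xtol=1e-300, rtol=8.9e-16)
    ph = -np.log10(h)
    if not 4.0 <= ph <= 12.0:
        raise ChemistryInfeasibleError(
            f"solution pH {ph:.3f} falls outside [4, 12]"
        )
    return float(ph)


def ph_from_alk_co2_vec(temperature, alkalinity, co2_aq, n_iter: int = 70):
    """Vectorized inverse solve via bisection on [H+].

    [H+] is the unique positive root of the cubic
    ``H^3 + Alk H^2 - (Kw + K1 co2) H - 2 K1 K2 co2 = 0`` (one sign change
    in the coefficient sequence).  Used by the synthetic generator for
    long sensor-cadence series.
    """
    t = np.asarray(temperature, dtype=float)
    alk = np.asarray(alkalinity, dtype=float)
    co2 = np.asarray(co2_aq, dtype=float)
    k = equilibrium_constants(t)

    def cubic(h):
        return (
            h**3 + alk * h**2 - (k.kw + k.k1 * co2) * h
            - 2.0 * k.k1 * k.k2 * co2
        )

    lo = np.full(np.broadcast(t, alk, co2).shape, 1e-14)
    hi = np.full_like(lo, 1e-2)
    if np.any(cubic(hi) < 0.0):
        raise ChemistryInfeasibleError("co2_aq too large for pH >= 2 solve")
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        below = cubic(mid) < 0.0
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    return -np.log10(0.5 * (lo + hi))


@dataclass(frozen=True)
class AlkConductivityFit:
    """OLS link Alk [mM] = slope * conductivity [mS/m] + intercept."""

    slope: float  # mM per mS/m
    intercept: float  # mM
    residual_sd: float  # mM
    n_pairs: int
    max_pairing_gap_hours: float

    def predict_alkalinity_mm(self, conductivity):
        return self.slope * np.asarray(conductivity, dtype=float) + self.intercept


def _nearest_pairs(
    lab_times: np.ndarray, sensor_times: np.ndarray
) -> np.ndarray:
    """Index of the nearest sensor timestamp for each lab timestamp.

    Ties in absolute gap break toward the earlier sensor observation.
    """
    pos = np.searchsorted(sensor_times, lab_times)
    left = np.clip(pos - 1, 0, len(sensor_times) - 1)
    right = np.clip(pos, 0, len(sensor_times) - 1)
    d_left = np.abs(lab_times - sensor_times[left])
    d_right = np.abs(lab_times - sensor_times[right])
    return np.where(d_left <= d_right, left, right)


def fit_alkalinity_conductivity(
    weekly_alk: pd.Series,
    conductivity: pd.Series,
    max_gap_hours: float = 6.0,
) -> AlkConductivityFit:
    """Regress weekly lab alkalinity (mM) on paired conductivity (mS/m).

    Each lab value is paired with the nearest-in-time conductivity
    observation; pairs further apart than ``max_gap_hours`` are dropped.
    Requires at least two surviving pairs.
    """
    if weekly_alk.empty or conductivity.empty:
        raise DataError("empty series passed to alkalinity-conductivity fit")
    lab_t = weekly_alk.index.values.astype("datetime64[ns]").astype("int64")
    sen_t = conductivity.index.values.astype("datetime64[ns]").astype("int64")
    order = np.argsort(sen_t, kind="stable")
    sen_t, sen_v = sen_t[order], conductivity.to_numpy()[order]
    idx = _nearest_pairs(lab_t, sen_t)
    gap_h = np.abs(lab_t - sen_t[idx]) / 3.6e12
    keep = gap_h <= max_gap_hours
    n = int(keep.sum())
    if n < 2:
        raise DataError(
            f"only {n} alkalinity-conductivity pairs within "
            f"{max_gap_hours} h; need >= 2"
        )
    x = sen_v[idx][keep]
    y = weekly_alk.to_numpy()[keep]
    design = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    residual_sd = float(np.sqrt(resid @ resid / max(n - 2, 1)))
    return AlkConductivityFit(
        slope=float(coef[0]),
        intercept=float(coef[1]),
        residual_sd=residual_sd,
        n_pairs=n,
        max_pairing_gap_hours=float(max_gap_hours),
    )


@dataclass
class Co2SeriesResult:
    """Sensor-cadence CO2 with explicit accounting of infeasible points."""

    series: ObservationSeries
    infeasible: pd.DataFrame  # columns: timestamp, ph, alkalinity_mm

    @property
    def n_infeasible(self) -> int:
        return len(self.infeasible)


def co2_series(
    sensor_series: ObservationSeries,
    fit: AlkConductivityFit,
) -> Co2SeriesResult:
    """Compute a sensor-cadence dissolved-CO2 series.

    Alkalinity is predicted from conductivity through ``fit``, then the
    carbonate system is solved pointwise at every timestamp where pH,
    temperature and conductivity are all present.  Chemically infeasible
    points are excluded from the output and reported, never silently
    dropped.
    """
    for name in ("ph", "temperature", "conductivity"):
        if not sensor_series.has(name):
            raise MissingFactorError(name, "sensor series")
    wide = sensor_series.wide(["ph", "temperature", "conductivity"])
    alk_mm = fit.predict_alkalinity_mm(wide["conductivity"].to_numpy())
    co2, _, _, feasible = speciate(
        wide["temperature"].to_numpy(),
        wide["ph"].to_numpy(),
        alk_mm * 1e-3,
    )
    ok = feasible & np.isfinite(co2)
    out = pd.DataFrame(
        {
            "timestamp": wide.index[ok],
            "factor": "co2",
            "value": co2[ok],
            "unit": "mol/L",
            "cadence": SENSOR,
        }
    )
    bad = pd.DataFrame(
        {
            "timestamp": wide.index[~ok],
            "ph": wide["ph"].to_numpy()[~ok],
            "alkalinity_mm": alk_mm[~ok],
        }
    )
    return Co2SeriesResult(ObservationSeries(out), bad)
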