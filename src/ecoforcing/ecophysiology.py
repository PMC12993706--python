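"""Daily ecophysiological diagnostics: WUE, EF, Ga, Gs and decoupling.

Big-leaf biometeorology on daytime daily means:

* water-use efficiency WUE = GPP / ET (g C per kg water), with ET derived
  from latent heat via the temperature-dependent heat of vaporization;
* evaporative fraction EF = LE / (LE + H);
* bulk aerodynamic conductance Ga = [u/u*^2 + 6.2 u*^(-2/3)]^-1;
* surface conductance Gs by inverting the Penman-Monteith equation with
  measured LE;
* the Jarvis-McNaughton decoupling coefficient
  Omega = (eps + 1) / (eps + 1 + Ga/Gs), eps = s/gamma, which is 0 for a
  surface fully coupled to the atmosphere and 1 when fully decoupled.

Psychrometrics use Magnus-type saturation vapor pressure and
gamma = Cp * P / (0.622 * lambda).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .tower_io import CONSTANTS, PhysicalConstants

log = logging.getLogger("ecoforcing")

#: physically plausible upper bound for inverted Gs (m s-1)
GS_MAX = 0.1


# ---------------------------------------------------------------------------
# Psychrometric helpers
# ---------------------------------------------------------------------------

def saturation_vapor_pressure(tair_c):
    """Saturation vapor pressure (kPa) via the Magnus formula."""
    t = np.asarray(tair_c, dtype=float)
    return 0.6108 * np.exp(17.27 * t / (t + 237.3))


def esat_slope(tair_c):
    """Slope of the saturation vapor-pressure curve (kPa K-1)."""
    t = np.asarray(tair_c, dtype=float)
    return 4098.0 * saturation_vapor_pressure(t) / (t + 237.3) ** 2


def psychrometric_constant(tair_c, pressure_kpa,
                           constants: PhysicalConstants = CONSTANTS):
    """gamma = Cp * P / (0.622 * lambda) in kPa K-1."""
    lam = constants.latent_heat(tair_c)  # J kg-1
    return constants.Cp * np.asarray(pressure_kpa, dtype=float) / (0.622 * lam)


def air_density(tair_c, pressure_kpa,
                constants: PhysicalConstants = CONSTANTS):
    """Dry-air density (kg m-3) from the ideal-gas law."""
    tk = np.asarray(tair_c, dtype=float) + 273.15
    return np.asarray(pressure_kpa, dtype=float) * 1e3 / (constants.Rd * tk)


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def et_from_le(le_daily_mean, tair_c,
               constants: PhysicalConstants = CONSTANTS):
    """Daily evapotranspiration (kg H2O m-2 d-1) from daily-mean LE."""
    lam = constants.latent_heat(tair_c)
    return np.asarray(le_daily_mean, dtype=float) * 86400.0 / lam


def water_use_efficiency(gpp_daily, et_daily, et_floor: float = 0.1):
    """WUE = GPP / ET (g C kg-1 H2O); NaN below the ET floor."""
    gpp = np.asarray(gpp_daily, dtype=float)
    et = np.asarray(et_daily, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        wue = gpp / et
    return np.where(et >= et_floor, wue, np.nan)


def evaporative_fraction(le, h, floor: float = 10.0):
    """EF = LE / (LE + H) on daytime means; NaN below the energy floor."""
    le = np.asarray(le, dtype=float)
    h = np.asarray(h, dtype=float)
    den = le + h
    with np.errstate(divide="ignore", invalid="ignore"):
        ef = le / den
    return np.where(den > floor, ef, np.nan)


def aerodynamic_conductance(u, ustar):
    """Bulk aerodynamic conductance Ga = [u/u*^2 + 6.2 u*^(-2/3)]^-1.

    Non-positive wind speed or friction velocity yields NaN.
    """
    u = np.asarray(u, dtype=float)
    us = np.asarray(ustar, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ga = 1.0 / (u / us ** 2 + 6.2 * us ** (-2.0 / 3.0))
    return np.where((u > 0) & (us > 0), ga, np.nan)


def surface_conductance(le, rn_minus_g, vpd_kpa, tair_c, pressure_kpa, ga,
                        constants: PhysicalConstants = CONSTANTS,
                        den_floor: float = 1.0):
    """Surface conductance by Penman-Monteith inversion (m s-1).

    Gs = gamma * LE * Ga / [ Delta * (Rn - G) + rho * Cp * VPD * Ga
                             - LE * (Delta + gamma) ]

    Near-zero denominators (|den| < den_floor), negative inversions and
    values above the physical plausibility bound (0.1 m s-1) yield NaN
    (with a counter logged).
    """
    le = np.asarray(le, dtype=float)
    ga = np.asarray(ga, dtype=float)
    delta = esat_slope(tair_c)
    gamma = psychrometric_constant(tair_c, pressure_kpa, constants)
    rho = air_density(tair_c, pressure_kpa, constants)
    den = (delta * np.asarray(rn_minus_g, dtype=float)
           + rho * constants.Cp * np.asarray(vpd_kpa, dtype=float) * ga
           - le * (delta + gamma))
    with np.errstate(divide="ignore", invalid="ignore"):
        gs = gamma * le * ga / den
    bad = (~np.isfinite(gs)) | (np.abs(den) < den_floor) | (gs < 0) | (gs > GS_MAX)
    # an exactly-zero LE legitimately gives Gs = 0
    bad &= ~(le == 0.0)
    n_bad = int(np.sum(bad & np.isfinite(le)))
    if n_bad:
        log.info("surface_conductance: %d implausible inversion(s) nulled",
                 n_bad)
    return np.where(bad, np.nan, gs)


def penman_monteith_le(gs, rn_minus_g, vpd_kpa, tair_c, pressure_kpa, ga,
                       constants: PhysicalConstants = CONSTANTS):
    """Forward Penman-Monteith latent heat (W m-2), for round-trip checks.

    LE = [Delta (Rn-G) + rho Cp VPD Ga] / [Delta + gamma (1 + Ga/Gs)]
    """
    delta = esat_slope(tair_c)
    gamma = psychrometric_constant(tair_c, pressure_kpa, constants)
    rho = air_density(tair_c, pressure_kpa, constants)
    num = (delta * np.asarray(rn_minus_g, dtype=float)
           + rho * constants.Cp * np.asarray(vpd_kpa, dtype=float)
           * np.asarray(ga, dtype=float))
    den = delta + gamma * (1.0 + np.asarray(ga, dtype=float)
                           / np.asarray(gs, dtype=float))
    return num / den


def decoupling_coefficient(ga, gs, tair_c, pressure_kpa,
                           constants: PhysicalConstants = CONSTANTS):
    """Jarvis-McNaughton Omega = (eps+1) / (eps+1 + Ga/Gs), eps = s/gamma.

    Non-positive conductances yield NaN; Omega lies in (0, 1).
    """
    ga = np.asarray(ga, dtype=float)
    gs = np.asarray(gs, dtype=float)
    eps = esat_slope(tair_c) / psychrometric_constant(
        tair_c, pressure_kpa, constants)
    with np.errstate(divide="ignore", invalid="ignore"):
        omega = (eps + 1.0) / (eps + 1.0 + ga / gs)
    return np.where((ga > 0) & (gs > 0), omega, np.nan)


# ---------------------------------------------------------------------------
# Daily table
# ---------------------------------------------------------------------------

def ecophys_daily(daytime_means: pd.DataFrame,
                  gpp_daily_gc: pd.Series,
                  tair_daily: pd.Series,
                  le_daily_24h: pd.Series | None = None,
                  constants: PhysicalConstants = CONSTANTS,
                  min_available: float = 20.0) -> pd.DataFrame:
    """Daily WUE, ET, EF, Ga, Gs and Omega for one site x layer.

    ``daytime_means`` holds daytime (SW_pot > 0) daily means of LE, H, Rn,
    G, VPD, Tair, pressure, u and ustar; Gs and Omega are computed only on
    days with available energy Rn - G above ``min_available`` (W m-2),
    below which the inversion is ill-posed. ET (and hence WUE) uses the
    24-h mean LE when given, since evapotranspiration integrates the whole
    day.
    """
    d = daytime_means
    le_for_et = (le_daily_24h.loc[d.index] if le_daily_24h is not None
                 else d["LE"])
    et = et_from_le(le_for_et, tair_daily.loc[d.index], constants)
    rn_g = (d["Rn"] - d["G"]).to_numpy()
    ga = aerodynamic_conductance(d["u"], d["ustar"])
    ok = rn_g > min_available
    gs = np.where(ok, surface_conductance(
        d["LE"], rn_g, d["VPD"], d["Tair"], d["pressure"], ga, constants),
        np.nan)
    omega = decoupling_coefficient(ga, gs, d["Tair"], d["pressure"],
                                   constants)
    return pd.DataFrame({
        "ET": et,
        "WUE": water_use_efficiency(gpp_daily_gc.loc[d.index], et),
        "EF": evaporative_fraction(d["LE"], d["H"]),
        "Ga": ga, "Gs": gs, "Omega": omega,
    }, index=d.index)
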