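"""Data-selection rules applied before forcing and decomposition analyses.

Implements the clear-sky screening of midday albedo, the rainy-day and
66%-missingness exclusions protecting the daily surface-temperature
decomposition, the sign/2-degC agreement filter between observed and
calculated temperature differences, the canopy-fraction weighting of soil
heat flux, and the energy-balance-closure diagnostic.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .tower_io import AnalysisConfig, day_of, midday_mask
from .synthetic_towers import potential_radiation

log = logging.getLogger("ecoforcing")


def clear_sky_index(swdr, sw_pot, transmissivity: float = 0.75):
    """Measured / expected clear-sky shortwave, NaN under a low-sun guard.

    The expected clear-sky irradiance is transmissivity-scaled potential
    radiation; the ratio is undefined (NaN) when that expectation is below
    20 W m-2, and for negative SWDR readings.
    """
    swdr = np.asarray(swdr, dtype=float)
    expect = transmissivity * np.asarray(sw_pot, dtype=float)
    bad = (expect <= 20.0) | (swdr < 0) | ~np.isfinite(swdr)
    n_neg = int(np.sum(swdr < 0))
    if n_neg:
        log.warning("clear_sky_index: %d negative SWDR values nulled", n_neg)
    with np.errstate(divide="ignore", invalid="ignore"):
        csi = np.where(bad, np.nan, swdr / np.where(expect > 0, expect, np.nan))
    return csi


def combine_soil_heat_flux(g_open, g_canopy, canopy_fraction: float):
    """Canopy-fraction-weighted ecosystem soil heat flux.

    G = f * G_canopy + (1 - f) * G_open; NaN if either input is missing.
    """
    if not 0.0 <= canopy_fraction <= 1.0:
        raise ValueError("canopy_fraction must be in [0, 1]")
    g_open = np.asarray(g_open, dtype=float)
    g_canopy = np.asarray(g_canopy, dtype=float)
    if canopy_fraction == 0.0:
        return g_open.copy() if g_open.ndim else float(g_open)
    if canopy_fraction == 1.0:
        return g_canopy.copy() if g_canopy.ndim else float(g_canopy)
    return canopy_fraction * g_canopy + (1.0 - canopy_fraction) * g_open


def _with_solar(df: pd.DataFrame, latitude: float) -> pd.DataFrame:
    """Attach potential radiation (at interval midpoints) and the date."""
    out = df.copy()
    mid = out["timestamp"] - pd.Timedelta(minutes=15)
    hour = mid.dt.hour.to_numpy() + mid.dt.minute.to_numpy() / 60.0
    out["sw_pot"] = potential_radiation(
        latitude, mid.dt.dayofyear.to_numpy(), hour)
    out["date"] = day_of(out["timestamp"])
    return out


def midday_albedo_daily(df: pd.DataFrame, config: AnalysisConfig,
                        latitude: float = 39.94) -> pd.DataFrame:
    """Daily midday surface albedo per site x layer.

    Albedo is SWUR/SWDR averaged over midday (11:00-14:30) half-hours with
    clear-sky index above threshold and SWDR above the low-sun floor, on
    non-rainy days. Days with no qualifying half-hour, and ratios outside
    (0, 1), yield NaN (with a discard counter logged).
    """
    d = _with_solar(df, latitude)
    d["csi"] = clear_sky_index(d["SWDR"], d["sw_pot"], config.transmissivity)
    rainy_days = (d.assign(r=d["precip"].fillna(0) > 0)
                    .groupby(["site_id", "layer", "date"])["r"].any())

    ok = (midday_mask(d["timestamp"], config)
          & (d["csi"] > config.clear_sky_threshold)
          & (d["SWDR"] > config.swdr_floor)
          & d["SWUR"].notna())
    d = d[ok].copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        d["ratio"] = d["SWUR"] / d["SWDR"]
    out_of_range = ~d["ratio"].between(0.0, 1.0, inclusive="neither")
    if out_of_range.any():
        log.info("midday_albedo_daily: %d ratios outside (0,1) discarded",
                 int(out_of_range.sum()))
        d.loc[out_of_range, "ratio"] = np.nan

    daily = (d.groupby(["site_id", "layer", "date"])["ratio"]
               .agg(albedo="mean", n_halfhours="count").reset_index())
    daily = daily.join(rainy_days.rename("is_rainy"),
                       on=["site_id", "layer", "date"])
    daily["is_rainy"] = daily["is_rainy"].fillna(False)
    daily.loc[daily["is_rainy"], "albedo"] = np.nan
    return daily


#: variables the decomposition consumes, protected by the missingness rule
DECOMPOSITION_VARS = ("LE", "H", "G_open", "SWDR", "SWUR", "LWDR", "LWUR")


def day_flags(df: pd.DataFrame, config: AnalysisConfig,
              latitude: float = 39.94) -> pd.DataFrame:
    """Per-day rain and missingness flags for the decomposition filter.

    A day passes when it is rain-free and neither its nighttime nor its
    daytime missing fraction (worst case over the variables the
    decomposition needs) exceeds the configured limits. Day/night is split
    by potential radiation > 0 at the interval midpoint.
    """
    d = _with_solar(df, latitude)
    d["is_day"] = d["sw_pot"] > 0
    d["missing"] = d[list(DECOMPOSITION_VARS)].isna().any(axis=1)
    d["rainy"] = d["precip"].fillna(0) > 0

    rows = []
    for (site, layer, date), grp in d.groupby(["site_id", "layer", "date"]):
        day = grp[grp["is_day"]]
        night = grp[~grp["is_day"]]
        fday = day["missing"].mean() if len(day) else 0.0
        fnight = night["missing"].mean() if len(night) else 0.0
        rainy = bool(grp["rainy"].any())
        passes = ((fnight <= config.max_missing_night)
                  and (fday <= config.max_missing_day)
                  and not rainy)
        rows.append((site, layer, date, rainy, fnight, fday, passes,
                     int(len(day) - day["missing"].sum())))
    return pd.DataFrame(rows, columns=[
        "site_id", "layer", "date", "is_rainy",
        "night_missing_fraction", "day_missing_fraction",
        "passes_missingness", "n_valid_day_halfhours"])


def delta_ts_agreement(dts_obs, dts_cal, threshold: float = 2.0):
    """Keep days where observed and calculated dTs agree.

    Keep iff the signs match (exact zero agrees with either sign) and the
    absolute difference is below the threshold; NaN in either input drops
    the day.
    """
    obs = np.asarray(dts_obs, dtype=float)
    cal = np.asarray(dts_cal, dtype=float)
    valid = np.isfinite(obs) & np.isfinite(cal)
    sign_ok = (np.sign(obs) == np.sign(cal)) | (obs == 0) | (cal == 0)
    keep = valid & sign_ok & (np.abs(obs - cal) < threshold)
    n_null = int(np.size(obs) - np.sum(valid))
    if n_null:
        log.info("delta_ts_agreement: %d day(s) with missing input dropped",
                 n_null)
    return keep


def energy_balance_closure(daily: pd.DataFrame) -> dict:
    """Energy-balance closure from daily means of LE, H, Rn and G.

    Returns the through-origin OLS slope of (LE + H) against (Rn - G) and
    the ratio of sums. Requires at least 30 complete days.
    """
    d = daily.dropna(subset=["LE", "H", "Rn", "G"])
    if len(d) < 30:
        raise ValueError(
            f"energy_balance_closure needs >= 30 valid days, got {len(d)}")
    y = (d["LE"] + d["H"]).to_numpy()
    x = (d["Rn"] - d["G"]).to_numpy()
    slope = float(np.sum(x * y) / np.sum(x * x))
    ratio = float(np.sum(y) / np.sum(x))
    return {"slope": slope, "ratio_of_sums": ratio, "n_days": int(len(d))}
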