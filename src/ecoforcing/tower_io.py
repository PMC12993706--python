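"""Shared data model, constants, configuration and I/O for the tower pipeline.

Half-hourly eddy-covariance / radiometric records are carried as pandas
DataFrames with a fixed column schema (one row per site x layer x half-hour).
Timestamps follow the flux-community convention: period-end, local standard
time, no daylight-saving shifts, strict 30-min spacing.

Missing values are NaN in memory and ``-9999`` (or empty) on disk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from datetime import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("ecoforcing")

# ---------------------------------------------------------------------------
# Schema
# ---------------------------------------------------------------------------

#: numeric columns of a half-hourly record, in canonical on-disk order
NUMERIC_COLUMNS = [
    "NEE", "GPP", "Reco",            # umol CO2 m-2 s-1
    "LE", "H",                       # W m-2
    "G_open", "G_canopy",            # W m-2
    "SWDR", "SWUR", "LWDR", "LWUR",  # W m-2
    "Tair",                          # degC
    "VPD",                           # kPa
    "pressure",                      # kPa
    "precip",                        # mm per half-hour
    "u", "ustar",                    # m s-1
    "qc_nee",                        # 0-2 quality flag
]

COLUMNS = ["timestamp", "site_id", "layer"] + NUMERIC_COLUMNS

SITES = ("CT", "NT", "NPT")
LAYERS = ("ecosystem", "understory")
SEASONS = ("autumn", "winter", "spring", "drydown", "summer")

MISSING_SENTINEL = -9999.0
TIMESTAMP_FORMAT = "%Y-%m-%d %H:%M"

# columns that may never be negative when present
_NONNEGATIVE = ("SWDR", "SWUR", "precip", "ustar")


@dataclass(frozen=True)
class PhysicalConstants:
    """Physical constants of the forcing and decomposition equations.

    Defaults are the values used throughout the analysis: the
    Stefan-Boltzmann constant, the mass of the atmosphere (5.15e21 g), the
    molar-mass ratio of air to carbon (2.414, for NEE given in g C), the CO2
    airborne fraction (0.44), the 2014 baseline CO2 dry mole fraction
    (399.4 ppm), the 5.35 W m-2 CO2 forcing coefficient, and Earth's surface
    area (5.1e14 m2).
    """

    sigma: float = 5.670374419e-8   # W m-2 K-4
    m_a: float = 5.15e21            # g, mass of the atmosphere
    Ma_over_Mc: float = 2.414       # molar mass air / molar mass carbon
    beta: float = 0.44              # airborne fraction
    chi0_ppm: float = 399.4         # baseline CO2 mole fraction, ppm
    rf_coeff: float = 5.35          # W m-2, CO2 forcing coefficient
    A_earth: float = 5.1e14         # m2
    Cp: float = 1004.834            # J kg-1 K-1, specific heat of air
    Rd: float = 287.058             # J kg-1 K-1, gas constant of dry air
    S0: float = 1361.0              # W m-2, solar constant
    mol_mass_C: float = 12.011      # g mol-1
    mol_mass_CO2: float = 44.009    # g mol-1

    def latent_heat(self, tair_c):
        """Latent heat of vaporization (J kg-1) at air temperature (degC)."""
        return (2.501 - 0.00237 * np.asarray(tair_c, dtype=float)) * 1e6

    def __post_init__(self):
        for k, v in asdict(self).items():
            if v <= 0:
                raise ValueError(f"constant {k} must be positive, got {v}")


CONSTANTS = PhysicalConstants()


@dataclass
class SiteMeta:
    site_id: str
    latitude: float = 39.94
    longitude: float = -5.77
    canopy_fraction: float = 0.2
    treatment_start: str = "2014-03-01"
    A_site: float = 1.0  # m2; 1.0 gives per-m2-of-surface forcing

    def __post_init__(self):
        if not 0.0 <= self.canopy_fraction <= 1.0:
            raise ValueError("canopy_fraction must be in [0, 1]")
        if self.A_site <= 0:
            raise ValueError("A_site must be positive")


@dataclass
class AnalysisConfig:
    """Tunable thresholds of the filtering and analysis stages."""

    midday_start: str = "11:00"
    midday_end: str = "14:30"
    clear_sky_threshold: float = 0.7
    delta_ts_threshold: float = 2.0          # degC
    max_missing_night: float = 0.66
    max_missing_day: float = 0.66
    transmissivity: float = 0.75             # clear-sky atmospheric transmissivity
    swdr_floor: float = 50.0                 # W m-2, floor for albedo ratios
    min_albedo_days_per_month: int = 3
    dtw_normalization: str = "pathlen-minmax"
    alpha: float = 0.05                      # statistics significance level
    gwp_horizon_years: float = 100.0
    kernel_paths: dict = field(default_factory=dict)
    season_calendar_path: str | None = None

    def __post_init__(self):
        for name in ("clear_sky_threshold", "max_missing_night", "max_missing_day",
                     "transmissivity", "alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        for name in ("midday_start", "midday_end"):
            time.fromisoformat(getattr(self, name))  # raises on bad window

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Reading and writing
# ---------------------------------------------------------------------------

def _validate_timestamps(ts: pd.Series, origin: str) -> None:
    diffs = ts.diff().dropna()
    bad = diffs[diffs <= pd.Timedelta(0)]
    if len(bad):
        i = bad.index[0]
        raise ValueError(
            f"{origin}: timestamps not strictly increasing at row {i} "
            f"({ts.loc[i].isoformat()})"
        )
    offgrid = diffs[diffs != pd.Timedelta(minutes=30)]
    if len(offgrid):
        i = offgrid.index[0]
        raise ValueError(
            f"{origin}: timestamp spacing is not 30 min at row {i} "
            f"({ts.loc[i].isoformat()})"
        )


def read_halfhourly_csv(path, site_id: str, layer: str) -> pd.DataFrame:
    """Read one site x layer half-hourly CSV into the canonical frame.

    ``-9999`` and empty cells decode to NaN. Timestamps must parse and be
    strictly increasing on a 30-min grid; violations are hard errors naming
    the first offending row. Negative values in non-negative fields (SWDR,
    SWUR, precip, ustar) are nulled with a logged count.
    """
    path = Path(path)
    df = pd.read_csv(path, na_values=[str(int(MISSING_SENTINEL)), "-9999.0", ""],
                     float_precision="round_trip")
    if "timestamp" not in df.columns:
        raise ValueError(f"{path}: missing 'timestamp' column")
    try:
        ts = pd.to_datetime(df["timestamp"], format=TIMESTAMP_FORMAT)
    except (ValueError, TypeError):
        try:
            ts = pd.to_datetime(df["timestamp"])
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: unparseable timestamp: {exc}") from exc
    _validate_timestamps(ts, str(path))

    out = pd.DataFrame({"timestamp": ts, "site_id": site_id, "layer": layer})
    n_dropped = 0
    for col in NUMERIC_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce") if col in df.columns else np.nan
        out[col] = vals
    for col in _NONNEGATIVE:
        neg = out[col] < 0
        if neg.any():
            n_dropped += int(neg.sum())
            out.loc[neg, col] = np.nan
    log.info("read %s: %d rows, %d negative values nulled", path, len(out), n_dropped)
    return out[COLUMNS]


def write_halfhourly_csv(df: pd.DataFrame, path) -> None:
    """Write the canonical frame back to the on-disk dialect (lossless)."""
    out = df[COLUMNS].copy()
    out["timestamp"] = out["timestamp"].dt.strftime(TIMESTAMP_FORMAT)
    for col in NUMERIC_COLUMNS:
        out[col] = out[col].map(
            lambda v: "-9999" if pd.isna(v) else np.format_float_positional(
                float(v), trim="0")
        )
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Calendar helpers
# ---------------------------------------------------------------------------

def day_of(timestamps: pd.Series) -> pd.Series:
    """Calendar day owning each period-end timestamp.

    The half-hour ending at midnight belongs to the day it covers, so the
    day is taken at the interval midpoint (timestamp minus 15 min).
    """
    return (timestamps - pd.Timedelta(minutes=15)).dt.normalize()


def midday_mask(timestamps: pd.Series, config: AnalysisConfig) -> pd.Series:
    """True for half-hours whose midpoint falls inside the midday window."""
    mid = (timestamps - pd.Timedelta(minutes=15)).dt.time
    lo = time.fromisoformat(config.midday_start)
    hi = time.fromisoformat(config.midday_end)
    return (mid >= lo) & (mid <= hi)


class SeasonCalendar:
    """Ordered phenological-season transitions per site.

    Each (site, season, start_date) row opens a season that runs to the next
    transition (closed start, open end). Coverage ends at ``end_date``.
    """

    def __init__(self, table: pd.DataFrame, end_date):
        t = table.copy()
        t["start_date"] = pd.to_datetime(t["start_date"])
        t = t.sort_values(["site_id", "start_date"]).reset_index(drop=True)
        for site, grp in t.groupby("site_id"):
            if grp["start_date"].duplicated().any():
                raise ValueError(f"duplicate transition dates for site {site}")
        self.table = t
        self.end_date = pd.Timestamp(end_date)

    @classmethod
    def from_csv(cls, path, end_date) -> "SeasonCalendar":
        return cls(pd.read_csv(path), end_date)

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out["start_date"] = out["start_date"].dt.strftime("%Y-%m-%d")
        out.to_csv(path, index=False)

    def assign(self, dates: pd.Series, site_id: str) -> pd.Series:
        """Season label for each date; errors on dates outside coverage."""
        grp = self.table[self.table["site_id"] == site_id]
        if grp.empty:
            raise ValueError(f"calendar has no transitions for site {site_id}")
        starts = grp["start_date"].to_numpy()
        labels = grp["season"].to_numpy()
        d = pd.to_datetime(dates).to_numpy()
        lo, hi = starts[0], np.datetime64(self.end_date)
        uncovered = (d < lo) | (d >= hi)
        if uncovered.any():
            bad = pd.to_datetime(d[uncovered])
            raise ValueError(
                f"dates outside calendar coverage for {site_id}: "
                f"{bad.min().date()}..{bad.max().date()} "
                f"(covered {pd.Timestamp(lo).date()}..{self.end_date.date()})"
            )
        idx = np.searchsorted(starts, d, side="right") - 1
        return pd.Series(labels[idx], index=pd.Series(dates).index, dtype=object)


def uniform_calendar(sites, start_year: int, n_years: int) -> SeasonCalendar:
    """Mediterranean five-season calendar on fixed dates, per hydrological year.

    Hydrological year opens with autumn on 1 Oct; winter 1 Dec, spring 1 Mar,
    drydown 15 May, summer 1 Jul.
    """
    rows = []
    anchors = [("autumn", 10, 1), ("winter", 12, 1), ("spring", 3, 1),
               ("drydown", 5, 15), ("summer", 7, 1)]
    for site in sites:
        for y in range(start_year, start_year + n_years + 1):
            for season, month, dom in anchors:
                year = y if month >= 10 else y + 1
                rows.append((site, season, f"{year:04d}-{month:02d}-{dom:02d}"))
    table = pd.DataFrame(rows, columns=["site_id", "season", "start_date"])
    end = pd.Timestamp(f"{start_year + n_years:04d}-10-01")
    table = table[pd.to_datetime(table["start_date"]) <= end]
    return SeasonCalendar(table, end_date=end)


def assign_seasons(df: pd.DataFrame, calendar: SeasonCalendar) -> pd.DataFrame:
    """Tag every record with its phenological season (new ``season`` column)."""
    out = df.copy()
    out["season"] = pd.Series(index=out.index, dtype=object)
    days = day_of(out["timestamp"])
    for site, idx in out.groupby("site_id").groups.items():
        out.loc[idx, "season"] = calendar.assign(days.loc[idx], site).to_numpy()
    return out


# ---------------------------------------------------------------------------
# Daily aggregation
# ---------------------------------------------------------------------------

def resample_daily(df: pd.DataFrame, variable: str, aggregator: str,
                   min_valid_fraction: float = 0.5,
                   config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Aggregate one variable to daily values per (site, layer).

    aggregator is one of ``mean``, ``sum`` or ``midday-mean``. Days whose
    valid-sample fraction (against 48 half-hours, or the midday window
    length for midday-mean) falls below ``min_valid_fraction`` yield NaN.
    Sums use available values only and carry a ``complete`` flag.
    """
    if aggregator not in ("mean", "sum", "midday-mean"):
        raise ValueError(f"unknown aggregator {aggregator!r}")
    config = config or AnalysisConfig()
    sub = df.copy()
    if aggregator == "midday-mean":
        sub = sub[midday_mask(sub["timestamp"], config)]
        lo = time.fromisoformat(config.midday_start)
        hi = time.fromisoformat(config.midday_end)
        expected = int(((hi.hour * 60 + hi.minute) - (lo.hour * 60 + lo.minute)) // 30)
    else:
        expected = 48
    sub["date"] = day_of(sub["timestamp"])
    rows = []
    for (site, layer, date), grp in sub.groupby(["site_id", "layer", "date"]):
        vals = grp[variable]
        n_valid = int(vals.notna().sum())
        frac = n_valid / expected
        if aggregator == "sum":
            value = vals.sum(min_count=1)
        else:
            value = vals.mean()
        if frac < min_valid_fraction:
            value = np.nan
        rows.append((site, layer, date, value, n_valid, frac >= min_valid_fraction
                     and n_valid == expected))
    return pd.DataFrame(rows, columns=["site_id", "layer", "date", variable,
                                       "n_valid", "complete"])
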