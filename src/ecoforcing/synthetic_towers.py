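"""Synthetic dual-layer flux-tower generator with known injected effects.

Emulates three co-located sites (control CT, N-added NT, N+P-added NPT),
each observed by an ecosystem-scale and an understory eddy-covariance /
radiometric system, at half-hourly resolution over a Mediterranean
five-season phenological cycle. Treatment effects (albedo offset, NEE
offset, latent/sensible repartition, surface-temperature offset) are
injected with known magnitudes so every downstream stage has a ground
truth to recover.

Construction principles:

* Weather (solar forcing, clouds, rain, air temperature) is drawn once per
  day and shared across sites, so between-site differences carry only the
  injected effects plus site-specific noise.
* Shortwave down is transmissivity x potential radiation; outgoing
  shortwave is albedo x SWDR; outgoing longwave follows the
  Stefan-Boltzmann law with emissivity tied to albedo (eps = -0.16 a + 0.99).
* The surface energy budget closes to a per-layer turbulent closure
  fraction, LE + H = closure * (Rn - G) at every half-hour before noise
  (full closure Rn = LE + H + G when the fraction is 1), mirroring the
  systematically lower closure of understory systems.
* NEE is a rectangular-hyperbola light response plus respiration; the
  treatment NEE offset is constant in time so its monthly cumulative sum
  is known exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .tower_io import (
    CONSTANTS, COLUMNS, LAYERS, SITES,
    SeasonCalendar, uniform_calendar, write_halfhourly_csv,
)

# ---------------------------------------------------------------------------
# Solar geometry
# ---------------------------------------------------------------------------

def potential_radiation(latitude, day_of_year, hour):
    """Top-of-atmosphere potential shortwave (W m-2) at local solar time.

    S0 * max(0, cos(zenith)) from standard solar-position geometry
    (declination via the 23.45 deg sine approximation, hour angle
    15 deg h-1 around solar noon). Total function: 0 whenever the sun is
    below the horizon.
    """
    lat = np.deg2rad(np.asarray(latitude, dtype=float))
    doy = np.asarray(day_of_year, dtype=float)
    h = np.asarray(hour, dtype=float)
    decl = np.deg2rad(23.45) * np.sin(2.0 * np.pi * (284.0 + doy) / 365.0)
    hour_angle = np.deg2rad(15.0 * (h - 12.0))
    cos_zen = (np.sin(lat) * np.sin(decl)
               + np.cos(lat) * np.cos(decl) * np.cos(hour_angle))
    return CONSTANTS.S0 * np.maximum(0.0, cos_zen)


# ---------------------------------------------------------------------------
# Scenario specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TreatmentEffect:
    """Injected treatment-minus-control offsets for one site x layer."""

    delta_albedo: float = 0.0     # unitless
    delta_nee: float = 0.0        # g C m-2 d-1 (negative = extra uptake)
    delta_ef: float = 0.0         # shift of evaporative fraction
    delta_ts: float = 0.0         # degC surface-temperature offset


def _default_treatments():
    # Mirrors the reported treatment responses: ecosystem albedo offsets
    # +0.015 (NT) / +0.013 (NPT), understory +0.017 / +0.015; small extra
    # CO2 uptake; LE/H repartition toward LE at NT (ecosystem) and NPT
    # (understory); ecosystem-scale cooling at NT and understory warming.
    return {
        ("NT", "ecosystem"): TreatmentEffect(0.015, -0.20, 0.05, -0.41),
        ("NPT", "ecosystem"): TreatmentEffect(0.013, -0.15, 0.02, 0.03),
        ("NT", "understory"): TreatmentEffect(0.017, -0.10, 0.02, 0.63),
        ("NPT", "understory"): TreatmentEffect(0.015, -0.15, 0.05, 0.80),
    }


@dataclass
class ScenarioSpec:
    """Everything the generator needs, with study-condition defaults."""

    seed: int = 0
    start: str = "2021-10-01"         # hydrological-year start (autumn)
    n_years: int = 2
    latitude: float = 39.94
    transmissivity: float = 0.75

    # per-season baselines (five Mediterranean phenological seasons)
    tair_base: dict = field(default_factory=lambda: {
        "autumn": 16.0, "winter": 9.0, "spring": 15.0,
        "drydown": 22.0, "summer": 27.0})
    albedo_base: dict = field(default_factory=lambda: {
        "autumn": 0.19, "winter": 0.18, "spring": 0.17,
        "drydown": 0.20, "summer": 0.22})
    gpp_max: dict = field(default_factory=lambda: {      # umol m-2 s-1
        "autumn": 6.0, "winter": 5.0, "spring": 12.0,
        "drydown": 6.0, "summer": 1.5})
    reco_base: dict = field(default_factory=lambda: {    # umol m-2 s-1
        "autumn": 2.0, "winter": 1.5, "spring": 3.0,
        "drydown": 2.5, "summer": 1.0})
    ef_base: dict = field(default_factory=lambda: {      # LE/(LE+H) of turbulent
        "autumn": 0.50, "winter": 0.55, "spring": 0.60,
        "drydown": 0.35, "summer": 0.20})
    vpd_midday: dict = field(default_factory=lambda: {   # kPa
        "autumn": 0.8, "winter": 0.4, "spring": 1.0,
        "drydown": 2.0, "summer": 3.0})

    # layer-level structure
    closure: dict = field(default_factory=lambda: {
        "ecosystem": 0.88, "understory": 0.60})
    u_base: dict = field(default_factory=lambda: {
        "ecosystem": 2.0, "understory": 1.0})
    ustar_base: dict = field(default_factory=lambda: {
        "ecosystem": 0.30, "understory": 0.15})
    understory_flux_scale: float = 0.6   # grass-layer share of CO2 fluxes
    soil_heat_fraction: float = 0.15     # share of available energy into G
    canopy_fraction: float = 0.2

    treatments: dict = field(default_factory=_default_treatments)

    # stochastic structure (weather shared across sites; noise per site)
    noise_sd: dict = field(default_factory=lambda: {
        "NEE": 0.8, "LE": 6.0, "H": 6.0, "albedo": 0.006,
        "LWDR": 4.0, "Tair": 0.3})
    gap_fraction: float = 0.05
    rain_day_freq: float = 0.08          # fraction of days with rain
    rain_depth_mm: float = 6.0           # mean daily depth on rain days
    cloudy_day_freq: float = 0.15        # non-rain days with reduced SWDR

    pressure_kpa: float = 97.0
    tair_amplitude: float = 5.0          # diurnal half-range, degC

    def __post_init__(self):
        for layer, c in self.closure.items():
            if not 0.0 < c <= 1.0:
                raise ValueError(f"closure[{layer}] must be in (0, 1]")
        if not 0.0 <= self.gap_fraction < 1.0:
            raise ValueError("gap_fraction must be in [0, 1)")
        for key, eff in self.treatments.items():
            for s, base in self.albedo_base.items():
                a = base + eff.delta_albedo
                if not 0.0 < a < 1.0:
                    raise ValueError(f"albedo out of (0,1) for {key}, {s}")

    def zero_noise(self, closure: float | None = None) -> "ScenarioSpec":
        """Copy with all stochastic structure switched off."""
        kw = asdict(self)
        kw["treatments"] = dict(self.treatments)
        kw["noise_sd"] = {k: 0.0 for k in self.noise_sd}
        kw["gap_fraction"] = 0.0
        kw["rain_day_freq"] = 0.0
        kw["cloudy_day_freq"] = 0.0
        if closure is not None:
            kw["closure"] = {layer: closure for layer in self.closure}
        return ScenarioSpec(**kw)


def truth_table(scenario: ScenarioSpec) -> pd.DataFrame:
    """Exact injected effects per site x layer, for recovery tests."""
    rows = []
    for site in SITES:
        for layer in LAYERS:
            eff = scenario.treatments.get((site, layer), TreatmentEffect())
            rows.append({
                "site_id": site, "layer": layer,
                "delta_albedo": eff.delta_albedo,
                "delta_nee_gc_per_day": eff.delta_nee,
                "delta_ef": eff.delta_ef,
                "delta_ts_degc": eff.delta_ts,
                "closure": scenario.closure[layer],
            })
    return pd.DataFrame(rows)


def calendar_for(scenario: ScenarioSpec) -> SeasonCalendar:
    start_year = pd.Timestamp(scenario.start).year
    return uniform_calendar(SITES, start_year, scenario.n_years)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

#: umol CO2 m-2 s-1 equivalent of 1 g C m-2 d-1 (constant-rate conversion)
UMOL_PER_GC_DAY = 1e6 / CONSTANTS.mol_mass_C / 86400.0


def generate_halfhourly(scenario: ScenarioSpec) -> pd.DataFrame:
    """Generate the full 3-site x 2-layer half-hourly record.

    Deterministic given ``scenario.seed``; the control site carries the
    seasonal baselines and treated sites add the injected offsets. With
    zero noise the turbulent-closure identity LE + H = closure * (Rn - G)
    holds at every half-hour by construction.
    """
    start = pd.Timestamp(scenario.start)
    end = start + pd.DateOffset(years=scenario.n_years)
    n_days = (end - start).days
    # period-end timestamps: first half-hour ends 00:30, last at 00:00 of end
    ts = pd.date_range(start + pd.Timedelta(minutes=30), end, freq="30min")
    n = len(ts)

    mid = ts - pd.Timedelta(minutes=15)
    day_index = np.repeat(np.arange(n_days), 48)
    doy = mid.dayofyear.to_numpy()
    hour = mid.hour.to_numpy() + mid.minute.to_numpy() / 60.0

    calendar = calendar_for(scenario)
    days = pd.date_range(start, periods=n_days, freq="D")
    season_daily = calendar.assign(pd.Series(days), "CT").to_numpy()
    season = season_daily[day_index]

    def per_season(mapping):
        return np.array([mapping[s] for s in season])

    sw_pot = potential_radiation(scenario.latitude, doy, hour)
    daylight = sw_pot > 0

    # --- shared daily weather -------------------------------------------
    wrng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 0]))
    rain_day = wrng.random(n_days) < scenario.rain_day_freq
    cloudy_day = (~rain_day) & (wrng.random(n_days) < scenario.cloudy_day_freq)
    sky_factor = np.ones(n_days)
    sky_factor[rain_day] = 0.25
    sky_factor[cloudy_day] = wrng.uniform(0.3, 0.65, int(cloudy_day.sum()))
    rain_depth = np.where(
        rain_day, wrng.gamma(2.0, scenario.rain_depth_mm / 2.0, n_days), 0.0)
    tair_day_anom = wrng.normal(0.0, 1.5, n_days)

    swdr = scenario.transmissivity * sw_pot * sky_factor[day_index]
    tair_shared = (per_season(scenario.tair_base)
                   + tair_day_anom[day_index]
                   - scenario.tair_amplitude
                   * np.cos(2 * np.pi * (hour - 14.0) / 24.0))
    precip = np.zeros(n)
    rain_slots = (hour >= 18.0) & (hour < 20.0)
    for d in np.flatnonzero(rain_day):
        sel = (day_index == d) & rain_slots
        precip[sel] = rain_depth[d] / max(1, int(sel.sum()))

    vpd_shared = per_season(scenario.vpd_midday) * np.clip(
        0.25 + 0.75 * sw_pot / CONSTANTS.S0, 0.25, None)

    frames = []
    for site in SITES:
        for layer in LAYERS:
            eff = scenario.treatments.get((site, layer), TreatmentEffect())
            srng = np.random.default_rng(np.random.SeedSequence(
                [scenario.seed, 1 + SITES.index(site), LAYERS.index(layer)]))

            def noise(name, srng=srng):
                sd = scenario.noise_sd.get(name, 0.0)
                return srng.normal(0.0, sd, n) if sd > 0 else np.zeros(n)

            albedo = np.clip(per_season(scenario.albedo_base)
                             + eff.delta_albedo + noise("albedo"),
                             1e-3, 0.999)
            swur = albedo * swdr
            tair = tair_shared + noise("Tair")

            ts_surf = (tair + 1.0 + 8.0 * sw_pot / CONSTANTS.S0
                       + eff.delta_ts)
            eps = -0.16 * albedo + 0.99
            lwur = CONSTANTS.sigma * eps * (ts_surf + 273.15) ** 4
            lwdr = (0.80 * CONSTANTS.sigma * (tair + 273.15) ** 4
                    + noise("LWDR"))

            rn = swdr - swur + lwdr - lwur
            # soil heat flux is measured directly; the closure fraction is
            # the turbulent-flux closure LE + H = closure * (Rn - G), so at
            # closure 1.0 the full budget Rn = LE + H + G closes exactly
            g_total = scenario.soil_heat_fraction * rn
            turbulent = scenario.closure[layer] * (rn - g_total)
            ef = np.clip(per_season(scenario.ef_base) + eff.delta_ef,
                         0.02, 0.98)
            n_le = noise("LE")
            le = ef * turbulent + n_le
            h = (1.0 - ef) * turbulent - n_le + noise("H")

            if layer == "ecosystem":
                f = scenario.canopy_fraction
                # below-canopy plates see damped flux; open plates chosen so
                # the canopy-fraction-weighted mean recovers g_total exactly
                g_open = g_total / (1.0 - 0.5 * f)
                g_canopy = 0.5 * g_open
            else:
                g_open = g_total
                g_canopy = np.full(n, np.nan)

            scale = (1.0 if layer == "ecosystem"
                     else scenario.understory_flux_scale)
            gpp = (per_season(scenario.gpp_max) * scale
                   * swdr / (swdr + 250.0)
                   - eff.delta_nee * UMOL_PER_GC_DAY)
            reco = per_season(scenario.reco_base) * scale * np.ones(n)
            nee = reco - gpp + noise("NEE")

            shape = 0.75 + 0.5 * sw_pot / CONSTANTS.S0
            u = scenario.u_base[layer] * shape
            ustar = scenario.ustar_base[layer] * shape

            df = pd.DataFrame({
                "timestamp": ts, "site_id": site, "layer": layer,
                "NEE": nee, "GPP": gpp, "Reco": reco,
                "LE": le, "H": h,
                "G_open": g_open, "G_canopy": g_canopy,
                "SWDR": swdr, "SWUR": swur, "LWDR": lwdr, "LWUR": lwur,
                "Tair": tair, "VPD": vpd_shared,
                "pressure": scenario.pressure_kpa,
                "precip": precip, "u": u, "ustar": ustar,
                "qc_nee": 0.0,
            })

            if scenario.gap_fraction > 0:
                flux_gap = srng.random(n) < scenario.gap_fraction
                rad_gap = srng.random(n) < scenario.gap_fraction / 2.0
                g_gap = srng.random(n) < scenario.gap_fraction / 2.0
                df.loc[flux_gap, ["NEE", "GPP", "Reco", "LE", "H"]] = np.nan
                df.loc[rad_gap, ["SWDR", "SWUR", "LWDR", "LWUR"]] = np.nan
                df.loc[g_gap, ["G_open", "G_canopy"]] = np.nan

            frames.append(df[COLUMNS])

    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Scenario I/O
# ---------------------------------------------------------------------------

def scenario_from_yaml(path) -> ScenarioSpec:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "treatments" in raw:
        raw["treatments"] = {
            (t["site_id"], t["layer"]): TreatmentEffect(
                t.get("delta_albedo", 0.0), t.get("delta_nee", 0.0),
                t.get("delta_ef", 0.0), t.get("delta_ts", 0.0))
            for t in raw["treatments"]
        }
    return ScenarioSpec(**raw)


def scenario_to_yaml(scenario: ScenarioSpec, path) -> None:
    raw = asdict(scenario)
    raw["treatments"] = [
        {"site_id": site, "layer": layer, **asdict(eff)}
        for (site, layer), eff in scenario.treatments.items()
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


def write_scenario(scenario: ScenarioSpec, outdir) -> dict:
    """Write per-site/layer CSVs, the season calendar and the truth table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = generate_halfhourly(scenario)
    paths = {}
    for (site, layer), grp in records.groupby(["site_id", "layer"]):
        p = outdir / f"{site}_{layer}.csv"
        write_halfhourly_csv(grp.reset_index(drop=True), p)
        paths[(site, layer)] = p
    calendar_for(scenario).to_csv(outdir / "season_calendar.csv")
    with open(outdir / "truth_table.yaml", "w") as fh:
        yaml.safe_dump(truth_table(scenario).to_dict(orient="records"), fh,
                       sort_keys=False)
    return paths
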