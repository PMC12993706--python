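"""End-to-end orchestration of the multiscale forcing/temperature analysis.

Stages, in the order the method runs: quality filtering (midday clear-sky
albedo, rain and missingness day flags, soil-heat-flux combination),
monthly radiative forcing per site pair, daily surface-temperature
decomposition with the sign/2-degC agreement filter, daily
ecophysiological diagnostics, and the DTW attribution plus seasonal
between-site tests. All stages exchange tidy DataFrames and can be run
individually; ``run_pipeline`` wires them together and ``write_outputs``
serializes each stage's table to CSV.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import qc_filters, radiative_forcing, ts_decomposition
from . import attribution_stats, ecophysiology
from .tower_io import (
    CONSTANTS, AnalysisConfig, SeasonCalendar, day_of,
)

log = logging.getLogger("ecoforcing")

SITE_PAIRS = (("NT", "CT"), ("NPT", "CT"))

#: g C per (umol CO2 m-2 s-1 sustained for one half-hour)
GC_PER_UMOL_HH = 1800.0 * CONSTANTS.mol_mass_C * 1e-6


def _prepare(records: pd.DataFrame, canopy_fraction: float,
             latitude: float) -> pd.DataFrame:
    """Attach combined G, net radiation, date and solar position."""
    d = qc_filters._with_solar(records, latitude)
    eco = d["layer"] == "ecosystem"
    d["G"] = np.where(
        eco,
        qc_filters.combine_soil_heat_flux(
            d["G_open"], d["G_canopy"], canopy_fraction),
        d["G_open"])
    d["Rn"] = d["SWDR"] - d["SWUR"] + d["LWDR"] - d["LWUR"]
    return d


def _daily_means(d: pd.DataFrame, variables, daytime_only: bool = False,
                 min_valid: int = 1) -> pd.DataFrame:
    sub = d[d["sw_pot"] > 0] if daytime_only else d
    g = sub.groupby(["site_id", "layer", "date"])[list(variables)]
    means = g.mean()
    counts = g.count()
    return means.where(counts >= min_valid)


def daily_tables(records: pd.DataFrame, config: AnalysisConfig,
                 canopy_fraction: float = 0.2,
                 latitude: float = 39.94) -> dict:
    """Daily QC products shared by the downstream stages."""
    d = _prepare(records, canopy_fraction, latitude)
    albedo = qc_filters.midday_albedo_daily(d, config, latitude)
    flags = qc_filters.day_flags(d, config, latitude)

    budget_vars = ["SWDR", "SWUR", "LWDR", "LWUR", "LE", "H", "G", "Rn",
                   "Tair"]
    daily24 = _daily_means(d, budget_vars, min_valid=16)
    daytime = _daily_means(
        d, ["LE", "H", "Rn", "G", "VPD", "Tair", "pressure", "u", "ustar"],
        daytime_only=True, min_valid=8)
    carbon = _daily_means(d, ["NEE", "GPP"], min_valid=16) * (
        86400.0 * CONSTANTS.mol_mass_C * 1e-6)  # mean rate -> g C m-2 d-1
    carbon.columns = ["NEE_gc", "GPP_gc"]

    # attach daily albedo; fill gaps with the site's month mean (logged)
    alb = albedo.set_index(["site_id", "layer", "date"])["albedo"]
    daily24 = daily24.join(alb)
    month = daily24.index.get_level_values("date").to_period("M")
    month_mean = daily24.groupby(
        [daily24.index.get_level_values("site_id"),
         daily24.index.get_level_values("layer"), month])["albedo"].transform("mean")
    n_fill = int((daily24["albedo"].isna() & month_mean.notna()).sum())
    if n_fill:
        log.info("daily_tables: %d day(s) use month-mean albedo", n_fill)
    daily24["albedo"] = daily24["albedo"].fillna(month_mean)

    return {"halfhourly": d, "daily_albedo": albedo, "day_flags": flags,
            "daily24": daily24, "daytime": daytime, "carbon": carbon}


def monthly_deltas(tables: dict, config: AnalysisConfig, treated: str,
                   control: str, layer: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Monthly albedo difference and monthly NEE difference for one pair."""
    alb = tables["daily_albedo"].set_index(["site_id", "layer", "date"])["albedo"]
    try:
        a_t = alb.loc[treated, layer]
        a_c = alb.loc[control, layer]
    except KeyError:
        a_t = pd.Series(dtype=float)
        a_c = pd.Series(dtype=float)
    dalb = (a_t - a_c).dropna()
    month = dalb.index.to_period("M")
    grp = dalb.groupby(month)
    monthly_alpha = grp.mean().where(grp.count() >= config.min_albedo_days_per_month)
    monthly_alpha = monthly_alpha.dropna()
    ma = pd.DataFrame({
        "month_start": monthly_alpha.index.to_timestamp(),
        "delta_alpha": monthly_alpha.to_numpy()})

    nee = tables["carbon"]["NEE_gc"]
    n_t = nee.loc[treated, layer]
    n_c = nee.loc[control, layer]
    dnee = (n_t - n_c).dropna()
    month = dnee.index.to_period("M")
    # mean daily difference scaled to the month length (gap-robust)
    mgrp = dnee.groupby(month)
    monthly_nee = mgrp.mean() * month.drop_duplicates().days_in_month.to_numpy()
    mn = pd.DataFrame({
        "month_start": monthly_nee.index.to_timestamp(),
        "delta_nee": monthly_nee.to_numpy()})
    return ma, mn


def rf_stage(tables: dict, config: AnalysisConfig,
             kernels: list, a_site: float = 1.0) -> pd.DataFrame:
    """Monthly forcing records for every site pair x layer."""
    frames = []
    for treated, control in SITE_PAIRS:
        for layer in ("ecosystem", "understory"):
            ma, mn = monthly_deltas(tables, config, treated, control, layer)
            if ma.empty and mn.empty:
                continue
            rf = radiative_forcing.monthly_rf_table(ma, mn, kernels, a_site)
            rf.insert(0, "site_pair", f"{treated}-{control}")
            rf.insert(1, "layer", layer)
            frames.append(rf)
    return pd.concat(frames, ignore_index=True)


def decomposition_stage(tables: dict, config: AnalysisConfig,
                        calendar: SeasonCalendar) -> pd.DataFrame:
    """Daily dTs decomposition with agreement filtering, all pairs/layers."""
    daily = tables["daily24"]
    flags = tables["day_flags"].set_index(["site_id", "layer", "date"])
    frames = []
    for treated, control in SITE_PAIRS:
        for layer in ("ecosystem", "understory"):
            try:
                c = daily.loc[control, layer]
                t = daily.loc[treated, layer]
            except KeyError:
                continue
            dec = ts_decomposition.decompose_delta_ts(c, t)
            if dec.empty:
                continue
            # both sites must pass the rain/missingness day filter
            ok_c = flags["passes_missingness"].reindex(
                [(control, layer, d) for d in dec.index]).to_numpy()
            ok_t = flags["passes_missingness"].reindex(
                [(treated, layer, d) for d in dec.index]).to_numpy()
            dec = dec[(ok_c == True) & (ok_t == True)]  # noqa: E712
            dec = dec.reset_index().rename(columns={"index": "date"})
            dec["kept"] = qc_filters.delta_ts_agreement(
                dec["dTs_obs"], dec["dTs_cal"], config.delta_ts_threshold)
            dec.insert(0, "site_pair", f"{treated}-{control}")
            dec.insert(1, "layer", layer)
            dec["season"] = calendar.assign(dec["date"], control)
            frames.append(dec)
    return pd.concat(frames, ignore_index=True)


def ecophys_stage(tables: dict, calendar: SeasonCalendar) -> pd.DataFrame:
    """Daily ecophysiology per site x layer, season-tagged."""
    daytime = tables["daytime"]
    carbon = tables["carbon"]
    daily24 = tables["daily24"]
    frames = []
    for (site, layer), grp in daytime.groupby(["site_id", "layer"]):
        grp = grp.droplevel(["site_id", "layer"])
        gpp = carbon["GPP_gc"].loc[site, layer].reindex(grp.index)
        tair = daily24["Tair"].loc[site, layer].reindex(grp.index)
        le24 = daily24["LE"].loc[site, layer].reindex(grp.index)
        eco = ecophysiology.ecophys_daily(grp, gpp, tair, le_daily_24h=le24)
        eco = eco.reset_index().rename(columns={"index": "date"})
        eco.insert(0, "site_id", site)
        eco.insert(1, "layer", layer)
        eco["season"] = calendar.assign(eco["date"], site)
        frames.append(eco)
    return pd.concat(frames, ignore_index=True)


def stats_stage(tables: dict, decomp: pd.DataFrame, ecophys: pd.DataFrame,
                calendar: SeasonCalendar, config: AnalysisConfig) -> dict:
    """DTW component ranking plus seasonal between-site tests."""
    kept = decomp[decomp["kept"]]
    dtw_report = attribution_stats.normalized_component_ranking(kept)

    daily = tables["daily24"].reset_index()
    daily["season"] = pd.Series(dtype=object)
    for site, idx in daily.groupby("site_id").groups.items():
        daily.loc[idx, "season"] = calendar.assign(
            daily.loc[idx, "date"], site).to_numpy()
    carbon = tables["carbon"].reset_index()
    daily = daily.merge(carbon, on=["site_id", "layer", "date"], how="left")
    seasonal = attribution_stats.seasonal_tests_table(
        daily, ["NEE_gc", "albedo", "LE", "H", "G"], alpha=config.alpha)
    eco_tests = attribution_stats.seasonal_tests_table(
        ecophys, ["WUE", "Ga", "Gs", "Omega", "EF"], alpha=config.alpha)
    return {"dtw_report": dtw_report,
            "seasonal_tests": pd.concat([seasonal, eco_tests],
                                        ignore_index=True)}


def run_pipeline(records: pd.DataFrame, config: AnalysisConfig,
                 calendar: SeasonCalendar, kernels: list,
                 canopy_fraction: float = 0.2,
                 latitude: float = 39.94) -> dict:
    """Run every stage; returns a dict of stage-output DataFrames."""
    tables = daily_tables(records, config, canopy_fraction, latitude)
    out = {
        "daily_albedo": tables["daily_albedo"],
        "day_flags": tables["day_flags"],
        "monthly_rf": rf_stage(tables, config, kernels),
        "decomposition_daily": decomposition_stage(tables, config, calendar),
    }
    out["ecophys_daily"] = ecophys_stage(tables, calendar)
    stats_out = stats_stage(tables, out["decomposition_daily"],
                            out["ecophys_daily"], calendar, config)
    out.update(stats_out)

    closures = []
    for (site, layer), grp in tables["daily24"].groupby(["site_id", "layer"]):
        try:
            res = qc_filters.energy_balance_closure(
                grp.droplevel(["site_id", "layer"]))
        except ValueError:
            continue
        closures.append({"site_id": site, "layer": layer, **res})
    out["closure"] = pd.DataFrame(closures)
    out["_tables"] = tables
    return out


def write_outputs(results: dict, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, table in results.items():
        if name.startswith("_") or not isinstance(table, pd.DataFrame):
            continue
        table.to_csv(outdir / f"{name}.csv", index=False)
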