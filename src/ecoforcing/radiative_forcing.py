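"""Top-of-atmosphere radiative forcing from albedo and CO2-flux changes.

The monthly forcing of a treated site relative to control combines two
terms, both expressed per m2 of treated surface (reported in units of
1e-14 W m-2 (global) m-2 (surface)):

* the albedo term, the month's mean albedo difference propagated to TOA
  through an ensemble of monthly albedo radiative kernels,
  RF_da = -K * d_alpha * A_site / A_earth;
* the CO2 term, the cumulative NEE difference since treatment start
  converted to a global CO2 mole-fraction perturbation (weighted by the
  airborne fraction) and then to forcing through the standard 5.35 W m-2
  logarithmic CO2 expression, linearized for small perturbations.

A global-warming-potential hook converts an annual-mean albedo forcing
into the sustained CO2-equivalent emission (kg CO2e ha-1 yr-1) whose own
forcing chain matches it at the chosen horizon.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tower_io import CONSTANTS, PhysicalConstants

log = logging.getLogger("ecoforcing")

KERNEL_MODELS = ("CAM5", "HadGEM2", "HadGEM3", "CACK")

#: reporting scale of all RF values (the customary 1e-14 W m-2 m-2)
RF_SCALE = 1e-14


@dataclass
class KernelSeries:
    """Monthly TOA albedo-kernel climatology for one model at the site.

    Values are W m-2 at TOA per unit increase of local surface albedo
    (normalized from per-0.01 files on ingestion), January..December.
    """

    model: str
    values: np.ndarray  # 12 monthly values, per unit albedo

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (12,):
            raise ValueError("kernel needs exactly 12 monthly values")
        if np.isnan(self.values).any():
            raise ValueError(f"kernel {self.model} has missing months")

    @classmethod
    def from_csv(cls, path, model: str) -> "KernelSeries":
        """Read the 12-row CSV fallback: columns month, value, units.

        ``units`` is 'per_unit' or 'per_0.01'; per-0.01 kernels are
        multiplied by 100 to the per-unit convention.
        """
        df = pd.read_csv(path)
        df = df.sort_values("month")
        if list(df["month"]) != list(range(1, 13)):
            raise ValueError(f"{path}: months 1..12 required")
        vals = df["value"].to_numpy(dtype=float)
        units = df["units"].iloc[0] if "units" in df.columns else "per_unit"
        if units == "per_0.01":
            vals = vals * 100.0
        elif units != "per_unit":
            raise ValueError(f"{path}: unknown kernel units {units!r}")
        return cls(model=model, values=vals)


def kernel_ensemble(kernels: list[KernelSeries]) -> pd.DataFrame:
    """Monthly ensemble mean and across-model SD of albedo kernels."""
    mat = np.vstack([k.values for k in kernels])
    return pd.DataFrame({
        "month": np.arange(1, 13),
        "K_mean": mat.mean(axis=0),
        "K_sd": mat.std(axis=0, ddof=1) if len(kernels) > 1 else 0.0,
    })


def synthetic_kernel_ensemble(seed: int = 0) -> list[KernelSeries]:
    """Synthetic stand-in for the four public albedo-kernel climatologies.

    Follows the characteristic mid-latitude annual cycle (winter minimum,
    summer maximum of TOA sensitivity to surface albedo, order 100 W m-2
    per unit albedo) with small between-model spread. It is a synthetic
    construction, not data from the published kernel files.
    """
    rng = np.random.default_rng(seed)
    month = np.arange(12)
    base = 110.0 - 55.0 * np.cos(2.0 * np.pi * (month - 0.5) / 12.0)
    out = []
    for model in KERNEL_MODELS:
        spread = rng.normal(1.0, 0.06) * base + rng.normal(0.0, 4.0, 12)
        out.append(KernelSeries(model=model, values=spread))
    return out


# ---------------------------------------------------------------------------
# CO2 term
# ---------------------------------------------------------------------------

def cumulative_delta_chi(delta_nee_cum_gc, a_site: float = 1.0,
                         constants: PhysicalConstants = CONSTANTS):
    """Global CO2 mole-fraction change from cumulative NEE difference.

    d_chi = beta * dNEE_cum * A_site * (Ma/Mc) / m_a, dimensionless mole
    fraction; ``delta_nee_cum_gc`` is the cumulative treated-minus-control
    NEE in g C m-2 since treatment start.
    """
    dnee = np.asarray(delta_nee_cum_gc, dtype=float)
    return (constants.beta * dnee * a_site * constants.Ma_over_Mc
            / constants.m_a)


def rf_delta_nee(delta_chi, constants: PhysicalConstants = CONSTANTS,
                 form: str = "linear"):
    """CO2 forcing per m2 of treated surface from a mole-fraction change.

    linear: RF = 5.35 * d_chi / chi0; log: RF = 5.35 * ln(1 + d_chi/chi0)
    (the exact form, exposed for validation). Negative = cooling. Warns
    when |d_chi|/chi0 > 0.01, where the linearization becomes dubious.
    """
    dchi = np.asarray(delta_chi, dtype=float)
    chi0 = constants.chi0_ppm * 1e-6
    rel = np.abs(dchi) / chi0
    if np.any(rel > 0.01):
        warnings.warn("rf_delta_nee: |d_chi|/chi0 > 0.01, linearization "
                      "dubious", stacklevel=2)
    if form == "linear":
        return constants.rf_coeff * dchi / chi0
    if form == "log":
        return constants.rf_coeff * np.log1p(dchi / chi0)
    raise ValueError(f"unknown form {form!r}")


# ---------------------------------------------------------------------------
# Albedo term
# ---------------------------------------------------------------------------

def rf_delta_alpha(delta_alpha, kernel_value, a_site: float = 1.0,
                   constants: PhysicalConstants = CONSTANTS):
    """Albedo forcing per m2 of treated surface.

    RF = -K * d_alpha * A_site / A_earth with K the (ensemble-mean) kernel
    for the month; brightening (positive d_alpha) with a positive kernel
    cools (negative RF).
    """
    return (-np.asarray(kernel_value, dtype=float)
            * np.asarray(delta_alpha, dtype=float)
            * a_site / constants.A_earth)


def combine_rf(rf_alpha: pd.Series, rf_nee_cum: pd.Series) -> pd.Series:
    """Total monthly forcing: current-month albedo term + cumulative CO2 term.

    Inputs must share an aligned monthly index.
    """
    if not rf_alpha.index.equals(rf_nee_cum.index):
        raise ValueError("combine_rf: misaligned monthly indices")
    return rf_alpha + rf_nee_cum


# ---------------------------------------------------------------------------
# Monthly pipeline
# ---------------------------------------------------------------------------

def monthly_rf_table(monthly_delta_alpha: pd.DataFrame,
                     monthly_delta_nee: pd.DataFrame,
                     kernels: list[KernelSeries],
                     a_site: float = 1.0,
                     constants: PhysicalConstants = CONSTANTS) -> pd.DataFrame:
    """Assemble the per-month forcing record for one site pair x layer.

    ``monthly_delta_alpha``: columns month_start (Timestamp), delta_alpha.
    ``monthly_delta_nee``: columns month_start, delta_nee (g C m-2 month-1).
    Months are aligned on their union; the CO2 term accumulates from the
    first month, treating missing monthly NEE differences as zero
    (logged). RF columns are reported on the 1e-14 scale.
    """
    ens = kernel_ensemble(kernels).set_index("month")
    a = monthly_delta_alpha.set_index("month_start").sort_index()
    c = monthly_delta_nee.set_index("month_start").sort_index()
    idx = a.index.union(c.index)
    n_missing = int(c["delta_nee"].reindex(idx).isna().sum())
    if n_missing:
        log.info("monthly_rf_table: %d month(s) without dNEE treated as 0",
                 n_missing)

    dnee = c["delta_nee"].reindex(idx).fillna(0.0)
    dnee_cum = dnee.cumsum()
    dchi = cumulative_delta_chi(dnee_cum.to_numpy(), a_site, constants)
    rf_nee_cum = rf_delta_nee(dchi, constants)

    months = idx.month
    k_mean = ens.loc[months, "K_mean"].to_numpy()
    k_sd = ens.loc[months, "K_sd"].to_numpy()
    dalpha = a["delta_alpha"].reindex(idx).to_numpy()
    rf_a = rf_delta_alpha(dalpha, k_mean, a_site, constants)
    rf_a_sd = np.abs(rf_delta_alpha(dalpha, k_sd, a_site, constants))

    out = pd.DataFrame({
        "month_start": idx,
        "month_index": np.arange(1, len(idx) + 1),
        "delta_alpha": dalpha,
        "delta_nee_monthly_gc": dnee.to_numpy(),
        "delta_nee_cum_gc": dnee_cum.to_numpy(),
        "rf_delta_alpha": rf_a / RF_SCALE,
        "rf_delta_nee_cum": rf_nee_cum / RF_SCALE,
        "kernel_spread_sd": rf_a_sd / RF_SCALE,
    })
    out["rf_total"] = combine_rf(out["rf_delta_alpha"],
                                 out["rf_delta_nee_cum"])
    return out


# ---------------------------------------------------------------------------
# GWP conversion of the albedo term
# ---------------------------------------------------------------------------

def gwp_delta_alpha(rf_alpha_annual_mean, horizon_years: float = 100.0,
                    constants: PhysicalConstants = CONSTANTS):
    """CO2-equivalent sustained emission of an annual-mean albedo forcing.

    Returns the emission rate (kg CO2e ha-1 yr-1) that, sustained over the
    horizon and weighted by the airborne fraction through the same
    mole-fraction/forcing chain as the CO2 term, accumulates to the given
    annual-mean albedo forcing (W m-2 of treated surface) at the horizon.
    Cooling (negative) forcing maps to a negative, avoided emission.
    """
    if horizon_years <= 0:
        raise ValueError("horizon_years must be positive")
    rf = np.asarray(rf_alpha_annual_mean, dtype=float)
    chi0 = constants.chi0_ppm * 1e-6
    # forcing per cumulative g C m-2: k = 5.35 * beta * (Ma/Mc) / (m_a chi0)
    k = (constants.rf_coeff * constants.beta * constants.Ma_over_Mc
         / (constants.m_a * chi0))
    rate_gc_m2_yr = rf / (k * horizon_years)
    # g C m-2 yr-1 -> kg CO2 ha-1 yr-1
    return (rate_gc_m2_yr * constants.mol_mass_CO2 / constants.mol_mass_C
            * 1e4 / 1e3)


def rf_from_sustained_emission(co2e_kg_ha_yr, horizon_years: float = 100.0,
                               constants: PhysicalConstants = CONSTANTS):
    """Forward chain of gwp_delta_alpha, for round-trip validation."""
    rate_gc = (np.asarray(co2e_kg_ha_yr, dtype=float) * 1e3 / 1e4
               * constants.mol_mass_C / constants.mol_mass_CO2)
    cum_gc = rate_gc * horizon_years
    return rf_delta_nee(cumulative_delta_chi(cum_gc, 1.0, constants),
                        constants)
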