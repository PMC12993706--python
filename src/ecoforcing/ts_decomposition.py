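"""Surface-temperature retrieval and first-order decomposition of dTs.

Surface temperature is retrieved from outgoing longwave radiation via the
Stefan-Boltzmann law, LWUR = sigma * eps * Ts^4, with emissivity tied to
albedo through the empirical relation eps = -0.16 * alpha + 0.99.

The daily treated-minus-control temperature difference is decomposed by a
first-order Taylor expansion of the surface energy budget around the
control-site daily state:

    dTs_cal ~ [ -SWDR * d_alpha + (1 - alpha) * dSWDR + dLWDR
                - dLE - dH - dG - dI - sigma * Ts^4 * d_eps ]
              / (4 * sigma * eps * Ts^3)

where I = Rn - LE - H - G is the residual energy imbalance (it absorbs
neglected storage/photosynthesis fluxes and systematic flux errors), and
the reference Ts, eps, alpha and SWDR in the coefficients come from the
control site. Each term is stored in degC so components can be compared
and ranked; by construction the stored components sum exactly to dTs_cal.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .tower_io import CONSTANTS, PhysicalConstants

log = logging.getLogger("ecoforcing")

#: the eight stored components, in the fixed reporting order
COMPONENTS = ("d_alpha", "d_swdr", "d_lwdr", "d_le", "d_h", "d_g", "d_i",
              "d_eps")


def emissivity_from_albedo(albedo):
    """Surface broadband emissivity from albedo: eps = -0.16 a + 0.99.

    Albedo outside (0, 1) yields NaN (counted in the log).
    """
    a = np.asarray(albedo, dtype=float)
    bad = ~((a > 0.0) & (a < 1.0))
    n_bad = int(np.sum(bad & np.isfinite(a)))
    if n_bad:
        log.info("emissivity_from_albedo: %d out-of-range albedo values",
                 n_bad)
    return np.where(bad, np.nan, -0.16 * a + 0.99)


def ts_from_lwur(lwur, eps, constants: PhysicalConstants = CONSTANTS):
    """Radiometric surface temperature (K) from outgoing longwave.

    Ts = (LWUR / (sigma * eps))^(1/4); non-positive LWUR yields NaN. No
    reflected-downwelling correction is applied (the inversion mirrors the
    plain Stefan-Boltzmann form).
    """
    lwur = np.asarray(lwur, dtype=float)
    eps = np.asarray(eps, dtype=float)
    bad = ~(lwur > 0.0) | ~((eps > 0.0) & (eps <= 1.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        ts = (lwur / (constants.sigma * eps)) ** 0.25
    return np.where(bad, np.nan, ts)


def residual_imbalance(rn, le, h, g):
    """Residual energy imbalance I = Rn - LE - H - G (W m-2)."""
    return (np.asarray(rn, dtype=float) - np.asarray(le, dtype=float)
            - np.asarray(h, dtype=float) - np.asarray(g, dtype=float))


def delta_ts_obs(ts_treated, ts_control):
    """Observed daily dTs (degC): treated minus control (K difference)."""
    return np.asarray(ts_treated, dtype=float) - np.asarray(
        ts_control, dtype=float)


def decompose_delta_ts(control: pd.DataFrame, treated: pd.DataFrame,
                       constants: PhysicalConstants = CONSTANTS
                       ) -> pd.DataFrame:
    """Decompose daily dTs for one site pair into degC components.

    Both inputs are daily tables indexed alike with columns SWDR, SWUR,
    LWDR, LWUR, LE, H, G, albedo (daily midday albedo), aligned on their
    shared index. The reference state (Ts, eps, alpha, SWDR) is the
    control site's daily mean; treated-minus-control differences of each
    budget term are divided by 4*sigma*eps*Ts^3. Days with missing
    denominator inputs are dropped (counted in the log).

    Returns a frame with dTs_obs, dTs_cal, the eight components, and the
    reference Ts (K) and eps used in the denominator.
    """
    idx = control.index.intersection(treated.index)
    c = control.loc[idx]
    t = treated.loc[idx]

    eps_c = emissivity_from_albedo(c["albedo"])
    eps_t = emissivity_from_albedo(t["albedo"])
    ts_c = ts_from_lwur(c["LWUR"], eps_c, constants)
    ts_t = ts_from_lwur(t["LWUR"], eps_t, constants)

    denom = 4.0 * constants.sigma * eps_c * ts_c ** 3
    valid = np.isfinite(denom) & (denom > 0)
    n_dropped = int(len(idx) - valid.sum())
    if n_dropped:
        log.info("decompose_delta_ts: %d day(s) dropped for missing "
                 "reference state", n_dropped)

    rn_c = c["SWDR"] - c["SWUR"] + c["LWDR"] - c["LWUR"]
    rn_t = t["SWDR"] - t["SWUR"] + t["LWDR"] - t["LWUR"]
    i_c = residual_imbalance(rn_c, c["LE"], c["H"], c["G"])
    i_t = residual_imbalance(rn_t, t["LE"], t["H"], t["G"])

    d_alpha = t["albedo"].to_numpy() - c["albedo"].to_numpy()
    d_eps = eps_t - eps_c

    out = pd.DataFrame(index=idx)
    out["dTs_obs"] = delta_ts_obs(ts_t, ts_c)
    out["d_alpha"] = -c["SWDR"] * d_alpha / denom
    out["d_swdr"] = (1.0 - c["albedo"]) * (t["SWDR"] - c["SWDR"]) / denom
    out["d_lwdr"] = (t["LWDR"] - c["LWDR"]) / denom
    out["d_le"] = -(t["LE"] - c["LE"]) / denom
    out["d_h"] = -(t["H"] - c["H"]) / denom
    out["d_g"] = -(t["G"] - c["G"]) / denom
    out["d_i"] = -(i_t - i_c) / denom
    # -sigma Ts^4 d_eps / (4 sigma eps Ts^3) = -Ts d_eps / (4 eps)
    out["d_eps"] = -ts_c * d_eps / (4.0 * eps_c)
    out["dTs_cal"] = out[list(COMPONENTS)].sum(axis=1, skipna=False)
    out["ts_ref_K"] = ts_c
    out["eps_ref"] = eps_c
    return out[valid.to_numpy() if hasattr(valid, "to_numpy") else valid]
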