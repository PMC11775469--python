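"""Vapour-pressure and stomatal-conductance relations.

Implements the Magnus-Tetens saturation vapour pressure, the ideal-gas
vapour pressure from water molar density, the vapour pressure deficit and
the simplified stomatal conductance g_s = E / VPD * P, plus a table-level
transform that appends SVP/VP/VPD/g_s columns to a gas-exchange table.

Air temperature is the *chamber* air temperature: the study setup carries
no leaf thermometer, so VPD is leaf-to-air only to the extent that leaf
and air temperature agree (VPD is underestimated, and g_s overestimated,
when the leaf runs warmer).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Ideal gas constant, J mol^-1 K^-1.
R_GAS = 8.314

#: Celsius offset of the Kelvin scale.
T_KELVIN = 273.15

#: Default minimum VPD (kPa) below which g_s is not reported.
VPD_MIN_KPA = 0.05

#: Magnus-Tetens coefficients (kPa, dimensionless, degC).
MAGNUS_A = 0.61078
MAGNUS_B = 17.27
MAGNUS_C = 237.3


def compute_svp(temp_c):
    """Saturation vapour pressure (kPa) at air temperature ``temp_c`` (degC).

    Magnus-Tetens form: SVP = 0.61078 * exp(17.27 T / (T + 237.3)).
    Strictly increasing in T; the domain is T > -237.3 degC.
    """
    t = np.asarray(temp_c, dtype=float)
    if np.any(t <= -MAGNUS_C):
        raise ValueError(f"temperature must exceed {-MAGNUS_C} degC")
    out = MAGNUS_A * np.exp(MAGNUS_B * t / (t + MAGNUS_C))
    return out if out.ndim else float(out)


def compute_vp(n_over_v, temp_c):
    """Vapour pressure (kPa) from water molar density (mol m^-3).

    Ideal gas law: VP = (n/V) * R * T_K, with R in J mol^-1 K^-1 giving Pa,
    divided by 1000 to kPa.
    """
    n = np.asarray(n_over_v, dtype=float)
    if np.any(n < 0):
        raise ValueError("water molar density must be >= 0")
    out = n * R_GAS * (np.asarray(temp_c, dtype=float) + T_KELVIN) / 1000.0
    return out if out.ndim else float(out)


def compute_vpd(svp, vp):
    """Vapour pressure deficit (kPa): SVP - VP, clipped at zero.

    Negative raw values (sensor noise near saturation, e.g. at dawn) are
    clipped to 0; callers needing the supersaturation flag should compare
    vp > svp themselves or use :func:`add_micromet`.
    """
    out = np.clip(np.asarray(svp, dtype=float) - np.asarray(vp, dtype=float), 0.0, None)
    return out if out.ndim else float(out)


def compute_gs(e_mmol, vpd_kpa, pressure_kpa, vpd_min=VPD_MIN_KPA):
    """Stomatal conductance to water vapour, mmol m^-2 s^-1.

    g_s = E / VPD * P, with E in mmol m^-2 s^-1 and VPD, P in kPa.
    Where VPD < ``vpd_min`` the division is numerically meaningless and
    NaN is returned instead (low-VPD guard).
    """
    e = np.asarray(e_mmol, dtype=float)
    vpd = np.asarray(vpd_kpa, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        gs = np.where(vpd >= vpd_min, e / vpd * np.asarray(pressure_kpa, dtype=float), np.nan)
    return gs if gs.ndim else float(gs)


def add_micromet(
    gas: pd.DataFrame,
    *,
    temp_column: str = "chamber_T",
    h2o_column: str = "h2o_ambient_mol_m3",
    pressure_column: str = "pressure",
    vpd_min: float = VPD_MIN_KPA,
) -> pd.DataFrame:
    """Append SVP, VP, VPD, g_s and QC flag columns to a gas-exchange table.

    Expects per-closure rows carrying chamber air temperature (degC),
    ambient water molar density (mol m^-3), atmospheric pressure (kPa) and
    a transpiration column ``E`` (mmol m^-2 s^-1). Adds:

    ``SVP``, ``VP``, ``VPD`` (kPa), ``g_s`` (mmol m^-2 s^-1),
    ``supersaturation_flag`` (VP exceeded SVP before clipping) and
    ``low_vpd_flag`` (g_s withheld because VPD < ``vpd_min``).
    """
    out = gas.copy()
    svp = compute_svp(out[temp_column].to_numpy())
    vp = compute_vp(out[h2o_column].to_numpy(), out[temp_column].to_numpy())
    raw = svp - vp
    out["SVP"] = svp
    out["VP"] = vp
    out["VPD"] = np.clip(raw, 0.0, None)
    out["supersaturation_flag"] = raw < 0
    out["low_vpd_flag"] = out["VPD"] < vpd_min
    out["g_s"] = compute_gs(
        out["E"].to_numpy(), out["VPD"].to_numpy(), out[pressure_column].to_numpy(), vpd_min
    )
    return out
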