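"""PAM chlorophyll-fluorescence quantities: Y(II), ETR and nightly Fv/Fm.

The effective quantum yield of photosystem II is Y(II) = 1 - F'/F_M',
where F' and F_M' are the current and maximal pulse-amplitude-modulated
fluorescence yields. The linear electron transport rate is
ETR = PAR * Y(II) * Abs * alpha_II, with leaf PAR absorptance Abs (default
0.84) and PSII allocation fraction alpha_II (default 0.5). The nightly
maximum of dark-acclimated Y(II) estimates the maximum quantum yield
Fv/Fm. All three are invariant to any common multiplicative scaling of F'
and F_M' (gain drift, step artifacts), since the gain cancels in the
ratio.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Default leaf PAR absorptance.
DEFAULT_ABSORPTANCE = 0.84

#: Default fraction of absorbed PAR allocated to PSII antennae.
DEFAULT_ALPHA_II = 0.5

#: PAR (umol m^-2 s^-1) below which a record counts as dark-acclimated.
DARK_PAR_THRESHOLD = 5.0


class ConfigError(ValueError):
    """Out-of-range Abs / alpha_II coefficients."""


def compute_yii(f_prime, f_m_prime):
    """Effective PSII quantum yield, Y(II) = 1 - F'/F_M'.

    Records with F' > F_M' indicate saturating-pulse failure and are
    returned as NaN (flagged-missing, never clipped to 0 — clipping would
    bias nightly Fv/Fm maxima). Nonpositive inputs raise ``ValueError``.
    """
    f = np.asarray(f_prime, dtype=float)
    fm = np.asarray(f_m_prime, dtype=float)
    if np.any(f <= 0) or np.any(fm <= 0):
        raise ValueError("F' and F_M' must be positive")
    yii = np.where(f <= fm, 1.0 - f / fm, np.nan)
    return yii if yii.ndim else float(yii)


def compute_etr(
    par,
    yii,
    absorptance: float = DEFAULT_ABSORPTANCE,
    alpha_ii: float = DEFAULT_ALPHA_II,
):
    """Linear electron transport rate, ETR = PAR * Y(II) * Abs * alpha_II.

    ``par`` should be the chamber PAR sensor reading (the PAM sensor's PAR
    is reserved for quality control). Units umol electrons m^-2 s^-1.
    """
    if not (0 < absorptance <= 1) or not (0 < alpha_ii <= 1):
        raise ConfigError("absorptance and alpha_ii must lie in (0, 1]")
    par_arr = np.asarray(par, dtype=float)
    if np.any(par_arr < 0):
        raise ValueError("PAR must be >= 0")
    out = par_arr * np.asarray(yii, dtype=float) * absorptance * alpha_ii
    return out if out.ndim else float(out)


def process_pam_stream(pam: pd.DataFrame) -> pd.DataFrame:
    """Append Y(II) and a pulse-failure flag to a raw PAM table.

    Expects columns ``timestamp``, ``F_prime``, ``F_M_prime``,
    ``PAR_MICRO``. Records with nonpositive fluorescence or F' > F_M' are
    flagged ``pulse_failure`` and carry Y_II = NaN rather than aborting
    the stream.
    """
    out = pam.copy()
    f = out["F_prime"].to_numpy(dtype=float)
    fm = out["F_M_prime"].to_numpy(dtype=float)
    bad = ~np.isfinite(f) | ~np.isfinite(fm) | (f <= 0) | (fm <= 0) | (f > fm)
    yii = np.full(len(out), np.nan)
    ok = ~bad
    yii[ok] = 1.0 - f[ok] / fm[ok]
    out["Y_II"] = yii
    out["pulse_failure"] = bad
    return out


def extract_fvfm(
    fluor: pd.DataFrame,
    par_column: str = "PAR_MICRO",
    dark_par_threshold: float = DARK_PAR_THRESHOLD,
) -> pd.DataFrame:
    """Nightly Fv/Fm estimates: the maximum dark-acclimated Y(II) per night.

    A record is dark when its PAR reading is below ``dark_par_threshold``.
    Nights are counted noon-to-noon, labelled by the date the night starts
    (boreal nights straddle midnight). Nights without any valid dark
    record are absent from the output, never reported as zero.

    Returns columns ``night`` (date), ``F_V_over_F_M``, ``n_records``,
    ``window_start``, ``window_end``.
    """
    dark = fluor[
        (fluor[par_column] < dark_par_threshold) & np.isfinite(fluor["Y_II"])
    ]
    if dark.empty:
        return pd.DataFrame(
            columns=["night", "F_V_over_F_M", "n_records", "window_start", "window_end"]
        )
    night = (dark["timestamp"] - pd.Timedelta(hours=12)).dt.date
    rows = []
    for night_date, grp in dark.groupby(night):
        rows.append(
            {
                "night": night_date,
                "F_V_over_F_M": float(grp["Y_II"].max()),
                "n_records": int(len(grp)),
                "window_start": grp["timestamp"].min(),
                "window_end": grp["timestamp"].max(),
            }
        )
    return pd.DataFrame(rows)
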