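"""Time-matching of gas-exchange and fluorescence records, and PAR-ratio QC.

The fluorometer logger clock drifts relative to the chamber controller (up
to ~8 min over a campaign), so records are paired by nearest timestamp
within a tolerance, one-to-one. Pairs measured under diverging light —
detected by the ratio of the chamber PAR sensor to the fluorometer PAR
sensor falling outside configurable bounds (default 0.5–2.0, strict
0.75–1.5) — are flagged and excluded from analysis.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .fluorescence import DARK_PAR_THRESHOLD

#: Default pairing tolerance, s (covers the reported <= 8-min drift).
DEFAULT_TOLERANCE_S = 600.0

#: Default and strict PAR-ratio QC bounds (inclusive).
PAR_RATIO_BOUNDS = (0.5, 2.0)
PAR_RATIO_BOUNDS_STRICT = (0.75, 1.5)

# QC reason codes
NO_MATCH = "no_match"
PAR_RATIO_OUT_OF_RANGE = "par_ratio_out_of_range"
DARK_PAIR = "dark_pair"
PULSE_FAILURE = "pulse_failure"
LOW_DENOMINATOR = "low_denominator"

_GAS_COLS = ["A_NET", "E", "g_s", "PAR_CH", "chamber_T", "pressure"]
_PAM_COLS = ["F_prime", "F_M_prime", "PAR_MICRO", "Y_II", "pulse_failure"]


def _check_sorted(ts: pd.Series, name: str) -> None:
    if not ts.is_monotonic_increasing:
        raise ValueError(f"{name} stream must be sorted by timestamp")


def pair_streams(
    gas: pd.DataFrame, fluor: pd.DataFrame, tolerance_s: float = DEFAULT_TOLERANCE_S
) -> pd.DataFrame:
    """Match each gas record to the nearest fluorescence record in time.

    Matching is one-to-one: a fluorescence record is consumed by at most
    one gas record; candidate pairs are taken in order of increasing
    absolute offset (earlier gas record wins exact ties). Records left
    without a partner within ``tolerance_s`` are emitted with the
    ``no_match`` QC code and missing partner fields.

    Returns one row per gas record (plus one per unmatched fluorescence
    record) with both streams' fields, ``gas_timestamp``,
    ``pam_timestamp``, ``time_offset_s`` (pam minus gas) and a ``matched``
    flag.
    """
    _check_sorted(gas["timestamp"], "gas")
    _check_sorted(fluor["timestamp"], "fluorescence")
    if gas.empty or fluor.empty:
        warnings.warn("empty input stream: no pairs produced", stacklevel=2)

    gas_t = gas["timestamp"].to_numpy()
    pam_t = fluor["timestamp"].to_numpy()
    candidates = []  # (abs_offset_s, gas_pos, pam_pos)
    for i, t in enumerate(gas_t):
        j = np.searchsorted(pam_t, t)
        for k in (j - 1, j):
            if 0 <= k < len(pam_t):
                dt = abs((pam_t[k] - t) / np.timedelta64(1, "s"))
                if dt <= tolerance_s:
                    candidates.append((dt, i, k))
    candidates.sort(key=lambda c: (c[0], c[1]))

    gas_match = np.full(len(gas), -1)
    pam_used = np.zeros(len(fluor), dtype=bool)
    for dt, i, k in candidates:
        if gas_match[i] == -1 and not pam_used[k]:
            gas_match[i] = k
            pam_used[k] = True

    gas_cols = [c for c in _GAS_COLS if c in gas.columns]
    pam_cols = [c for c in _PAM_COLS if c in fluor.columns]
    rows = []
    for i in range(len(gas)):
        row = {"gas_timestamp": gas["timestamp"].iloc[i]}
        for c in gas_cols:
            row[c] = gas[c].iloc[i]
        k = gas_match[i]
        if k >= 0:
            row["pam_timestamp"] = fluor["timestamp"].iloc[k]
            for c in pam_cols:
                row[c] = fluor[c].iloc[k]
            row["time_offset_s"] = (
                row["pam_timestamp"] - row["gas_timestamp"]
            ).total_seconds()
            row["matched"] = True
            row["qc_reasons"] = ""
        else:
            row["pam_timestamp"] = pd.NaT
            for c in pam_cols:
                row[c] = np.nan
            row["time_offset_s"] = np.nan
            row["matched"] = False
            row["qc_reasons"] = NO_MATCH
        rows.append(row)
    for k in np.flatnonzero(~pam_used):
        row = {"gas_timestamp": pd.NaT}
        for c in gas_cols:
            row[c] = np.nan
        row["pam_timestamp"] = fluor["timestamp"].iloc[k]
        for c in pam_cols:
            row[c] = fluor[c].iloc[k]
        row["time_offset_s"] = np.nan
        row["matched"] = False
        row["qc_reasons"] = NO_MATCH
        rows.append(row)
    out = pd.DataFrame(rows)
    if out.empty:
        cols = (
            ["gas_timestamp"] + gas_cols + ["pam_timestamp"] + pam_cols
            + ["time_offset_s", "matched", "qc_reasons"]
        )
        return pd.DataFrame(columns=cols)
    order = out["gas_timestamp"].fillna(out["pam_timestamp"])
    return out.iloc[np.argsort(order.to_numpy(), kind="stable")].reset_index(drop=True)


def _append_reason(reasons: pd.Series, mask, code: str) -> pd.Series:
    add = np.where(mask, code, "")
    joined = reasons.str.cat(pd.Series(add, index=reasons.index), sep=";")
    return joined.str.strip(";").str.replace(";;", ";", regex=False)


def qc_par_ratio(
    pairs: pd.DataFrame,
    lo: float = PAR_RATIO_BOUNDS[0],
    hi: float = PAR_RATIO_BOUNDS[1],
    dark_par_threshold: float = DARK_PAR_THRESHOLD,
) -> pd.DataFrame:
    """Apply the PAR_CH/PAR_MICRO illumination-mismatch filter.

    The ratio discriminates pairs whose two measurements sampled different
    light environments (clouds plus clock drift). Bounds are inclusive:
    ratios exactly at ``lo`` or ``hi`` are retained. Pairs with both PAR
    readings below ``dark_par_threshold`` are night pairs: the ratio is
    undefined there and they bypass the filter with the ``dark_pair`` tag
    (tag only — it never fails a record). Mixed pairs (one sensor dark,
    one lit) are genuine mismatches and are judged by the ratio. Pulse
    failures (missing Y(II)) also fail QC.

    Adds ``par_ratio``, ``dark_pair``, ``qc_pass`` and extends
    ``qc_reasons`` (dark_pair lives in its own column so that passing
    records keep an empty reason list).
    """
    if not (0 < lo < hi):
        raise ValueError("bounds must satisfy 0 < lo < hi")
    out = pairs.copy()
    par_ch = out["PAR_CH"].to_numpy(dtype=float)
    par_mi = out["PAR_MICRO"].to_numpy(dtype=float)
    matched = out["matched"].to_numpy(dtype=bool)

    both_dark = matched & (par_ch < dark_par_threshold) & (par_mi < dark_par_threshold)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(matched & ~both_dark, par_ch / par_mi, np.nan)
    out["par_ratio"] = ratio
    out["dark_pair"] = both_dark
    out_of_range = matched & ~both_dark & ~((ratio >= lo) & (ratio <= hi))

    reasons = out["qc_reasons"].astype(str)
    reasons = _append_reason(reasons, out_of_range, PAR_RATIO_OUT_OF_RANGE)
    if "pulse_failure" in out.columns:
        pulse = matched & out["pulse_failure"].fillna(False).to_numpy(dtype=bool)
        reasons = _append_reason(reasons, pulse, PULSE_FAILURE)
    else:
        pulse = np.zeros(len(out), dtype=bool)
    out["qc_reasons"] = reasons
    out["qc_pass"] = matched & ~out_of_range & ~pulse
    return out
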