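"""The ETR/A_NET electron-use-efficiency diagnostic and daily summaries.

ETR/A_NET counts the electrons transported through PSII per molecule of
CO2 contributing to the leaf's net carbon balance. Its theoretical floor
is 4 (four electrons generate the two NADPH that fix one CO2);
photorespiration, mitochondrial respiration and alternative electron
sinks all raise it. Values of 8–10 are typical for unstressed C3 leaves;
under combined heat and water stress, with net assimilation near zero,
the ratio can climb into the hundreds — so low-denominator records are
flagged but reported, not censored.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: |A_NET| (umol m^-2 s^-1) below which the ratio is flagged as fragile.
DEFAULT_DENOM_GUARD = 0.5

#: Noon-averaging window, local hours [start, end).
NOON_WINDOW = (11, 15)


def compute_ratio(pairs: pd.DataFrame, guard: float = DEFAULT_DENOM_GUARD) -> pd.DataFrame:
    """Append ``etr_over_anet``, ``denom_flag`` and ``sign_flag`` columns.

    The ratio is reported for A_NET > 0 (``denom_flag`` set when
    |A_NET| < ``guard``, value still reported — extreme values are the
    signal under stress, not an artifact). For A_NET <= 0 the ratio loses
    its per-CO2-fixed meaning: ``sign_flag`` is set and the value
    suppressed (NaN).
    """
    out = pairs.copy()
    a = out["A_NET"].to_numpy(dtype=float)
    etr = out["ETR"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(a > 0, etr / a, np.nan)
    out["etr_over_anet"] = ratio
    out["denom_flag"] = np.abs(a) < guard
    out["sign_flag"] = a <= 0
    return out


def summarize_daily(
    records: pd.DataFrame,
    noon_window: tuple[int, int] = NOON_WINDOW,
    dark_par_threshold: float = 5.0,
) -> pd.DataFrame:
    """Per-day noon means, daily extrema and record counts.

    Noon means (half-open local window, default [11:00, 15:00)) use only
    qc-passing daylight records (PAR_CH at or above ``dark_par_threshold``).
    Every mean carries its record count; days present in the data but
    without any qualifying record get count 0 and missing means.
    """
    df = records.dropna(subset=["gas_timestamp"]).copy()
    if df.empty:
        return pd.DataFrame(
            columns=[
                "date", "n_qc_pass", "noon_n",
                "noon_g_s", "noon_A_NET", "noon_ETR", "noon_etr_over_anet",
                "max_etr_over_anet", "min_etr_over_anet", "max_A_NET", "min_A_NET",
            ]
        )
    df["date"] = df["gas_timestamp"].dt.date
    hours = df["gas_timestamp"].dt.hour
    is_noon = (hours >= noon_window[0]) & (hours < noon_window[1])
    qc = df["qc_pass"].fillna(False).astype(bool)
    daylight = df["PAR_CH"] >= dark_par_threshold
    noon_ok = is_noon & qc & daylight

    rows = []
    for date, grp in df.groupby("date", sort=True):
        sel = grp[noon_ok.loc[grp.index]]
        passing = grp[qc.loc[grp.index]]
        def _mean(col):
            vals = sel[col].dropna() if col in sel.columns else pd.Series(dtype=float)
            return (float(vals.mean()), int(len(vals))) if len(vals) else (np.nan, 0)
        noon_gs, _ = _mean("g_s")
        noon_a, _ = _mean("A_NET")
        noon_etr, _ = _mean("ETR")
        noon_ratio, n_ratio = _mean("etr_over_anet")
        ratios = passing["etr_over_anet"].dropna() if "etr_over_anet" in passing else []
        rows.append(
            {
                "date": date,
                "n_qc_pass": int(qc.loc[grp.index].sum()),
                "noon_n": int(noon_ok.loc[grp.index].sum()),
                "noon_g_s": noon_gs,
                "noon_A_NET": noon_a,
                "noon_ETR": noon_etr,
                "noon_etr_over_anet": noon_ratio,
                "noon_ratio_n": n_ratio,
                "max_etr_over_anet": float(np.max(ratios)) if len(ratios) else np.nan,
                "min_etr_over_anet": float(np.min(ratios)) if len(ratios) else np.nan,
                "max_A_NET": float(passing["A_NET"].max()) if len(passing) else np.nan,
                "min_A_NET": float(passing["A_NET"].min()) if len(passing) else np.nan,
            }
        )
    return pd.DataFrame(rows)
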