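"""Reading and writing the delimited-text record streams.

Both instrument streams are comma-separated text with a header row and
ISO-8601 timestamps: the chamber stream has one row per 5-s closure sample
(columns ``closure_id, timestamp, co2, h2o, chamber_T, PAR_CH[, pressure]``),
the PAM stream one row per measurement cycle
(``timestamp, F_prime, F_M_prime, PAR_MICRO``).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

CHAMBER_COLUMNS = ["closure_id", "timestamp", "co2", "h2o", "chamber_T", "PAR_CH"]
PAM_COLUMNS = ["timestamp", "F_prime", "F_M_prime", "PAR_MICRO"]


def read_chamber_stream(path: str | Path) -> pd.DataFrame:
    """Read a chamber-IRGA closure stream, parsing timestamps."""
    df = pd.read_csv(path, parse_dates=["timestamp"])
    missing = set(CHAMBER_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"chamber stream missing columns: {sorted(missing)}")
    return df


def read_pam_stream(path: str | Path) -> pd.DataFrame:
    """Read a PAM fluorometer stream, parsing timestamps."""
    df = pd.read_csv(path, parse_dates=["timestamp"])
    missing = set(PAM_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"PAM stream missing columns: {sorted(missing)}")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write any derived table as comma-separated text with ISO timestamps."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, date_format="%Y-%m-%dT%H:%M:%S.%f")
    return path
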