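"""End-to-end processing: streams in, paired QC'd records and summaries out.

Chains the per-module operations in the order the measurement logic
demands: closure slopes -> fluxes -> VPD and g_s; PAM records -> Y(II) and
nightly Fv/Fm; nearest-in-time pairing under clock drift; PAR-ratio QC;
ETR from chamber PAR; the ETR/A_NET ratio; daily/noon aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import chamber, fluorescence, micromet, pairing, ratios


@dataclass(frozen=True)
class PipelineConfig:
    """Processing options shared across the pipeline stages."""

    chamber_volume_m3: float = 2.1e-3
    leaf_area_m2: float = 42.5e-4
    pressure_kpa: Optional[float] = None  # None: take per-row pressure column
    h2o_unit: str = "mol_m3"
    lag_discard_s: float = chamber.DEFAULT_LAG_DISCARD_S
    flux_method: str = "linear"  # or "mass_balance" for non-hermetic chambers
    inflow_time_constant_s: Optional[float] = None
    tolerance_s: float = pairing.DEFAULT_TOLERANCE_S
    par_ratio_lo: float = pairing.PAR_RATIO_BOUNDS[0]
    par_ratio_hi: float = pairing.PAR_RATIO_BOUNDS[1]
    dark_par_threshold: float = fluorescence.DARK_PAR_THRESHOLD
    absorptance: float = fluorescence.DEFAULT_ABSORPTANCE
    alpha_ii: float = fluorescence.DEFAULT_ALPHA_II
    vpd_min_kpa: float = micromet.VPD_MIN_KPA
    denom_guard: float = ratios.DEFAULT_DENOM_GUARD

    def strict(self) -> "PipelineConfig":
        """Copy with the strict 0.75-1.5 PAR-ratio bounds."""
        from dataclasses import replace

        lo, hi = pairing.PAR_RATIO_BOUNDS_STRICT
        return replace(self, par_ratio_lo=lo, par_ratio_hi=hi)


@dataclass
class PipelineResult:
    """All derived tables for one campaign."""

    gas: pd.DataFrame       # per-closure fluxes + micromet columns
    fluor: pd.DataFrame     # per-cycle Y(II)
    fvfm: pd.DataFrame      # nightly Fv/Fm estimates
    pairs: pd.DataFrame     # paired, QC'd records with ETR and ETR/A_NET
    daily: pd.DataFrame     # noon means and daily extrema


def run_pipeline(
    chamber_stream: pd.DataFrame,
    pam_stream: pd.DataFrame,
    config: PipelineConfig = PipelineConfig(),
) -> PipelineResult:
    """Process raw chamber and PAM streams into paired, QC'd records."""
    gas = chamber.process_chamber_stream(
        chamber_stream,
        chamber_volume=config.chamber_volume_m3,
        leaf_area=config.leaf_area_m2,
        pressure=config.pressure_kpa,
        h2o_unit=config.h2o_unit,
        lag_discard=config.lag_discard_s,
        method=config.flux_method,
        inflow_time_constant=config.inflow_time_constant_s,
    )
    gas = micromet.add_micromet(gas, vpd_min=config.vpd_min_kpa)

    fluor = fluorescence.process_pam_stream(pam_stream)
    fvfm = fluorescence.extract_fvfm(
        fluor, dark_par_threshold=config.dark_par_threshold
    )

    pairs = pairing.pair_streams(gas, fluor, tolerance_s=config.tolerance_s)
    pairs = pairing.qc_par_ratio(
        pairs,
        lo=config.par_ratio_lo,
        hi=config.par_ratio_hi,
        dark_par_threshold=config.dark_par_threshold,
    )

    # ETR uses the chamber PAR sensor; the PAM sensor's PAR is QC-only.
    etr = np.full(len(pairs), np.nan)
    ok = pairs["matched"].to_numpy(dtype=bool) & np.isfinite(
        pairs["PAR_CH"].to_numpy(dtype=float)
    )
    etr[ok] = fluorescence.compute_etr(
        pairs.loc[ok, "PAR_CH"].to_numpy(dtype=float),
        pairs.loc[ok, "Y_II"].to_numpy(dtype=float),
        absorptance=config.absorptance,
        alpha_ii=config.alpha_ii,
    )
    pairs = pairs.assign(ETR=etr, PAR_used=pairs["PAR_CH"], PAR_source="chamber")
    pairs = ratios.compute_ratio(pairs, guard=config.denom_guard)
    daily = ratios.summarize_daily(
        pairs, dark_par_threshold=config.dark_par_threshold
    )
    return PipelineResult(gas=gas, fluor=fluor, fvfm=fvfm, pairs=pairs, daily=daily)
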