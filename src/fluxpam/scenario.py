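"""Parameterization of a synthetic leaf/chamber/PAM measurement campaign.

A :class:`Scenario` freezes every knob of the simulator: the diurnal
forcing, the leaf physiology (light response, respiration and electron-sink
fractions, stomatal model), the chamber geometry, the instrument artifacts
(fluorometer gain, gain step, clock drift, sensor noise) and the RNG seed.
Identical scenario + seed produces bit-identical output streams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import pandas as pd
import yaml


class InvalidScenarioError(ValueError):
    """Raised when a Scenario violates its own invariants."""


@dataclass(frozen=True)
class NoiseLevels:
    """Additive Gaussian sensor-noise standard deviations.

    co2_ppm
        SD of each CO2 sample during closure, ppm.
    h2o_mol_m3
        SD of each H2O sample, mol m^-3.
    fluorescence
        SD of F' and F_M' samples, instrument units (F_M' base level is
        ``Scenario.f_m_base``).
    par
        SD of the PAR sensor readings, umol m^-2 s^-1.
    """

    co2_ppm: float = 0.2
    h2o_mol_m3: float = 0.002
    fluorescence: float = 0.01
    par: float = 2.0

    def __post_init__(self) -> None:
        for name in ("co2_ppm", "h2o_mol_m3", "fluorescence", "par"):
            if getattr(self, name) < 0:
                raise InvalidScenarioError(f"noise SD {name} must be >= 0")

    @classmethod
    def zero(cls) -> "NoiseLevels":
        """Noise-free configuration (all SDs zero)."""
        return cls(0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class Scenario:
    """Full parameterization of a synthetic measurement campaign.

    Defaults reproduce the study conditions of a boreal-summer birch
    campaign: a 2.1 dm^3 shoot chamber enclosing 42.5 cm^2 of leaf, closed
    for 60 s every 20 min with 5-s IRGA sampling, midday PAR up to
    1700 umol m^-2 s^-1 and a 12 degC diurnal temperature swing.
    """

    # -- campaign clock ----------------------------------------------------
    start_time: str | pd.Timestamp = "2021-07-01 00:00"
    end_time: str | pd.Timestamp = "2021-07-04 00:00"
    cadence_min: float = 20.0

    # -- forcing -----------------------------------------------------------
    par_max: float = 1700.0
    t_min: float = 13.0
    t_max: float = 25.0
    night_hours: float = 6.0
    pressure_kpa: float = 99.2
    co2_ambient_ppm: float = 412.0
    rh_night: float = 0.9  # relative humidity at the nightly T minimum

    # -- chamber geometry --------------------------------------------------
    leaf_area_m2: float = 42.5e-4
    chamber_volume_m3: float = 2.1e-3
    closure_duration_s: float = 60.0
    sample_interval_s: float = 5.0

    # -- leaf physiology ---------------------------------------------------
    resp_fraction: float = 0.15
    photoresp_fraction: float = 0.35
    alt_sink_fraction: float = 0.10
    par_sat: float = 450.0  # e-folding PAR of the saturating light response
    yii_dark: float = 0.82  # dark-acclimated Y(II), i.e. true Fv/Fm
    absorptance: float = 0.84
    alpha_ii: float = 0.5
    gs_max: float = 250.0  # mmol m^-2 s^-1
    gs_vpd_sensitivity: float = 0.6  # per kPa
    gs_dark_fraction: float = 0.05  # residual nocturnal conductance
    gs_par_scale: float = 250.0  # PAR e-folding of stomatal opening

    # -- instrument artifacts ----------------------------------------------
    inflow_time_constant_s: Optional[float] = None  # None = hermetic chamber
    clock_drift_s: float = 0.0  # PAM timestamp offset, linear 0 -> this
    pam_gain: float = 1.0
    f_m_base: float = 2.5  # F_M' level at gain 1, instrument units
    gain_step: Optional[Tuple[str | pd.Timestamp, float]] = None
    n_light_mismatch: int = 0
    light_mismatch_factor: float = 0.2  # cloud-shading factor on PAR_MICRO
    noise: NoiseLevels = field(default_factory=NoiseLevels)
    seed: int = 0

    def __post_init__(self) -> None:
        start = pd.Timestamp(self.start_time)
        end = pd.Timestamp(self.end_time)
        object.__setattr__(self, "start_time", start)
        object.__setattr__(self, "end_time", end)
        if end <= start:
            raise InvalidScenarioError("end_time must be after start_time")
        if self.cadence_min <= 0 or self.closure_duration_s <= 0 or self.sample_interval_s <= 0:
            raise InvalidScenarioError("cadence, closure duration and sample interval must be > 0")
        ratio = self.closure_duration_s / self.sample_interval_s
        if abs(ratio - round(ratio)) > 1e-9:
            raise InvalidScenarioError("sample_interval_s must divide closure_duration_s")
        if self.closure_duration_s >= self.cadence_min * 60.0:
            raise InvalidScenarioError("closure must be shorter than the cycle cadence")
        if self.resp_fraction < 0:
            raise InvalidScenarioError("resp_fraction must be >= 0")
        if not (0 <= self.photoresp_fraction < 1) or not (0 <= self.alt_sink_fraction < 1):
            raise InvalidScenarioError("sink fractions must lie in [0, 1)")
        if self.photoresp_fraction + self.alt_sink_fraction >= 1:
            raise InvalidScenarioError("photoresp_fraction + alt_sink_fraction must be < 1")
        if self.t_max <= self.t_min:
            raise InvalidScenarioError("t_max must exceed t_min")
        if not (0 < self.night_hours < 24):
            raise InvalidScenarioError("night_hours must lie in (0, 24)")
        if self.par_max < 0 or self.pressure_kpa <= 0:
            raise InvalidScenarioError("par_max must be >= 0 and pressure > 0")
        if self.leaf_area_m2 <= 0 or self.chamber_volume_m3 <= 0:
            raise InvalidScenarioError("leaf area and chamber volume must be > 0")
        if not (0 < self.yii_dark <= 1):
            raise InvalidScenarioError("yii_dark must lie in (0, 1]")
        if not (0 < self.absorptance <= 1) or not (0 < self.alpha_ii <= 1):
            raise InvalidScenarioError("absorptance and alpha_ii must lie in (0, 1]")
        if self.inflow_time_constant_s is not None and self.inflow_time_constant_s <= 0:
            raise InvalidScenarioError("inflow_time_constant_s must be > 0 or None")
        if self.pam_gain <= 0 or self.f_m_base <= 0:
            raise InvalidScenarioError("pam_gain and f_m_base must be > 0")
        if self.gain_step is not None:
            t, factor = self.gain_step
            object.__setattr__(self, "gain_step", (pd.Timestamp(t), float(factor)))
            if factor <= 0:
                raise InvalidScenarioError("gain_step factor must be > 0")
        if self.n_light_mismatch < 0:
            raise InvalidScenarioError("n_light_mismatch must be >= 0")
        if not (0 < self.light_mismatch_factor) or math.isclose(self.light_mismatch_factor, 1.0):
            raise InvalidScenarioError("light_mismatch_factor must be > 0 and != 1")

    # -- convenience -------------------------------------------------------
    @property
    def n_samples_per_closure(self) -> int:
        return int(round(self.closure_duration_s / self.sample_interval_s)) + 1

    def with_(self, **kwargs) -> "Scenario":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def load_scenario(path: str) -> Scenario:
    """Load a Scenario from a YAML mapping of field names to values."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "noise" in raw and isinstance(raw["noise"], dict):
        raw["noise"] = NoiseLevels(**raw["noise"])
    if "gain_step" in raw and raw["gain_step"] is not None:
        t, factor = raw["gain_step"]
        raw["gain_step"] = (t, float(factor))
    return Scenario(**raw)
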