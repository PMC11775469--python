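"""Synthetic leaf / chamber / PAM campaign generator.

Produces the two instrument streams consumed by the processing pipeline —
a chamber-IRGA closure stream and a PAM fluorometer stream — from a fully
known ground-truth physiology, so that every downstream stage can be
verified by parameter recovery.

The generative chain is:

1. diurnal forcing — PAR follows a half-sine day arc (zero during a
   configurable night window), air temperature a 24-h sinusoid between
   ``t_min`` and ``t_max`` (minimum at 03:00, maximum at 15:00);
2. leaf physiology — electron transport follows a one-parameter saturating
   exponential of PAR scaled so its quantum efficiency at zero light is the
   dark-acclimated Y(II); gross assimilation is ETR/4 discounted by the
   photorespiratory and alternative-sink electron fractions; net
   assimilation discounts day respiration as a fraction of gross;
   transpiration inverts g_s = E/VPD*P with a stomatal conductance that
   opens with PAR and closes with VPD;
3. chamber closures — each 60-s closure yields a concentration trace whose
   slope follows the ideal-gas mass balance of the imposed fluxes, with
   optional first-order relaxation toward ambient (non-hermetic inflow) and
   additive Gaussian sensor noise;
4. PAM observations — F_M' and F' are generated so 1 - F'/F_M' equals the
   true Y(II) before noise, multiplied by the fluorometer gain and an
   optional step artifact; PAM timestamps carry a linear clock-drift ramp
   (the measurement happens on the cycle, its logged stamp drifts).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .micromet import R_GAS, T_KELVIN, compute_svp
from .scenario import InvalidScenarioError, Scenario

__all__ = [
    "CampaignData",
    "simulate_forcing",
    "simulate_leaf",
    "simulate_closures",
    "simulate_pam",
    "simulate_campaign",
    "write_campaign",
]


def _rng(scenario: Scenario, stream: int) -> np.random.Generator:
    # Independent, reproducible substream per simulator stage.
    return np.random.default_rng(np.random.SeedSequence(scenario.seed, spawn_key=(stream,)))


def _cycle_times(scenario: Scenario) -> pd.DatetimeIndex:
    return pd.date_range(
        scenario.start_time,
        scenario.end_time,
        freq=pd.Timedelta(minutes=scenario.cadence_min),
        inclusive="left",
    )


def simulate_forcing(scenario: Scenario) -> pd.DataFrame:
    """Diurnal PAR and air-temperature forcing on the measurement-cycle grid.

    Returns a DataFrame indexed by cycle start time with columns ``par``
    (umol m^-2 s^-1, >= 0, zero through the night window) and ``temp``
    (degC, sinusoidal between ``t_min`` and ``t_max``).
    """
    if not isinstance(scenario, Scenario):
        raise InvalidScenarioError("expected a Scenario")
    times = _cycle_times(scenario)
    hours = (
        times.hour.to_numpy() + times.minute.to_numpy() / 60.0 + times.second.to_numpy() / 3600.0
    )
    day_len = 24.0 - scenario.night_hours
    sunrise = 12.0 - day_len / 2.0
    x = (hours - sunrise) / day_len
    par = np.where((x > 0) & (x < 1), scenario.par_max * np.sin(np.pi * x), 0.0)
    par = np.clip(par, 0.0, None)
    mid = 0.5 * (scenario.t_min + scenario.t_max)
    amp = 0.5 * (scenario.t_max - scenario.t_min)
    temp = mid - amp * np.cos(2.0 * np.pi * (hours - 3.0) / 24.0)
    return pd.DataFrame({"par": par, "temp": temp}, index=times)


def simulate_leaf(forcing: pd.DataFrame, scenario: Scenario) -> pd.DataFrame:
    """Ground-truth leaf physiology for each measurement cycle.

    Returns a DataFrame indexed like ``forcing`` with the true values of
    ``etr`` (umol e- m^-2 s^-1), ``yii``, ``gross``/``a_net``
    (umol CO2 m^-2 s^-1, uptake positive), ``gs`` (mmol m^-2 s^-1),
    ``vpd`` (kPa), ``e`` (mmol H2O m^-2 s^-1), the constant ambient water
    molar density ``n_h2o_ambient`` (mol m^-3), the per-cycle PAM clock
    offset ``clock_offset_s`` and the light-mismatch injection log
    ``light_mismatch``.

    With all three sink/respiration fractions zero, ETR/A_NET is exactly 4
    at every lit cycle (four electrons per two NADPH per CO2 fixed); each
    positive fraction raises the ratio by construction:
    ETR/A_NET = 4 / ((1 - photoresp - alt_sink) * (1 - resp)).
    """
    par = forcing["par"].to_numpy()
    temp = forcing["temp"].to_numpy()
    quantum_eff = scenario.absorptance * scenario.alpha_ii
    etr = (
        quantum_eff
        * scenario.yii_dark
        * scenario.par_sat
        * -np.expm1(-par / scenario.par_sat)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        yii = np.where(par > 0, etr / (par * quantum_eff), scenario.yii_dark)
    gross = etr / 4.0 * (1.0 - scenario.photoresp_fraction - scenario.alt_sink_fraction)
    a_net = gross * (1.0 - scenario.resp_fraction)

    # Constant absolute humidity pegged to rh_night at the nightly T minimum.
    n_amb = (
        scenario.rh_night
        * compute_svp(scenario.t_min)
        * 1000.0
        / (R_GAS * (scenario.t_min + T_KELVIN))
    )
    vp = n_amb * R_GAS * (temp + T_KELVIN) / 1000.0
    vpd = np.clip(compute_svp(temp) - vp, 0.0, None)
    light_opening = scenario.gs_dark_fraction + (1.0 - scenario.gs_dark_fraction) * (
        -np.expm1(-par / scenario.gs_par_scale)
    )
    gs = scenario.gs_max * light_opening / (1.0 + scenario.gs_vpd_sensitivity * vpd)
    e = gs * vpd / scenario.pressure_kpa  # mmol m^-2 s^-1, inverse of g_s = E/VPD*P

    total = (scenario.end_time - scenario.start_time).total_seconds()
    elapsed = (forcing.index - scenario.start_time).total_seconds().to_numpy()
    clock_offset = scenario.clock_drift_s * elapsed / total

    mismatch = np.zeros(len(forcing), dtype=bool)
    if scenario.n_light_mismatch:
        lit = np.flatnonzero(par >= 100.0)
        if len(lit) < scenario.n_light_mismatch:
            raise InvalidScenarioError(
                "fewer well-lit cycles than requested light-mismatch injections"
            )
        pick = _rng(scenario, 0).choice(lit, size=scenario.n_light_mismatch, replace=False)
        mismatch[pick] = True

    return pd.DataFrame(
        {
            "par": par,
            "temp": temp,
            "etr": etr,
            "yii": yii,
            "gross": gross,
            "a_net": a_net,
            "gs": gs,
            "vpd": vpd,
            "e": e,
            "n_h2o_ambient": n_amb,
            "clock_offset_s": clock_offset,
            "light_mismatch": mismatch,
        },
        index=forcing.index,
    )


def simulate_closures(truth: pd.DataFrame, scenario: Scenario) -> pd.DataFrame:
    """Chamber-IRGA stream: one row per 5-s sample of each closure.

    Columns: ``closure_id``, ``timestamp``, ``co2`` (ppm), ``h2o``
    (mol m^-3), ``chamber_T`` (degC), ``PAR_CH`` (umol m^-2 s^-1),
    ``pressure`` (kPa).

    The noise-free CO2 slope is -A_NET * leaf_area / n_air with
    n_air = P V / (R T_K) mol of chamber air, so integrating the trace
    recovers the imposed flux exactly when inflow is off; H2O rises at
    E * leaf_area / V in molar-density units. With a finite inflow time
    constant tau the deviation relaxes as s*tau*(1 - exp(-t/tau)).
    """
    rng = _rng(scenario, 1)
    noise = scenario.noise
    rel_t = np.arange(scenario.n_samples_per_closure, dtype=float) * scenario.sample_interval_s
    tau = scenario.inflow_time_constant_s
    frames = []
    for cycle_idx, (t0, row) in enumerate(truth.iterrows()):
        t_k = row["temp"] + T_KELVIN
        n_air = scenario.pressure_kpa * 1000.0 * scenario.chamber_volume_m3 / (R_GAS * t_k)
        s_co2 = -row["a_net"] * scenario.leaf_area_m2 / n_air  # ppm s^-1
        s_h2o = row["e"] * 1e-3 * scenario.leaf_area_m2 / scenario.chamber_volume_m3
        if tau is None:
            dev = rel_t
        else:
            dev = tau * -np.expm1(-rel_t / tau)
        co2 = scenario.co2_ambient_ppm + s_co2 * dev
        h2o = row["n_h2o_ambient"] + s_h2o * dev
        if noise.co2_ppm:
            co2 = co2 + rng.normal(0.0, noise.co2_ppm, co2.shape)
        if noise.h2o_mol_m3:
            h2o = h2o + rng.normal(0.0, noise.h2o_mol_m3, h2o.shape)
        par_ch = row["par"] + (rng.normal(0.0, noise.par) if noise.par else 0.0)
        frames.append(
            pd.DataFrame(
                {
                    "closure_id": cycle_idx,
                    "timestamp": t0 + pd.to_timedelta(rel_t, unit="s"),
                    "co2": co2,
                    "h2o": h2o,
                    "chamber_T": row["temp"],
                    "PAR_CH": max(par_ch, 0.0),
                    "pressure": scenario.pressure_kpa,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_pam(truth: pd.DataFrame, scenario: Scenario) -> pd.DataFrame:
    """PAM fluorometer stream: one row per measurement cycle.

    Columns: ``timestamp`` (cycle time plus the clock-drift offset),
    ``F_prime``, ``F_M_prime`` (instrument units) and ``PAR_MICRO``
    (umol m^-2 s^-1). F' and F_M' share the multiplicative gain (and the
    optional step artifact), which cancels in 1 - F'/F_M'; injected
    light-mismatch cycles shade PAR_MICRO by ``light_mismatch_factor``.
    """
    rng = _rng(scenario, 2)
    noise = scenario.noise
    times = truth.index
    gain = np.full(len(times), scenario.pam_gain)
    if scenario.gain_step is not None:
        step_time, factor = scenario.gain_step
        gain = np.where(times >= step_time, gain * factor, gain)
    f_m = scenario.f_m_base * gain
    f_prime = f_m * (1.0 - truth["yii"].to_numpy())
    if noise.fluorescence:
        f_m = f_m + rng.normal(0.0, noise.fluorescence, f_m.shape)
        f_prime = f_prime + rng.normal(0.0, noise.fluorescence, f_prime.shape)
    par_micro = truth["par"].to_numpy().copy()
    shade = truth["light_mismatch"].to_numpy()
    par_micro[shade] *= scenario.light_mismatch_factor
    if noise.par:
        par_micro = par_micro + rng.normal(0.0, noise.par, par_micro.shape)
    stamps = times + pd.to_timedelta(truth["clock_offset_s"].to_numpy(), unit="s")
    return pd.DataFrame(
        {
            "timestamp": stamps,
            "F_prime": f_prime,
            "F_M_prime": f_m,
            "PAR_MICRO": np.clip(par_micro, 0.0, None),
        }
    )


@dataclass
class CampaignData:
    """One simulated campaign: ground truth plus the two instrument streams."""

    scenario: Scenario
    truth: pd.DataFrame
    chamber: pd.DataFrame
    pam: pd.DataFrame


def simulate_campaign(scenario: Scenario) -> CampaignData:
    """Run the full generative chain for one scenario."""
    forcing = simulate_forcing(scenario)
    truth = simulate_leaf(forcing, scenario)
    chamber = simulate_closures(truth, scenario)
    pam = simulate_pam(truth, scenario)
    return CampaignData(scenario=scenario, truth=truth, chamber=chamber, pam=pam)


def write_campaign(campaign: CampaignData, out_dir: str | Path) -> dict[str, Path]:
    """Write chamber.csv, pam.csv and ground_truth.csv (test use) to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "chamber": out / "chamber.csv",
        "pam": out / "pam.csv",
        "ground_truth": out / "ground_truth.csv",
    }
    campaign.chamber.to_csv(paths["chamber"], index=False, date_format="%Y-%m-%dT%H:%M:%S.%f")
    campaign.pam.to_csv(paths["pam"], index=False, date_format="%Y-%m-%dT%H:%M:%S.%f")
    campaign.truth.rename_axis("timestamp").to_csv(
        paths["ground_truth"], date_format="%Y-%m-%dT%H:%M:%S.%f"
    )
    return paths
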