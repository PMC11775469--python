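"""Chamber-closure flux estimation.

Each chamber closure yields a short concentration-vs-time trace for CO2
and H2O; the net CO2 assimilation (A_NET) and transpiration (E) per leaf
area follow from the rate of concentration change, the chamber air content
(ideal gas law) and the enclosed leaf area. The default estimator is the
ordinary least-squares slope of the retained samples after a mixing-lag
discard; an opt-in mass-balance fit handles non-hermetic chambers by
fitting the first-order exponential approach and reporting its initial
rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .micromet import R_GAS, T_KELVIN

#: Seconds of each closure discarded before fitting (fan-mixing transient).
DEFAULT_LAG_DISCARD_S = 10.0

#: Minimum number of retained samples for a slope fit.
MIN_SAMPLES = 4

H2O_UNITS = ("mol_m3", "mmol_mol")


class InsufficientDataError(ValueError):
    """Fewer than MIN_SAMPLES usable samples remain in a closure trace."""


class UnitError(ValueError):
    """Missing or unknown concentration unit tag."""


@dataclass(frozen=True)
class ClosureTrace:
    """One chamber-closure event.

    ``sample_times`` are seconds since closure start; ``co2`` is in ppm
    (umol mol^-1) and ``h2o`` in the unit named by ``h2o_unit`` —
    ``"mol_m3"`` (molar density) or ``"mmol_mol"`` (mole fraction).
    """

    closure_start: pd.Timestamp
    sample_times: np.ndarray
    co2: np.ndarray
    h2o: np.ndarray
    chamber_T: float  # degC
    pressure: float  # kPa
    chamber_volume: float  # m^3
    leaf_area: float  # m^2
    h2o_unit: str = "mol_m3"
    par_ch: float = np.nan

    def __post_init__(self) -> None:
        t = np.asarray(self.sample_times, dtype=float)
        object.__setattr__(self, "sample_times", t)
        object.__setattr__(self, "co2", np.asarray(self.co2, dtype=float))
        object.__setattr__(self, "h2o", np.asarray(self.h2o, dtype=float))
        if len(t) != len(self.co2) or len(t) != len(self.h2o):
            raise ValueError("sample_times, co2 and h2o must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("sample_times must be strictly increasing")
        if self.chamber_volume <= 0 or self.leaf_area <= 0:
            raise ValueError("chamber_volume and leaf_area must be > 0")
        if self.chamber_T <= -T_KELVIN:
            raise ValueError("chamber_T must exceed absolute zero")
        if self.h2o_unit not in H2O_UNITS:
            raise UnitError(f"h2o_unit must be one of {H2O_UNITS}")

    def concentration(self, gas: str) -> np.ndarray:
        if gas == "co2":
            return self.co2
        if gas == "h2o":
            return self.h2o
        raise ValueError("gas must be 'co2' or 'h2o'")


@dataclass(frozen=True)
class SlopeFit:
    """OLS (or mass-balance) fit diagnostics for one gas in one closure."""

    slope: float  # concentration unit per second
    stderr: float
    r_squared: float
    n_samples: int
    intercept: float  # concentration at t = 0, extrapolated
    method: str = "linear"
    tau: Optional[float] = None  # inflow time constant (mass_balance only)
    flags: tuple = field(default=())


def _retained(trace: ClosureTrace, gas: str, lag_discard: float):
    conc = trace.concentration(gas)
    keep = trace.sample_times >= lag_discard
    finite = np.isfinite(conc)
    flags = () if finite.all() else ("nonfinite_samples",)
    keep &= finite
    if keep.sum() < MIN_SAMPLES:
        raise InsufficientDataError(
            f"only {int(keep.sum())} usable samples after lag discard (need {MIN_SAMPLES})"
        )
    return trace.sample_times[keep], conc[keep], flags


def fit_closure_slope(
    trace: ClosureTrace, gas: str, lag_discard: float = DEFAULT_LAG_DISCARD_S
) -> SlopeFit:
    """OLS slope of concentration vs. time over the retained samples.

    The first ``lag_discard`` seconds are dropped (fan-mixing transient);
    non-finite samples are excluded and flagged. Raises
    :class:`InsufficientDataError` when fewer than 4 samples remain.
    """
    t, c, flags = _retained(trace, gas, lag_discard)
    res = stats.linregress(t, c)
    fitted = res.intercept + res.slope * t
    ss_res = float(np.sum((c - fitted) ** 2))
    ss_tot = float(np.sum((c - c.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0.0 and ss_res <= 1e-30 else (1.0 - ss_res / ss_tot if ss_tot else 0.0)
    return SlopeFit(
        slope=float(res.slope),
        stderr=float(res.stderr),
        r_squared=r2,
        n_samples=len(t),
        intercept=float(res.intercept),
        method="linear",
        flags=flags,
    )


def fit_mass_balance(
    trace: ClosureTrace,
    gas: str,
    ambient_concentration: Optional[float] = None,
    inflow_time_constant: Optional[float] = None,
    lag_discard: float = DEFAULT_LAG_DISCARD_S,
) -> SlopeFit:
    """Initial-rate slope from a first-order mass-balance fit.

    Fits c(t) = c0 + s * tau * (1 - exp(-t/tau)) — the solution of
    dc/dt = s + (c_amb - c)/tau with c(0) = c_amb — and returns the initial
    rate ``s``. ``ambient_concentration`` seeds c0 (first sample used as
    fallback); ``inflow_time_constant`` seeds tau. Falls back to the linear
    fit with an ``mass_balance_fallback`` flag when the nonlinear fit does
    not converge.
    """
    t, c, flags = _retained(trace, gas, lag_discard)
    lin = stats.linregress(t, c)
    c0_guess = ambient_concentration if ambient_concentration is not None else float(c[0])
    tau_guess = inflow_time_constant if inflow_time_constant is not None else 60.0

    def model(tt, c0, s, tau):
        return c0 + s * tau * -np.expm1(-tt / tau)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = optimize.curve_fit(
                model,
                t,
                c,
                p0=(c0_guess, lin.slope if lin.slope != 0 else 1e-6, tau_guess),
                bounds=([-np.inf, -np.inf, 1e-3], [np.inf, np.inf, 1e9]),
                maxfev=10000,
            )
        c0, s, tau = popt
        fitted = model(t, *popt)
        ss_res = float(np.sum((c - fitted) ** 2))
        ss_tot = float(np.sum((c - c.mean()) ** 2))
        r2 = 1.0 if ss_tot == 0.0 and ss_res <= 1e-30 else (
            1.0 - ss_res / ss_tot if ss_tot else 0.0
        )
        stderr = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else np.nan
        return SlopeFit(
            slope=float(s),
            stderr=stderr,
            r_squared=r2,
            n_samples=len(t),
            intercept=float(c0),
            method="mass_balance",
            tau=float(tau),
            flags=flags,
        )
    except (RuntimeError, ValueError):
        fitted = lin.intercept + lin.slope * t
        ss_tot = float(np.sum((c - c.mean()) ** 2))
        ss_res = float(np.sum((c - fitted) ** 2))
        r2 = 1.0 if ss_tot == 0.0 and ss_res <= 1e-30 else (
            1.0 - ss_res / ss_tot if ss_tot else 0.0
        )
        return SlopeFit(
            slope=float(lin.slope),
            stderr=float(lin.stderr),
            r_squared=r2,
            n_samples=len(t),
            intercept=float(lin.intercept),
            method="linear",
            flags=flags + ("mass_balance_fallback",),
        )


def chamber_air_moles(pressure_kpa: float, volume_m3: float, temp_c: float) -> float:
    """Moles of air in the chamber from the ideal gas law, n = P V / (R T_K)."""
    return pressure_kpa * 1000.0 * volume_m3 / (R_GAS * (temp_c + T_KELVIN))


def slope_to_flux(slope: float, trace: ClosureTrace, gas: str) -> float:
    """Convert a concentration slope to a per-leaf-area flux.

    CO2: slope in ppm s^-1 (umol per mol of chamber air per second) times
    the chamber air content (mol) gives umol s^-1; sign is flipped so CO2
    drawdown yields positive A_NET (umol m^-2 s^-1, uptake positive).

    H2O: molar-density slopes (mol m^-3 s^-1) are multiplied by the chamber
    volume; mole-fraction slopes (mmol mol^-1 s^-1) by the chamber air
    content. Build-up yields positive E (mmol m^-2 s^-1, efflux positive).
    """
    if gas == "co2":
        n_air = chamber_air_moles(trace.pressure, trace.chamber_volume, trace.chamber_T)
        return -slope * n_air / trace.leaf_area
    if gas == "h2o":
        if trace.h2o_unit == "mol_m3":
            return slope * trace.chamber_volume / trace.leaf_area * 1e3
        if trace.h2o_unit == "mmol_mol":
            n_air = chamber_air_moles(trace.pressure, trace.chamber_volume, trace.chamber_T)
            return slope * n_air / trace.leaf_area
        raise UnitError(f"unknown h2o unit {trace.h2o_unit!r}")
    raise ValueError("gas must be 'co2' or 'h2o'")


#: Plausibility windows for flagging, not rejecting, odd chamber states.
PLAUSIBLE_T_C = (-40.0, 60.0)
PLAUSIBLE_P_KPA = (50.0, 110.0)


def traces_from_stream(
    stream: pd.DataFrame,
    *,
    chamber_volume: float,
    leaf_area: float,
    pressure: Optional[float] = None,
    h2o_unit: str = "mol_m3",
) -> list[ClosureTrace]:
    """Group a chamber stream table into ClosureTrace objects.

    The stream has one row per 5-s sample with columns ``closure_id``,
    ``timestamp``, ``co2``, ``h2o``, ``chamber_T``, ``PAR_CH`` and either a
    ``pressure`` column or a per-file ``pressure`` argument.
    """
    traces = []
    for _, grp in stream.groupby("closure_id", sort=True):
        t0 = grp["timestamp"].iloc[0]
        rel = (grp["timestamp"] - t0).dt.total_seconds().to_numpy()
        p = float(grp["pressure"].iloc[0]) if "pressure" in grp.columns else pressure
        if p is None:
            raise UnitError("pressure must be supplied per-file or per-row")
        traces.append(
            ClosureTrace(
                closure_start=t0,
                sample_times=rel,
                co2=grp["co2"].to_numpy(),
                h2o=grp["h2o"].to_numpy(),
                chamber_T=float(grp["chamber_T"].mean()),
                pressure=p,
                chamber_volume=chamber_volume,
                leaf_area=leaf_area,
                h2o_unit=h2o_unit,
                par_ch=float(grp["PAR_CH"].mean()),
            )
        )
    return traces


def process_chamber_stream(
    stream: pd.DataFrame,
    *,
    chamber_volume: float,
    leaf_area: float,
    pressure: Optional[float] = None,
    h2o_unit: str = "mol_m3",
    lag_discard: float = DEFAULT_LAG_DISCARD_S,
    method: str = "linear",
    inflow_time_constant: Optional[float] = None,
) -> pd.DataFrame:
    """Derive one gas-exchange record per closure from a chamber stream.

    Returns a table with columns ``timestamp``, ``A_NET``, ``E``,
    ``chamber_T``, ``PAR_CH``, ``pressure``, ``h2o_ambient_mol_m3`` (the
    fitted trace intercept at closure start, i.e. the pre-closure ambient
    vapour density) and per-gas fit diagnostics
    ``{co2,h2o}_slope``, ``_slope_se``, ``_r2``, ``_n`` plus ``method`` and
    ``flagged`` (implausible T or P, or fit-level flags).
    """
    if method not in ("linear", "mass_balance"):
        raise ValueError("method must be 'linear' or 'mass_balance'")
    rows = []
    for trace in traces_from_stream(
        stream,
        chamber_volume=chamber_volume,
        leaf_area=leaf_area,
        pressure=pressure,
        h2o_unit=h2o_unit,
    ):
        fits = {}
        for gas in ("co2", "h2o"):
            if method == "mass_balance":
                fits[gas] = fit_mass_balance(
                    trace, gas, inflow_time_constant=inflow_time_constant, lag_discard=lag_discard
                )
            else:
                fits[gas] = fit_closure_slope(trace, gas, lag_discard=lag_discard)
        a_net = slope_to_flux(fits["co2"].slope, trace, "co2")
        e = slope_to_flux(fits["h2o"].slope, trace, "h2o")
        if trace.h2o_unit == "mol_m3":
            h2o_ambient = fits["h2o"].intercept
        else:  # mole fraction mmol/mol -> mol m^-3 via ideal gas
            h2o_ambient = (
                fits["h2o"].intercept
                * 1e-3
                * trace.pressure
                * 1000.0
                / (R_GAS * (trace.chamber_T + T_KELVIN))
            )
        flagged = bool(fits["co2"].flags or fits["h2o"].flags)
        flagged |= not (PLAUSIBLE_T_C[0] <= trace.chamber_T <= PLAUSIBLE_T_C[1])
        flagged |= not (PLAUSIBLE_P_KPA[0] <= trace.pressure <= PLAUSIBLE_P_KPA[1])
        rows.append(
            {
                "timestamp": trace.closure_start,
                "A_NET": a_net,
                "E": e,
                "chamber_T": trace.chamber_T,
                "PAR_CH": trace.par_ch,
                "pressure": trace.pressure,
                "h2o_ambient_mol_m3": h2o_ambient,
                "co2_slope": fits["co2"].slope,
                "co2_slope_se": fits["co2"].stderr,
                "co2_r2": fits["co2"].r_squared,
                "co2_n": fits["co2"].n_samples,
                "h2o_slope": fits["h2o"].slope,
                "h2o_slope_se": fits["h2o"].stderr,
                "h2o_r2": fits["h2o"].r_squared,
                "h2o_n": fits["h2o"].n_samples,
                "method": fits["co2"].method,
                "flagged": flagged,
            }
        )
    return pd.DataFrame(rows)
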