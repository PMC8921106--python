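"""Forward and reverse dosimetry and kinetic summary statistics.

Reverse dosimetry inverts the model: given a steady-state blood
concentration (the biomarker epidemiological studies measure), find the
constant external oral dose that produces it.  At environmentally relevant
concentrations the model is linear, so the inversion is a single division
by the unit steady-state response; outside the linear regime a damped
fixed-point/bisection search is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import linregress

from .core import simulate, steady_state_concentrations, SimulationResult
from .exposure import repeated_daily_oral, HOURS_PER_DAY
from .parameters import PBPKParameters
from .physiology import SpeciesPhysiology

__all__ = ["ReverseDoseResult", "reverse_dose", "terminal_half_life",
           "excretion_fractions", "washout_simulation"]

_RESIDUAL_TOL = 1e-3  # relative, on the target concentration
_LINEARITY_TOL = 1e-2
_MAX_ITER = 60


@dataclass
class ReverseDoseResult:
    target_blood_ug_per_L: float
    dose_ug_per_kg_per_day: float
    converged: bool
    linear: bool
    residual_ug_per_L: float
    exposure_days: float


def _css(dose: float, params, physiology, exposure_days, solver_options):
    return steady_state_concentrations(
        dose, params, physiology, exposure_days,
        solver_options=solver_options).concentrations["blood_total"]


def reverse_dose(target_css_ug_per_L: float,
                 params: PBPKParameters,
                 physiology: SpeciesPhysiology,
                 exposure_days: float = 1000.0,
                 probe_dose: float = 0.01,
                 solver_options: dict | None = None) -> ReverseDoseResult:
    """External oral dose (ug/kg bw/day) producing a steady-state blood
    concentration of ``target_css_ug_per_L`` after ``exposure_days`` of
    constant exposure.
    """
    if target_css_ug_per_L < 0:
        raise ValueError("target concentration must be non-negative")
    if target_css_ug_per_L == 0:
        return ReverseDoseResult(0.0, 0.0, True, True, 0.0, exposure_days)

    c1 = _css(probe_dose, params, physiology, exposure_days, solver_options)
    if c1 <= 0:
        raise RuntimeError("probe dose produced no blood concentration; "
                           "check absorption parameters")
    slope = c1 / probe_dose
    c2 = _css(2.0 * probe_dose, params, physiology, exposure_days, solver_options)
    linear = abs(c2 / (2.0 * c1) - 1.0) <= _LINEARITY_TOL

    dose = target_css_ug_per_L / slope
    for _ in range(_MAX_ITER):
        c = _css(dose, params, physiology, exposure_days, solver_options)
        resid = c - target_css_ug_per_L
        if abs(resid) <= _RESIDUAL_TOL * target_css_ug_per_L:
            return ReverseDoseResult(target_css_ug_per_L, dose, True, linear,
                                     float(resid), exposure_days)
        if c <= 0:
            dose *= 2.0  # expand until the target is enclosed
            continue
        dose *= target_css_ug_per_L / c  # monotone fixed-point update
    return ReverseDoseResult(target_css_ug_per_L, dose, False, linear,
                             float(resid), exposure_days)


def terminal_half_life(result: SimulationResult,
                       window_days: tuple[float, float]) -> float:
    """Terminal blood half-life (days) by log-linear regression on a window.

    The blood concentration must be strictly positive and decreasing on the
    window and the window must contain at least five grid points.
    """
    t_start, t_end = window_days
    t = result.time_days
    mask = (t >= t_start) & (t <= t_end)
    if mask.sum() < 5:
        raise ValueError("window contains fewer than 5 grid points")
    conc = result.blood_concentration()[mask]
    if np.any(conc <= 0):
        raise ValueError("blood concentration not strictly positive on the window")
    if np.any(np.diff(conc) >= 0):
        raise ValueError("blood concentration not monotonically decreasing on "
                         "the window; choose a later window")
    fit = linregress(t[mask], np.log(conc))
    return float(np.log(2.0) / abs(fit.slope))


def excretion_fractions(result: SimulationResult,
                        t_days: float) -> tuple[float, float]:
    """Cumulative (faecal %, urinary %) of the administered dose at ``t_days``."""
    t_h = t_days * HOURS_PER_DAY
    state = result.at_time(t_h)
    from .core import StateIndex as S
    admin = state[S.ADMIN_CUM]
    if admin <= 0:
        return 0.0, 0.0
    return (100.0 * state[S.FAECES] / admin,
            100.0 * state[S.URINE] / admin)


def washout_simulation(dose_ug_per_kg_per_day: float,
                       params: PBPKParameters,
                       physiology: SpeciesPhysiology,
                       exposure_days: float = 1000.0,
                       washout_days: float = 900.0,
                       n_points: int = 800,
                       solver_options: dict | None = None) -> SimulationResult:
    """Chronic oral exposure followed by washout, for half-life estimation."""
    total_h = (exposure_days + washout_days) * HOURS_PER_DAY
    scenario = repeated_daily_oral(dose_ug_per_kg_per_day, 0.0,
                                   exposure_days * HOURS_PER_DAY,
                                   species=physiology.species)
    grid = np.linspace(0.0, total_h, n_points)
    return simulate(scenario, params, physiology, total_h, grid,
                    solver_options=solver_options)
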