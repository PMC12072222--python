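"""Victim-perpetrator coupling: control vs treatment simulation and ratios.

The engine simulates the victim (endogenous biomarker or dosed drug) with
and without a perpetrator and reports the treatment/control ratios of peak
concentration (CmaxR) and area under the curve (AUCR) over an explicit
window.  For the endogenous biomarker the control arm is its baseline steady
state, which is also the treatment arm's initial condition.

Two static (constant-exposure) oracles accompany the dynamic engine:

* :func:`static_ratio` — the flow-aware well-stirred ratio
  ``CL_total(control) / CL_total(inhibited)``, which the dynamic model
  converges to under constant inhibitor exposure;
* :func:`static_aucr_uptake_limited` — the classical static DDI formula
  ``1 / (sum ft_i/(1+Iu/Ki) + 1 - sum ft_i)``, exact only when hepatic
  uptake, not blood flow, is rate-determining.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import core
from .exceptions import (
    AmbiguousVictimError,
    CalibrationError,
    InvalidParameterError,
)
from .params import (
    DosingRegimen,
    InhibitorParams,
    PhysiologyRef,
    VictimParams,
)
from .perpetrator import inhibition_ratio_fn

__all__ = [
    "DDIOutcome",
    "inhibited_clint",
    "exposure_metrics",
    "simulate_ddi",
    "static_ratio",
    "static_aucr_uptake_limited",
    "aucr_ceiling",
]

DEFAULT_GRID_DT = 0.05  # h; well under the 0.1 h output requirement


@dataclass(frozen=True)
class DDIOutcome:
    """Paired control/treatment interaction metrics over a window."""

    cmax_ratio: float
    auc_ratio: float
    window: tuple[float, float]
    tmax_biomarker: float  # h, treatment-arm Tmax within the window
    control_metrics: tuple[float, float, float]  # (Cmax, Tmax, AUC)
    treatment_metrics: tuple[float, float, float]
    times: np.ndarray | None = None  # full simulation grid, h
    conc_control: np.ndarray | None = None  # nM
    conc_treatment: np.ndarray | None = None  # nM


def inhibited_clint(clint: float, iu: float, ki: float) -> float:
    """Competitive inhibition: ``clint / (1 + iu/ki)``."""
    if ki <= 0:
        raise InvalidParameterError("ki must be > 0")
    if iu < 0:
        raise InvalidParameterError("iu must be >= 0")
    return clint / (1.0 + iu / ki)


def exposure_metrics(
    times: Sequence[float],
    conc: Sequence[float],
    window: tuple[float, float],
) -> tuple[float, float, float]:
    """(Cmax, Tmax, AUC) on the sampled grid over ``window``.

    Cmax is the grid maximum; AUC is trapezoidal.  The grid must cover the
    window with at least two points.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(conc, dtype=float)
    lo, hi = window
    if hi <= lo:
        raise InvalidParameterError("window start must precede window end")
    mask = (t >= lo - 1e-9) & (t <= hi + 1e-9)
    if mask.sum() < 2:
        raise InvalidParameterError("grid does not cover the requested window")
    tw, cw = t[mask], c[mask]
    i = int(np.argmax(cw))
    return float(cw[i]), float(tw[i]), float(np.trapezoid(cw, tw))


def _require_calibrated(victim: VictimParams) -> None:
    if victim.hepatic_scaler_gamma is None:
        raise CalibrationError(
            "victim model is uncalibrated: set hepatic_scaler_gamma "
            "(via calibrate_hepatic_scaler) before simulating interactions"
        )


def simulate_ddi(
    victim: VictimParams,
    inhibitor: InhibitorParams,
    regimen: DosingRegimen,
    phys: PhysiologyRef,
    window: tuple[float, float],
    victim_regimen: DosingRegimen | None = None,
    grid_dt: float = DEFAULT_GRID_DT,
    keep_profiles: bool = True,
) -> DDIOutcome:
    """Simulate control and treatment arms and compute CmaxR / AUCR.

    For the endogenous biomarker (``k_syn > 0``) both arms start from the
    control steady state, so the control arm is a flat baseline.  A dosed
    victim (``k_syn == 0``) instead requires ``victim_regimen``; both arms
    then start drug-free.  Supplying both synthesis and dosing is ambiguous
    and raises.
    """
    _require_calibrated(victim)
    if victim.k_syn > 0 and victim_regimen is not None:
        raise AmbiguousVictimError(
            "victim has both endogenous synthesis (k_syn > 0) and a dosing "
            "regimen; zero one of them"
        )
    if victim.k_syn == 0 and victim_regimen is None:
        raise InvalidParameterError(
            "a dosed victim (k_syn == 0) needs a victim_regimen"
        )
    lo, hi = window
    if hi <= lo or lo < 0:
        raise InvalidParameterError("invalid interaction window")

    n = int(np.ceil(hi / grid_dt)) + 1
    t_eval = np.unique(np.concatenate([np.linspace(0.0, hi, n), [lo, hi]]))
    breakpoints = [t for t in regimen.dose_times if 0.0 < t < hi]

    if victim.k_syn > 0:
        y0 = core.steady_state_amounts(victim, phys)
        dose_events: tuple[tuple[float, float], ...] = ()
    else:
        y0 = np.zeros(3)
        dose_events = tuple(
            (t, victim_regimen.dose * 1e6 / victim.molecular_weight)
            for t in victim_regimen.dose_times
            if t <= hi
        )

    inh_fn = inhibition_ratio_fn(inhibitor, regimen, phys) if regimen.dose > 0 else None

    if victim.k_syn > 0:
        css = y0[0] / phys.v_central_plasma
        conc_control = np.full(len(t_eval), css)
    else:
        states_c = core.simulate_victim(
            victim, phys, t_eval, y0=y0, dose_events=dose_events
        )
        conc_control = states_c[:, 0] / phys.v_central_plasma

    if inh_fn is None:
        conc_treat = conc_control.copy()
    else:
        states_t = core.simulate_victim(
            victim,
            phys,
            t_eval,
            y0=y0,
            inhibition_fn=inh_fn,
            breakpoints=breakpoints,
            dose_events=dose_events,
        )
        conc_treat = states_t[:, 0] / phys.v_central_plasma

    cm_c = exposure_metrics(t_eval, conc_control, window)
    cm_t = exposure_metrics(t_eval, conc_treat, window)
    return DDIOutcome(
        cmax_ratio=cm_t[0] / cm_c[0],
        auc_ratio=cm_t[2] / cm_c[2],
        window=(lo, hi),
        tmax_biomarker=cm_t[1],
        control_metrics=cm_c,
        treatment_metrics=cm_t,
        times=t_eval if keep_profiles else None,
        conc_control=conc_control if keep_profiles else None,
        conc_treatment=conc_treat if keep_profiles else None,
    )


def static_ratio(
    victim: VictimParams,
    phys: PhysiologyRef,
    inhibition: Mapping[str, float],
) -> float:
    """Constant-exposure clearance ratio (flow-aware well-stirred oracle).

    Equals the steady-state AUCR (and CmaxR) the dynamic model approaches
    when the inhibitor exposure is held constant at the given Iu/Ki map.
    """
    _require_calibrated(victim)
    cl0 = core.total_plasma_clearance(victim, phys)
    cli = core.total_plasma_clearance(victim, phys, inhibition)
    return cl0 / cli


def static_aucr_uptake_limited(
    ft: Mapping[str, float],
    iu_over_ki: Mapping[str, float],
) -> float:
    """Classical static DDI formula on pathway fractions.

    ``1 / (sum_T ft_T/(1+r_T) + 1 - sum_T ft_T)`` over the inhibited
    pathways.  Valid when uptake is rate-determining (no flow limitation);
    provided as the textbook reference, not as the engine's oracle.
    """
    inhibited = {t: r for t, r in iu_over_ki.items() if t in ft}
    ft_inh = sum(ft[t] for t in inhibited)
    term = sum(ft[t] / (1.0 + r) for t, r in inhibited.items())
    return 1.0 / (term + 1.0 - ft_inh)


def aucr_ceiling(victim: VictimParams, phys: PhysiologyRef) -> float:
    """Largest attainable steady-state AUCR under complete OATP1B blockade."""
    huge = {t: 1e12 for t in victim.cl_uptake_per_cell}
    return static_ratio(victim, phys, huge)
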