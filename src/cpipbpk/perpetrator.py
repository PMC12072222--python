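"""Perpetrator (inhibitor) pharmacokinetics.

Linear first-order absorption into a 1- or 2-compartment disposition model,
solved analytically by eigendecomposition of the transfer matrix and
superposed across doses.  The quantity that drives OATP1B inhibition is the
unbound concentration at the liver inlet,

    Iu(t) = fu_plasma * ( C_sys,plasma(t) + ka * A_gut(t) / Q_portal,plasma ),

i.e. systemic exposure plus the first-pass absorption flux diluted into
portal plasma flow.  During absorption the inlet therefore exceeds the
systemic unbound concentration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np

from .exceptions import InvalidParameterError
from .params import DosingRegimen, InhibitorParams, PhysiologyRef

__all__ = [
    "ExposureProfile",
    "simulate_inhibitor_pk",
    "unbound_inlet_concentration",
    "half_life",
    "inlet_unbound_fn",
    "inhibition_ratio_fn",
]


@dataclass(frozen=True)
class ExposureProfile:
    """Simulated inhibitor exposure on a time grid."""

    times: np.ndarray  # h
    conc_systemic_plasma: np.ndarray  # uM
    conc_inlet_unbound: np.ndarray  # uM
    cmax: float  # uM, systemic plasma
    tmax: float  # h
    auc_window: float  # uM*h over the simulated span


def _transfer_matrix(p: InhibitorParams) -> np.ndarray:
    """Amount-space transfer matrix over (gut, central, peripheral)."""
    vp = p.v_peripheral if p.q_inter > 0 else 1.0
    return np.array(
        [
            [-p.ka, 0.0, 0.0],
            [p.ka, -(p.cl_over_f + p.q_inter) / p.v_central, p.q_inter / vp],
            [0.0, p.q_inter / p.v_central, -p.q_inter / vp],
        ]
    )


def _unit_dose_weights(p: InhibitorParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Eigen-weights for central and gut amounts after a unit gut dose.

    Returns ``(lams, w_central, w_gut)`` such that for t >= 0 the amounts are
    ``sum_k w_k * exp(lams_k * t)``.  Near-degenerate eigenvalues (e.g. ka
    numerically equal to a disposition rate) are lifted by a relative 1e-9
    nudge of ka, which is far below any parameter's precision.
    """
    params = p
    for _ in range(3):
        m = _transfer_matrix(params)
        lams, vecs = np.linalg.eig(m)
        spread = np.min(
            [abs(a - b) for i, a in enumerate(lams) for b in lams[i + 1 :]]
        )
        if spread > 1e-9 * max(1.0, np.max(np.abs(lams))):
            break
        from dataclasses import replace

        params = replace(params, ka=params.ka * (1 + 1e-9))
    coeff = np.linalg.solve(vecs, np.eye(3)[:, 0])  # unit amount in gut
    w_central = vecs[1, :] * coeff
    w_gut = vecs[0, :] * coeff
    return lams, w_central, w_gut


def _superpose(
    times: np.ndarray,
    dose_amounts_umol: float,
    dose_times: tuple[float, ...],
    lams: np.ndarray,
    weights: np.ndarray,
) -> np.ndarray:
    out = np.zeros(len(times), dtype=complex)
    for td in dose_times:
        dt = times - td
        mask = dt >= 0
        out[mask] += dose_amounts_umol * (
            np.exp(np.outer(dt[mask], lams)) @ weights
        )
    return np.maximum(out.real, 0.0)


def simulate_inhibitor_pk(
    params: InhibitorParams,
    regimen: DosingRegimen,
    t_end: float,
    phys: PhysiologyRef | None = None,
    dt: float = 0.1,
) -> ExposureProfile:
    """Simulate systemic and liver-inlet unbound inhibitor concentrations.

    The grid spacing is at most ``dt`` (default 0.1 h) and always contains
    the dose times.  Exposure metrics (Cmax, Tmax, AUC) refer to systemic
    plasma over the simulated span.
    """
    if t_end <= regimen.start_time:
        raise InvalidParameterError("t_end must cover the dosing regimen")
    phys = phys or PhysiologyRef.reference()
    n = int(np.ceil(t_end / dt)) + 1
    times = np.unique(
        np.concatenate(
            [np.linspace(0.0, t_end, n), [t for t in regimen.dose_times if t <= t_end]]
        )
    )
    dose_umol = regimen.dose * params.f_abs * 1e3 / params.molecular_weight
    lams, w_central, w_gut = _unit_dose_weights(params)
    amount_central = _superpose(times, dose_umol, regimen.dose_times, lams, w_central)
    amount_gut = _superpose(times, dose_umol, regimen.dose_times, lams, w_gut)
    conc = amount_central / params.v_central
    inlet = params.fu_plasma * (conc + params.ka * amount_gut / phys.q_portal_plasma)
    i_max = int(np.argmax(conc))
    return ExposureProfile(
        times=times,
        conc_systemic_plasma=conc,
        conc_inlet_unbound=inlet,
        cmax=float(conc[i_max]),
        tmax=float(times[i_max]),
        auc_window=float(np.trapezoid(conc, times)),
    )


def unbound_inlet_concentration(
    conc_systemic_plasma: float,
    params: InhibitorParams,
    phys: PhysiologyRef,
    absorption_amount_mg: float,
) -> float:
    """Unbound liver-inlet concentration (uM) at one profile point.

    ``absorption_amount_mg`` is the drug amount remaining in the absorption
    depot (already corrected for f_abs at dosing time).
    """
    amount_umol = absorption_amount_mg * 1e3 / params.molecular_weight
    return params.fu_plasma * (
        conc_systemic_plasma + params.ka * amount_umol / phys.q_portal_plasma
    )


def half_life(params: InhibitorParams) -> float:
    """Terminal half-life (h) from the disposition eigenvalues."""
    if params.q_inter == 0:
        return np.log(2.0) * params.v_central / params.cl_over_f
    m = _transfer_matrix(params)[1:, 1:]
    lams = np.linalg.eigvals(m)
    slow = np.min(np.abs(np.real(lams)))
    return float(np.log(2.0) / slow)


def inlet_unbound_fn(
    params: InhibitorParams,
    regimen: DosingRegimen,
    phys: PhysiologyRef,
) -> Callable[[float], float]:
    """Scalar callable t (h) -> unbound liver-inlet concentration (uM)."""
    dose_umol = regimen.dose * params.f_abs * 1e3 / params.molecular_weight
    lams, w_central, w_gut = _unit_dose_weights(params)
    dose_times = np.array(regimen.dose_times)
    fu = params.fu_plasma
    ka = params.ka
    vc = params.v_central
    qpp = phys.q_portal_plasma

    def iu(t: float) -> float:
        dt = t - dose_times
        mask = dt >= 0
        if not mask.any():
            return 0.0
        e = np.exp(np.outer(dt[mask], lams))
        central = dose_umol * float(np.real(e @ w_central).sum())
        gut = dose_umol * float(np.real(e @ w_gut).sum())
        return fu * (max(central, 0.0) / vc + ka * max(gut, 0.0) / qpp)

    return iu


def inhibition_ratio_fn(
    params: InhibitorParams,
    regimen: DosingRegimen,
    phys: PhysiologyRef,
) -> Callable[[float], Mapping[str, float]]:
    """Callable t -> {transporter: Iu/Ki} driving victim uptake inhibition."""
    iu = inlet_unbound_fn(params, regimen, phys)
    ki = dict(params.ki)

    def ratios(t: float) -> dict[str, float]:
        x = iu(t)
        return {name: x / k for name, k in ki.items()}

    return ratios
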