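"""Virtual-inhibitor trial design: CmaxR vs AUCR as monitoring metrics.

Four virtual OATP1B inhibitors spanning potency (weak/moderate/strong, set
by the steady-state unbound inlet Cmax relative to Ki) and half-life
(short ~4 h, long ~30 h) are dosed once daily to steady state, and the
biomarker's CmaxR and AUCR on the steady-state dosing day are compared.
A short half-life makes inhibitor exposure — and hence biomarker elevation —
strongly fluctuating within the day, so CmaxR exceeds AUCR and is the more
sensitive monitoring metric; with a long half-life exposure is sustained and
the two metrics agree.  Sparse-sampling error quantifies how much of the
peak ratio is missed when the single sample deviates from the biomarker's
Tmax.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import ddi
from .exceptions import InvalidParameterError, SteadyStateError
from .params import (
    DosingRegimen,
    InhibitorParams,
    PhysiologyRef,
    VictimParams,
)
from .perpetrator import half_life, simulate_inhibitor_pk

__all__ = [
    "VirtualInhibitorScenario",
    "ScenarioResult",
    "POTENCY_RATIO",
    "make_virtual_inhibitor",
    "default_scenario_grid",
    "simulate_scenario",
    "sparse_sampling_cmaxr",
    "recommend_metric",
]

#: target steady-state unbound inlet Cmax / Ki per potency class
POTENCY_RATIO = {"weak": 0.5, "moderate": 3.0, "strong": 20.0}
#: 1-compartment clearance (L/h) per half-life class; V = 115 L, ka = 1/h
_CLASS_CL = {"short": 20.0, "long": 2.66}
_KI_UM = 0.1  # uM, both OATP1B isoforms


@dataclass(frozen=True)
class VirtualInhibitorScenario:
    potency_class: str
    t_half_class: str
    params: InhibitorParams
    regimen: DosingRegimen

    def __post_init__(self) -> None:
        if self.potency_class not in POTENCY_RATIO:
            raise InvalidParameterError(f"unknown potency class {self.potency_class!r}")
        if self.t_half_class not in _CLASS_CL:
            raise InvalidParameterError(f"unknown t1/2 class {self.t_half_class!r}")

    @property
    def label(self) -> str:
        return f"{self.potency_class}/{self.t_half_class}"


@dataclass(frozen=True)
class ScenarioResult:
    scenario: VirtualInhibitorScenario
    cmax_ratio: float
    auc_ratio: float  # AUCR over the steady-state dosing day (0-24 h)
    tmax: float  # h after the steady-state-day dose
    css_control: float  # nM
    times: np.ndarray  # h, steady-state day, relative to its dose
    conc: np.ndarray  # nM, treatment arm


def make_virtual_inhibitor(
    potency_class: str,
    t_half_class: str,
    phys: PhysiologyRef | None = None,
    interval: float = 24.0,
) -> VirtualInhibitorScenario:
    """Build a virtual inhibitor whose steady-state inlet Cmax/Ki hits the
    class target.

    Disposition is 1-compartment (V 115 L, ka 1/h, fu 0.1) with clearance
    set by the half-life class; linearity lets the dose be solved from a
    single probe simulation.  The number of once-daily doses covers at least
    seven half-lives so the final interval is at steady state.
    """
    phys = phys or PhysiologyRef.reference()
    cl = _CLASS_CL[t_half_class]
    probe = InhibitorParams(
        name=f"virtual-{potency_class}-{t_half_class}",
        molecular_weight=500.0,
        fu_plasma=0.1,
        blood_plasma_ratio=1.0,
        ka=1.0,
        f_abs=1.0,
        cl_over_f=cl,
        v_central=115.0,
        ki={"OATP1B1": _KI_UM, "OATP1B3": _KI_UM},
    )
    t_half = half_life(probe)
    n_doses = max(3, int(np.ceil(7.0 * t_half / interval)) + 1)
    probe_dose = 100.0
    regimen0 = DosingRegimen(dose=probe_dose, interval=interval, n_doses=n_doses)
    prof = simulate_inhibitor_pk(probe, regimen0, n_doses * interval, phys)
    last = prof.times >= (n_doses - 1) * interval
    iu_max = float(prof.conc_inlet_unbound[last].max())
    dose = probe_dose * POTENCY_RATIO[potency_class] * _KI_UM / iu_max
    return VirtualInhibitorScenario(
        potency_class=potency_class,
        t_half_class=t_half_class,
        params=probe,
        regimen=DosingRegimen(dose=dose, interval=interval, n_doses=n_doses),
    )


def default_scenario_grid() -> list[VirtualInhibitorScenario]:
    """The four scenario classes: strong/short, moderate/short, weak/short,
    strong/long."""
    return [
        make_virtual_inhibitor("strong", "short"),
        make_virtual_inhibitor("moderate", "short"),
        make_virtual_inhibitor("weak", "short"),
        make_virtual_inhibitor("strong", "long"),
    ]


def simulate_scenario(
    scn: VirtualInhibitorScenario,
    victim: VictimParams,
    phys: PhysiologyRef | None = None,
) -> ScenarioResult:
    """Steady-state-day CmaxR, AUCR and biomarker profile for one scenario.

    The regimen must span at least seven inhibitor half-lives; steady state
    is certified by a day-over-day change in biomarker AUC below 0.5 %.
    """
    phys = phys or PhysiologyRef.reference()
    t_half = half_life(scn.params)
    regimen = scn.regimen
    span = regimen.interval * regimen.n_doses
    if span < 7.0 * t_half:
        raise InvalidParameterError(
            f"regimen spans {span:.3g} h but steady state needs >= "
            f"{7 * t_half:.3g} h (7 half-lives)"
        )
    tau = regimen.interval
    last_start = (regimen.n_doses - 1) * tau
    out = ddi.simulate_ddi(
        victim, scn.params, regimen, phys, window=(last_start, last_start + tau)
    )
    prev = ddi.exposure_metrics(
        out.times, out.conc_treatment, (last_start - tau, last_start)
    )
    if regimen.dose > 0:
        change = abs(out.treatment_metrics[2] - prev[2]) / out.treatment_metrics[2]
        if change > 0.005:
            raise SteadyStateError(
                f"biomarker AUC still changing {100 * change:.2f} % "
                "day-over-day; extend the regimen"
            )
    mask = out.times >= last_start - 1e-9
    return ScenarioResult(
        scenario=scn,
        cmax_ratio=out.cmax_ratio,
        auc_ratio=out.auc_ratio,
        tmax=out.tmax_biomarker - last_start,
        css_control=out.control_metrics[0],
        times=out.times[mask] - last_start,
        conc=out.conc_treatment[mask],
    )


def sparse_sampling_cmaxr(
    result: ScenarioResult,
    sample_times: "list[float]",
) -> pd.DataFrame:
    """Percent loss of the peak ratio when sampling away from Tmax.

    For a sample drawn at ``t`` (h after the steady-state-day dose) the
    apparent CmaxR uses C(t) instead of the true Cmax; the deviation is
    expressed as the percent reduction of the ratio elevation above control:
    ``100 * (Cmax - C(t)) / (Cmax - css_control)``, 0 % at Tmax by
    construction.
    """
    tmax = result.tmax
    cmax = float(np.interp(tmax, result.times, result.conc))
    floor = result.css_control
    if cmax <= floor:
        raise InvalidParameterError("no biomarker elevation in this scenario")
    rows = []
    for t in sample_times:
        if not 0 <= t <= result.times[-1]:
            raise InvalidParameterError("sample times must lie within the dosing day")
        c = float(np.interp(t, result.times, result.conc))
        rows.append(
            {
                "sample_time_h": t,
                "deviation_pct": 100.0 * (cmax - c) / (cmax - floor),
            }
        )
    return pd.DataFrame(rows)


#: (potency class, t1/2 class) -> (dosing needed for max inhibition,
#: recommended metric, Tmax-sensitivity of a sparse CmaxR estimate)
_RECOMMENDATION = {
    ("strong", "short"): ("single dose", "CmaxR", True),
    ("moderate", "short"): ("single dose", "CmaxR", True),
    ("weak", "short"): ("single dose", "CmaxR and AUCR", False),
    ("strong", "long"): ("multiple dose", "CmaxR and AUCR", False),
}


def recommend_metric(results: "list[ScenarioResult]") -> pd.DataFrame:
    """Per-class study-design recommendation table.

    Requires the full four-class grid; emits the dosing needed to capture
    maximal inhibition, the recommended exposure metric and whether a
    sparse CmaxR estimate is sensitive to missing Tmax, alongside the
    simulated metrics that motivate each row.
    """
    keyed = {(r.scenario.potency_class, r.scenario.t_half_class): r for r in results}
    missing = set(_RECOMMENDATION) - set(keyed)
    if missing:
        raise InvalidParameterError(
            f"scenario grid incomplete; missing classes: {sorted(missing)}"
        )
    rows = []
    for key, (dosing, metric, tmax_sensitive) in _RECOMMENDATION.items():
        r = keyed[key]
        rows.append(
            {
                "potency_class": key[0],
                "t_half_class": key[1],
                "dosing": dosing,
                "recommended_metric": metric,
                "tmax_sensitive": tmax_sensitive,
                "cmaxr": r.cmax_ratio,
                "aucr": r.auc_ratio,
                "cmaxr_minus_aucr_pct": 100.0 * (r.cmax_ratio - r.auc_ratio) / r.auc_ratio,
            }
        )
    return pd.DataFrame(rows)
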