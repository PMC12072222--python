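"""Parameter containers for the CP-I / OATP1B biomarker PBPK model.

The central objects are:

* :class:`VictimParams` — the biomarker (or a dosed victim drug): physical
  chemistry, binding, per-cell transporter intrinsic clearances, renal
  clearance and, for endogenous compounds, a zero-order synthesis rate.
* :class:`PhysiologyRef` — reference-subject physiology (liver size, blood
  flows, compartment volumes) with allometric scaling to other body weights.
* :class:`InhibitorParams` / :class:`DosingRegimen` — perpetrator drug
  disposition and dosing, with per-transporter unbound inhibition constants.

All containers are frozen dataclasses; derived variants are produced with
:func:`dataclasses.replace`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

from .exceptions import InvalidParameterError

__all__ = [
    "VictimParams",
    "PhysiologyRef",
    "InhibitorParams",
    "DosingRegimen",
    "ModelState",
    "BaselineResult",
    "cp1_reference",
    "UPTAKE_TRANSPORTERS",
    "EFFLUX_TRANSPORTERS",
]

#: Sinusoidal uptake transporters recognised by the liver model.
UPTAKE_TRANSPORTERS = ("OATP1B1", "OATP1B3")
#: Canalicular efflux transporters recognised by the liver model.
EFFLUX_TRANSPORTERS = ("MRP2",)

REFERENCE_BODY_WEIGHT = 70.0  # kg


def _check_nonneg(name: str, value: float) -> None:
    if not math.isfinite(value) or value < 0:
        raise InvalidParameterError(f"{name} must be finite and >= 0, got {value!r}")


def _check_pos(name: str, value: float) -> None:
    if not math.isfinite(value) or value <= 0:
        raise InvalidParameterError(f"{name} must be finite and > 0, got {value!r}")


@dataclass(frozen=True)
class PhysiologyRef:
    """Reference-subject physiology for the lumped three-compartment model.

    Flows and whole-liver scaling factors follow an allometric exponent of
    0.75 relative to the 70-kg reference; compartment volumes scale linearly
    with body weight.  ``liver_mass`` carries the clearance exponent so that
    whole-liver intrinsic clearances (per-cell CLint x hepatocellularity x
    liver mass) follow BW^0.75.
    """

    body_weight: float = 70.0  # kg
    liver_mass: float = 1650.0  # g
    hepatocellularity: float = 99.0  # 1e6 cells / g liver
    q_hepatic_blood: float = 87.0  # L/h
    q_portal_blood: float = 66.0  # L/h
    hematocrit: float = 0.45  # fraction
    v_central_plasma: float = 5.0  # L
    v_liver_extracellular: float = 0.283  # L
    v_liver_intracellular: float = 1.04  # L
    allometric_exponent_cl: float = 0.75

    def __post_init__(self) -> None:
        for name in (
            "body_weight",
            "liver_mass",
            "hepatocellularity",
            "q_hepatic_blood",
            "q_portal_blood",
            "v_central_plasma",
            "v_liver_extracellular",
            "v_liver_intracellular",
        ):
            _check_pos(name, getattr(self, name))
        if not 0 < self.hematocrit < 1:
            raise InvalidParameterError("hematocrit must lie in (0, 1)")
        if self.q_portal_blood >= self.q_hepatic_blood:
            raise InvalidParameterError(
                "portal blood flow must be smaller than total hepatic blood flow"
            )

    @classmethod
    def reference(cls, body_weight: float = REFERENCE_BODY_WEIGHT) -> "PhysiologyRef":
        """Standard adult physiology, allometrically scaled to ``body_weight``."""
        _check_pos("body_weight", body_weight)
        base = cls()
        s_cl = (body_weight / REFERENCE_BODY_WEIGHT) ** base.allometric_exponent_cl
        s_v = body_weight / REFERENCE_BODY_WEIGHT
        return cls(
            body_weight=body_weight,
            liver_mass=base.liver_mass * s_cl,
            hepatocellularity=base.hepatocellularity,
            q_hepatic_blood=base.q_hepatic_blood * s_cl,
            q_portal_blood=base.q_portal_blood * s_cl,
            hematocrit=base.hematocrit,
            v_central_plasma=base.v_central_plasma * s_v,
            v_liver_extracellular=base.v_liver_extracellular * s_v,
            v_liver_intracellular=base.v_liver_intracellular * s_v,
            allometric_exponent_cl=base.allometric_exponent_cl,
        )

    @property
    def q_portal_plasma(self) -> float:
        """Portal plasma flow, L/h (blood flow corrected for hematocrit)."""
        return self.q_portal_blood * (1.0 - self.hematocrit)


@dataclass(frozen=True)
class VictimParams:
    """Victim/biomarker compound parameters.

    Transporter intrinsic clearances are in vitro values per million
    hepatocytes (uL/min/1e6 cells); :func:`cpipbpk.core.scale_intrinsic_clearance`
    converts them to whole-liver unbound clearances.  ``hepatic_scaler_gamma``
    is the hepatic activity scaler applied uniformly to all hepatocyte-level
    intrinsic clearances; it reconciles in vitro scaling with the observed
    clinical baseline and must be set (usually by
    :func:`cpipbpk.core.calibrate_hepatic_scaler`) before the model is solved.
    """

    name: str
    molecular_weight: float  # g/mol
    log_p: float
    pka_acid: float
    pka_base: float
    blood_plasma_ratio: float
    fu_plasma: float  # fraction
    cl_renal_plasma: float  # L/h, plasma-referenced
    k_syn: float  # mg/day/kg; 0 for dosed victims
    cl_passive_per_cell: float  # uL/min/1e6 cells
    cl_uptake_per_cell: Mapping[str, float] = field(default_factory=dict)
    cl_efflux_per_cell: Mapping[str, float] = field(default_factory=dict)
    raf: Mapping[str, float] = field(default_factory=dict)
    hepatic_scaler_gamma: float | None = None

    def __post_init__(self) -> None:
        _check_pos("molecular_weight", self.molecular_weight)
        _check_pos("blood_plasma_ratio", self.blood_plasma_ratio)
        if not 0 < self.fu_plasma <= 1:
            raise InvalidParameterError("fu_plasma must lie in (0, 1]")
        _check_nonneg("cl_renal_plasma", self.cl_renal_plasma)
        _check_nonneg("k_syn", self.k_syn)
        _check_nonneg("cl_passive_per_cell", self.cl_passive_per_cell)
        for t, v in self.cl_uptake_per_cell.items():
            _check_nonneg(f"cl_uptake_per_cell[{t}]", v)
        for t, v in self.cl_efflux_per_cell.items():
            _check_nonneg(f"cl_efflux_per_cell[{t}]", v)
        for t, v in self.raf.items():
            _check_nonneg(f"raf[{t}]", v)
        if self.hepatic_scaler_gamma is not None:
            _check_pos("hepatic_scaler_gamma", self.hepatic_scaler_gamma)
        # normalise mappings to plain dicts so replace() copies are independent
        object.__setattr__(self, "cl_uptake_per_cell", dict(self.cl_uptake_per_cell))
        object.__setattr__(self, "cl_efflux_per_cell", dict(self.cl_efflux_per_cell))
        object.__setattr__(self, "raf", dict(self.raf))

    @property
    def fu_blood(self) -> float:
        """Unbound fraction in blood, fu_plasma / (B/P)."""
        return self.fu_plasma / self.blood_plasma_ratio

    def raf_for(self, transporter: str) -> float:
        return float(self.raf.get(transporter, 1.0))

    def with_gamma(self, gamma: float) -> "VictimParams":
        return replace(self, hepatic_scaler_gamma=gamma)

    def synthesis_rate_nmol_h(self, body_weight: float) -> float:
        """Zero-order synthesis rate in nmol/h for a subject of given weight."""
        # mg/day/kg * kg -> mg/day -> nmol/h
        return self.k_syn * body_weight * 1e6 / self.molecular_weight / 24.0


@dataclass(frozen=True)
class DosingRegimen:
    """Repeated oral dosing: ``n_doses`` doses of ``dose`` mg every ``interval`` h."""

    dose: float  # mg
    interval: float = 24.0  # h
    n_doses: int = 1
    start_time: float = 0.0  # h

    def __post_init__(self) -> None:
        _check_nonneg("dose", self.dose)
        _check_pos("interval", self.interval)
        if self.n_doses < 1:
            raise InvalidParameterError("n_doses must be >= 1")
        _check_nonneg("start_time", self.start_time)

    @property
    def dose_times(self) -> tuple[float, ...]:
        return tuple(self.start_time + i * self.interval for i in range(self.n_doses))


@dataclass(frozen=True)
class InhibitorParams:
    """Perpetrator drug: linear 1- or 2-compartment disposition with
    first-order absorption and per-transporter unbound inhibition constants.

    ``cl_over_f`` is the apparent oral clearance; ``f_abs`` (Fa x Fg) scales
    the dose reaching the absorption depot.  ``ki`` maps transporter name to
    the unbound competitive inhibition constant in uM; ``ki_source`` records
    whether those values are in vitro or estimated in vivo from biomarker
    data.
    """

    name: str
    molecular_weight: float  # g/mol
    fu_plasma: float
    blood_plasma_ratio: float
    ka: float  # 1/h
    f_abs: float  # Fa*Fg
    cl_over_f: float  # L/h
    v_central: float  # L
    ki: Mapping[str, float] = field(default_factory=dict)
    q_inter: float = 0.0  # L/h; 0 -> 1-compartment
    v_peripheral: float = 0.0  # L
    ki_source: str = "in_vitro"

    def __post_init__(self) -> None:
        _check_pos("molecular_weight", self.molecular_weight)
        if not 0 < self.fu_plasma <= 1:
            raise InvalidParameterError("fu_plasma must lie in (0, 1]")
        _check_pos("blood_plasma_ratio", self.blood_plasma_ratio)
        _check_pos("ka", self.ka)
        if not 0 < self.f_abs <= 1:
            raise InvalidParameterError("f_abs must lie in (0, 1]")
        _check_pos("cl_over_f", self.cl_over_f)
        _check_pos("v_central", self.v_central)
        _check_nonneg("q_inter", self.q_inter)
        if self.q_inter > 0:
            _check_pos("v_peripheral", self.v_peripheral)
        for t, v in self.ki.items():
            _check_pos(f"ki[{t}]", v)
        if self.ki_source not in ("in_vitro", "in_vivo_estimated"):
            raise InvalidParameterError(
                "ki_source must be 'in_vitro' or 'in_vivo_estimated'"
            )
        object.__setattr__(self, "ki", dict(self.ki))

    def with_ki(self, ki: Mapping[str, float], source: str = "in_vivo_estimated") -> "InhibitorParams":
        return replace(self, ki=dict(ki), ki_source=source)


@dataclass(frozen=True)
class ModelState:
    """Amounts (nmol) in the three victim compartments."""

    amount_central: float
    amount_liver_ec: float
    amount_liver_ic: float

    def as_array(self):
        import numpy as np

        return np.array(
            [self.amount_central, self.amount_liver_ec, self.amount_liver_ic]
        )


@dataclass(frozen=True)
class BaselineResult:
    """Steady-state baseline summary for an endogenous victim."""

    css_plasma: float  # nM
    cl_total_plasma: float  # L/h
    cl_hepatic_plasma: float  # L/h
    cl_renal_plasma: float  # L/h
    fe: float  # renal fraction of elimination
    ft: Mapping[str, float]  # pathway -> fraction of total elimination
    amounts: tuple[float, float, float] = (0.0, 0.0, 0.0)  # nmol, steady state


def cp1_reference(gamma: float | None = None) -> VictimParams:
    """Coproporphyrin-I with the harmonized model's input parameters.

    Physicochemistry, binding, renal clearance, synthesis rate (White male)
    and per-cell transporter clearances are the published consensus values for
    this biomarker.  The hepatic scaler is left unset unless supplied; call
    :func:`cpipbpk.core.calibrate_hepatic_scaler` to fix it against a baseline
    or renal-fraction target.
    """
    return VictimParams(
        name="coproporphyrin-I",
        molecular_weight=654.71,
        log_p=2.53,
        pka_acid=3.56,
        pka_base=5.18,
        blood_plasma_ratio=0.628,
        fu_plasma=0.069,
        cl_renal_plasma=2.3,
        k_syn=0.0036,
        cl_passive_per_cell=0.76,
        cl_uptake_per_cell={"OATP1B1": 106.0, "OATP1B3": 31.0},
        cl_efflux_per_cell={"MRP2": 0.612},
        raf={"OATP1B1": 1.0, "OATP1B3": 1.0, "MRP2": 1.0},
        hepatic_scaler_gamma=gamma,
    )
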