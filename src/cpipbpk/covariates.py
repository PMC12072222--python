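"""Ethnicity / SLCO1B1 genotype / sex covariates and virtual populations.

Covariate effects on the biomarker baseline are carried by three scalars:

* synthesis rate ``k_syn`` (mg/day/kg) differs by ethnicity and sex — the
  female rate is 88 % of the male rate, and the Japanese rate is reduced by
  35 % relative to White;
* OATP1B1 activity is scaled by an ethnicity factor (58 % in Japanese
  relative to White; Asian-Indian kept at the White level) and a genotype
  factor for the reduced-function c.521T>C variant;
* demographic body weight feeds allometric scaling of flows and clearances.

The genotype activity factors are not direct in vitro measurements: the CC
(homozygous variant) factor is calibrated so that the predicted White
mixed-sex CC:TT baseline ratio equals 1.4, accounting for hepatic flow
limitation; TC is the gene-dose midpoint.  Use
:func:`calibrate_genotype_multiplier` to re-derive the factor under other
assumptions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import core
from .exceptions import InvalidParameterError
from .params import PhysiologyRef, VictimParams

__all__ = [
    "CovariateSpec",
    "PopulationSpec",
    "ETHNICITIES",
    "GENOTYPES",
    "SEXES",
    "K_SYN",
    "OATP1B1_ETHNICITY_ACTIVITY",
    "GENOTYPE_ACTIVITY",
    "BODY_WEIGHT",
    "apply_covariates",
    "baseline_scenario_table",
    "all_scenarios",
    "sample_population",
    "genotype_baseline_ratio",
    "calibrate_genotype_multiplier",
]

ETHNICITIES = ("White", "Japanese", "AsianIndian")
GENOTYPES = ("TT", "TC", "CC")
SEXES = ("M", "F")

#: biomarker synthesis rate, mg/day/kg, by (ethnicity, sex)
K_SYN = {
    ("White", "M"): 0.0036,
    ("White", "F"): 0.0032,
    ("AsianIndian", "M"): 0.0036,
    ("AsianIndian", "F"): 0.0032,
    ("Japanese", "M"): 0.0024,
    ("Japanese", "F"): 0.0021,
}

#: OATP1B1 activity relative to White (Japanese abundance 58 % of White;
#: no separate datum for Asian-Indian, kept at the White level — configurable)
OATP1B1_ETHNICITY_ACTIVITY = {"White": 1.0, "AsianIndian": 1.0, "Japanese": 0.58}

#: OATP1B1 activity by c.521T>C genotype.  CC calibrated (flow-aware) to a
#: White mixed-sex CC:TT baseline ratio of 1.4; TC is the gene-dose midpoint.
GENOTYPE_ACTIVITY = {"TT": 1.0, "TC": 0.72, "CC": 0.4409}

#: default demographic body weight, kg, by (ethnicity, sex)
BODY_WEIGHT = {
    ("White", "M"): 70.0,
    ("White", "F"): 60.0,
    ("Japanese", "M"): 65.0,
    ("Japanese", "F"): 52.0,
    ("AsianIndian", "M"): 65.0,
    ("AsianIndian", "F"): 52.0,
}


@dataclass(frozen=True)
class CovariateSpec:
    ethnicity: str = "White"
    genotype: str = "TT"
    sex: str = "M"

    def __post_init__(self) -> None:
        if self.ethnicity not in ETHNICITIES:
            raise InvalidParameterError(f"unknown ethnicity {self.ethnicity!r}")
        if self.genotype not in GENOTYPES:
            raise InvalidParameterError(f"unknown genotype {self.genotype!r}")
        if self.sex not in SEXES:
            raise InvalidParameterError(f"unknown sex {self.sex!r}")

    @property
    def scenario_id(self) -> str:
        return f"{self.ethnicity}_{self.genotype}_{self.sex}"


@dataclass(frozen=True)
class PopulationSpec:
    """Virtual-population settings: covariate stratum, size and variability.

    CVs are log-normal coefficients of variation on the hepatic uptake
    clearances (shared factor for both OATP1B transporters), the synthesis
    rate, the renal clearance and body weight.
    """

    covariates: CovariateSpec
    n: int
    cv_clint: float = 0.35
    cv_ksyn: float = 0.25
    cv_clr: float = 0.30
    cv_bw: float = 0.15
    body_weight_mean: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise InvalidParameterError("population size n must be >= 1")
        for name in ("cv_clint", "cv_ksyn", "cv_clr", "cv_bw"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")


def all_scenarios() -> list[CovariateSpec]:
    """The 18 ethnicity x genotype x sex baseline scenarios."""
    return [
        CovariateSpec(e, g, s) for e in ETHNICITIES for g in GENOTYPES for s in SEXES
    ]


def apply_covariates(
    base: VictimParams,
    phys: PhysiologyRef,
    cov: CovariateSpec,
) -> tuple[VictimParams, PhysiologyRef]:
    """Covariate-adjusted parameters and physiology.

    ``base`` must be the calibrated White-male-TT reference; the ethnicity
    and genotype factors act multiplicatively on the OATP1B1 relative
    activity factor, ``k_syn`` is looked up per (ethnicity, sex), and the
    physiology is rebuilt at the demographic body weight.
    """
    if base.k_syn <= 0:
        raise InvalidParameterError("base victim must be the endogenous biomarker")
    scalar = (
        OATP1B1_ETHNICITY_ACTIVITY[cov.ethnicity] * GENOTYPE_ACTIVITY[cov.genotype]
    )
    raf = dict(base.raf)
    raf["OATP1B1"] = base.raf_for("OATP1B1") * scalar
    params = replace(base, k_syn=K_SYN[(cov.ethnicity, cov.sex)], raf=raf)
    bw = BODY_WEIGHT[(cov.ethnicity, cov.sex)]
    return params, PhysiologyRef.reference(bw)


def baseline_scenario_table(
    scenarios: Sequence[CovariateSpec],
    base: VictimParams,
    phys: PhysiologyRef,
) -> pd.DataFrame:
    """Representative-subject baseline for each covariate scenario."""
    if not scenarios:
        raise InvalidParameterError("scenario list must be nonempty")
    rows = []
    for cov in scenarios:
        p, ph = apply_covariates(base, phys, cov)
        res = core.solve_baseline(p, ph)
        rows.append(
            {
                "scenario_id": cov.scenario_id,
                "ethnicity": cov.ethnicity,
                "genotype": cov.genotype,
                "sex": cov.sex,
                "body_weight_kg": ph.body_weight,
                "css_nM": res.css_plasma,
                "cl_total_L_h": res.cl_total_plasma,
                "fe": res.fe,
                "ft_oatp1b1": res.ft["OATP1B1"],
                "ft_oatp1b3": res.ft["OATP1B3"],
                "ft_passive": res.ft["passive"],
            }
        )
    return pd.DataFrame(rows)


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Median-preserving log-normal multipliers with the given CV."""
    if cv == 0:
        return np.ones(n)
    sigma = np.sqrt(np.log1p(cv**2))
    return np.exp(sigma * rng.standard_normal(n))


def sample_population(
    spec: PopulationSpec,
    base: VictimParams,
    phys: PhysiologyRef,
) -> list[tuple[VictimParams, PhysiologyRef]]:
    """Reproducible virtual subjects for one covariate stratum.

    Between-subject variability is applied as median-preserving log-normal
    factors on the shared OATP1B uptake activity, synthesis rate, renal
    clearance and body weight.  Identical ``seed`` gives identical draws.
    """
    cov = spec.covariates
    p0, ph0 = apply_covariates(base, phys, cov)
    bw_mean = spec.body_weight_mean or ph0.body_weight
    rng = np.random.default_rng(spec.seed)
    f_cl = _lognormal_factors(rng, spec.cv_clint, spec.n)
    f_ks = _lognormal_factors(rng, spec.cv_ksyn, spec.n)
    f_cr = _lognormal_factors(rng, spec.cv_clr, spec.n)
    f_bw = _lognormal_factors(rng, spec.cv_bw, spec.n)
    subjects = []
    for i in range(spec.n):
        raf = dict(p0.raf)
        for t in p0.cl_uptake_per_cell:
            raf[t] = p0.raf_for(t) * f_cl[i]
        subjects.append(
            (
                replace(
                    p0,
                    raf=raf,
                    k_syn=p0.k_syn * f_ks[i],
                    cl_renal_plasma=p0.cl_renal_plasma * f_cr[i],
                ),
                PhysiologyRef.reference(bw_mean * f_bw[i]),
            )
        )
    return subjects


def genotype_baseline_ratio(
    base: VictimParams,
    phys: PhysiologyRef,
    genotype: str = "CC",
    ethnicity: str = "White",
) -> float:
    """Mixed-sex baseline ratio of a variant genotype relative to TT."""

    def mixed_css(g: str) -> float:
        vals = []
        for sex in SEXES:
            p, ph = apply_covariates(base, phys, CovariateSpec(ethnicity, g, sex))
            vals.append(core.solve_baseline(p, ph).css_plasma)
        return float(np.mean(vals))

    return mixed_css(genotype) / mixed_css("TT")


def calibrate_genotype_multiplier(
    base: VictimParams,
    phys: PhysiologyRef,
    target_ratio: float = 1.4,
    ethnicity: str = "White",
) -> float:
    """OATP1B1 activity factor reproducing a mixed-sex variant:TT ratio.

    Solves for the activity multiplier (on the calibrated TT model) whose
    mixed-sex baseline ratio relative to TT equals ``target_ratio``; the
    packaged CC default was frozen from this procedure at 1.4.
    """
    if target_ratio <= 1:
        raise InvalidParameterError("target_ratio must exceed 1")

    def ratio_minus_target(mult: float) -> float:
        vals_tt, vals_g = [], []
        for sex in SEXES:
            cov = CovariateSpec(ethnicity, "TT", sex)
            p, ph = apply_covariates(base, phys, cov)
            vals_tt.append(core.solve_baseline(p, ph).css_plasma)
            raf = dict(p.raf)
            raf["OATP1B1"] = p.raf_for("OATP1B1") * mult
            vals_g.append(core.solve_baseline(replace(p, raf=raf), ph).css_plasma)
        return float(np.mean(vals_g) / np.mean(vals_tt)) - target_ratio

    return float(brentq(ratio_minus_target, 1e-3, 1.0, xtol=1e-10))
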