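"""Synthetic clinical-style datasets generated from the model itself.

Real biomarker trial data live in study reports; these generators emulate
their statistical structure — per-subject baselines log-normally distributed
around covariate-scenario means, and paired control/treatment biomarker
profiles with multiplicative residual error — from the model with known
ground truth, so the whole pipeline (baseline prediction, interaction
metrics, Ki recovery, evaluation statistics) is testable end to end.

Every generator is a pure function of its configuration and seed, and each
returns the truth record alongside the data.
"""

from __future__ import annotations

import json
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import core, ddi
from .covariates import CovariateSpec, apply_covariates
from .exceptions import InvalidParameterError
from .params import (
    DosingRegimen,
    InhibitorParams,
    PhysiologyRef,
    VictimParams,
)
from .perpetrator import inhibition_ratio_fn

__all__ = [
    "generate_baseline_dataset",
    "generate_ddi_dataset",
    "evaluation_fixture",
    "DEFAULT_SAMPLING_TIMES",
    "write_with_truth",
]

#: default post-dose sampling schedule for interaction fixtures, h
DEFAULT_SAMPLING_TIMES = (0.0, 1.0, 2.0, 4.0, 6.0, 8.0, 12.0, 24.0)


def _factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    if cv == 0:
        return np.ones(n)
    sigma = np.sqrt(np.log1p(cv**2))
    return np.exp(sigma * rng.standard_normal(n))


def generate_baseline_dataset(
    scenarios: Sequence[CovariateSpec],
    base: VictimParams,
    phys: PhysiologyRef,
    n_per_arm: int,
    cv_between: float = 0.35,
    cv_residual: float = 0.10,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Subject-level baseline table across covariate arms.

    Each subject's true baseline is the scenario's model prediction times a
    log-normal between-subject factor; the observed value multiplies in a
    residual factor.  Returns the table and the truth record (per-scenario
    model css and the CVs used).
    """
    if n_per_arm < 1:
        raise InvalidParameterError("n_per_arm must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    truth: dict = {"cv_between": cv_between, "cv_residual": cv_residual, "css_model_nM": {}}
    for cov in scenarios:
        p, ph = apply_covariates(base, phys, cov)
        css = core.solve_baseline(p, ph).css_plasma
        truth["css_model_nM"][cov.scenario_id] = css
        f_bsv = _factors(rng, cv_between, n_per_arm)
        f_res = _factors(rng, cv_residual, n_per_arm)
        for i in range(n_per_arm):
            rows.append(
                {
                    "subject_id": f"{cov.scenario_id}_{i + 1:03d}",
                    "ethnicity": cov.ethnicity,
                    "genotype": cov.genotype,
                    "sex": cov.sex,
                    "css_true_nM": css * f_bsv[i],
                    "css_nM": css * f_bsv[i] * f_res[i],
                }
            )
    return pd.DataFrame(rows), truth


def generate_ddi_dataset(
    victim: VictimParams,
    inhibitor: InhibitorParams,
    regimen: DosingRegimen,
    phys: PhysiologyRef,
    true_ki_scale: float = 1.0,
    sampling_times: Sequence[float] = DEFAULT_SAMPLING_TIMES,
    cv_residual: float = 0.20,
    n_subjects: int = 1,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Paired control/treatment biomarker profiles with known true Ki.

    The treatment profile is simulated with the inhibitor's Ki map scaled by
    ``true_ki_scale``; the control arm is the flat baseline.  Observations
    multiply in log-normal residual error per sample.  Returns the long
    table (subject_id, arm, time_h, conc_nM) and the truth record.
    """
    if true_ki_scale <= 0:
        raise InvalidParameterError("true_ki_scale must be > 0")
    t = np.asarray(sampling_times, dtype=float)
    if np.any(t < 0) or np.any(np.diff(t) <= 0):
        raise InvalidParameterError("sampling times must be increasing and >= 0")
    true_ki = {k: v * true_ki_scale for k, v in inhibitor.ki.items()}
    inh_true = inhibitor.with_ki(true_ki, source=inhibitor.ki_source)

    y0 = core.steady_state_amounts(victim, phys)
    css = y0[0] / phys.v_central_plasma
    t_end = float(t[-1]) if t[-1] > 0 else regimen.interval
    t_eval = np.unique(np.concatenate([[0.0], t, [t_end]]))
    sel = np.searchsorted(t_eval, t)
    states = core.simulate_victim(
        victim,
        phys,
        t_eval,
        y0=y0,
        inhibition_fn=inhibition_ratio_fn(inh_true, regimen, phys),
        breakpoints=[x for x in regimen.dose_times if 0 < x < t_end],
    )
    conc_treat = states[sel, 0] / phys.v_central_plasma

    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subjects):
        for arm, conc in (("control", np.full(len(t), css)), ("treatment", conc_treat)):
            f = _factors(rng, cv_residual, len(t))
            for tj, cj, fj in zip(t, conc, f):
                rows.append(
                    {
                        "subject_id": f"S{i + 1:03d}",
                        "arm": arm,
                        "time_h": float(tj),
                        "conc_nM": float(cj * fj),
                    }
                )
    truth = {
        "true_ki_uM": dict(true_ki),
        "true_ki_scale": true_ki_scale,
        "css_nM": float(css),
        "cv_residual": cv_residual,
        "seed": seed,
        "conc_model_nM": [float(x) for x in conc_treat],
        "sampling_times_h": [float(x) for x in t],
    }
    return pd.DataFrame(rows), truth


def evaluation_fixture() -> pd.DataFrame:
    """Pred/obs pairs exercising every evaluation-criterion branch.

    Includes pairs exactly on the 1.5- and 2-fold boundaries, a degenerate
    observed ratio of 1, observed ratios below 1 (inverted Guest branch),
    and clear passes/failures of the Guest band.
    """
    rows = [
        ("exact", 1.0, 1.0),
        ("on_1p5_boundary_high", 1.5, 1.0),
        ("on_1p5_boundary_low", 1.0, 1.5),
        ("inside_1p5", 1.4, 1.0),
        ("outside_1p5", 0.5, 1.0),
        ("on_2fold_boundary", 2.0, 1.0),
        ("outside_2fold", 2.2, 1.0),
        ("guest_degenerate_robs_1", 1.05, 1.0),
        ("guest_pass_robs_2", 2.5, 2.0),
        ("guest_fail_robs_2", 3.5, 2.0),
        ("guest_robs_below_1", 0.55, 0.5),
        ("guest_robs_below_1_fail", 1.4, 0.5),
        ("strong_interaction", 4.0, 4.6),
    ]
    return pd.DataFrame(rows, columns=["label", "predicted", "observed"])


def write_with_truth(
    df: pd.DataFrame,
    truth: Mapping,
    csv_path: str,
    truth_path: str | None = None,
) -> None:
    """Write a dataset CSV plus its JSON truth sidecar."""
    df.to_csv(csv_path, index=False)
    if truth_path is None:
        truth_path = str(csv_path).rsplit(".", 1)[0] + ".truth.json"
    with open(truth_path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
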