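"""YAML configuration files for compounds and regimens, plus CSV helpers.

Keys carry their units (e.g. ``cl_renal_plasma_L_h``) so files are
self-describing.  Built-in illustrative inhibitor files ship under
``cpipbpk/configs`` and are loaded with :func:`load_builtin_inhibitor`;
they are placeholders with literature inhibition constants but non-validated
disposition parameters, intended for structural and synthetic-data work —
supply study-specific PK parameters for quantitative reproduction of any
particular trial.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Any

import yaml

from .exceptions import InvalidParameterError
from .params import DosingRegimen, InhibitorParams, VictimParams

__all__ = [
    "load_victim",
    "save_victim",
    "load_inhibitor",
    "save_inhibitor",
    "load_builtin_inhibitor",
    "builtin_inhibitor_names",
]

_VICTIM_KEYS = {
    "name": "name",
    "molecular_weight_g_mol": "molecular_weight",
    "log_p": "log_p",
    "pka_acid": "pka_acid",
    "pka_base": "pka_base",
    "blood_plasma_ratio": "blood_plasma_ratio",
    "fu_plasma": "fu_plasma",
    "cl_renal_plasma_L_h": "cl_renal_plasma",
    "k_syn_mg_day_kg": "k_syn",
    "cl_passive_uL_min_1e6cells": "cl_passive_per_cell",
    "cl_uptake_uL_min_1e6cells": "cl_uptake_per_cell",
    "cl_efflux_uL_min_1e6cells": "cl_efflux_per_cell",
    "raf": "raf",
    "hepatic_scaler_gamma": "hepatic_scaler_gamma",
}

_INHIBITOR_KEYS = {
    "name": "name",
    "molecular_weight_g_mol": "molecular_weight",
    "fu_plasma": "fu_plasma",
    "blood_plasma_ratio": "blood_plasma_ratio",
    "ka_per_h": "ka",
    "f_abs": "f_abs",
    "cl_over_f_L_h": "cl_over_f",
    "v_central_L": "v_central",
    "q_inter_L_h": "q_inter",
    "v_peripheral_L": "v_peripheral",
    "ki_uM": "ki",
    "ki_source": "ki_source",
}


def _translate(doc: dict, mapping: dict[str, str], what: str) -> dict[str, Any]:
    out = {}
    for key, field in mapping.items():
        if key in doc:
            out[field] = doc[key]
    unknown = set(doc) - set(mapping) - {"regimen"}
    if unknown:
        raise InvalidParameterError(f"unknown {what} config keys: {sorted(unknown)}")
    return out


def load_victim(path: str | Path) -> VictimParams:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return VictimParams(**_translate(doc, _VICTIM_KEYS, "victim"))


def save_victim(params: VictimParams, path: str | Path) -> None:
    doc = {key: getattr(params, field) for key, field in _VICTIM_KEYS.items()}
    doc["cl_uptake_uL_min_1e6cells"] = dict(params.cl_uptake_per_cell)
    doc["cl_efflux_uL_min_1e6cells"] = dict(params.cl_efflux_per_cell)
    doc["raf"] = dict(params.raf)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def _regimen_from(doc: dict) -> DosingRegimen | None:
    block = doc.get("regimen")
    if block is None:
        return None
    return DosingRegimen(
        dose=block["dose_mg"],
        interval=block.get("interval_h", 24.0),
        n_doses=block.get("n_doses", 1),
        start_time=block.get("start_time_h", 0.0),
    )


def load_inhibitor(path: str | Path) -> tuple[InhibitorParams, DosingRegimen | None]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    params = InhibitorParams(**_translate(doc, _INHIBITOR_KEYS, "inhibitor"))
    return params, _regimen_from(doc)


def save_inhibitor(
    params: InhibitorParams,
    path: str | Path,
    regimen: DosingRegimen | None = None,
) -> None:
    doc = {key: getattr(params, field) for key, field in _INHIBITOR_KEYS.items()}
    doc["ki_uM"] = dict(params.ki)
    if regimen is not None:
        doc["regimen"] = {
            "dose_mg": regimen.dose,
            "interval_h": regimen.interval,
            "n_doses": regimen.n_doses,
            "start_time_h": regimen.start_time,
        }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def builtin_inhibitor_names() -> list[str]:
    files = resources.files("cpipbpk").joinpath("configs")
    return sorted(
        p.name.removesuffix(".yaml")
        for p in files.iterdir()
        if p.name.endswith(".yaml")
    )


def load_builtin_inhibitor(name: str) -> tuple[InhibitorParams, DosingRegimen | None]:
    """Load one of the shipped illustrative inhibitor configurations."""
    ref = resources.files("cpipbpk").joinpath("configs", f"{name}.yaml")
    if not ref.is_file():
        raise InvalidParameterError(
            f"no builtin inhibitor {name!r}; available: {builtin_inhibitor_names()}"
        )
    with ref.open() as fh:
        doc = yaml.safe_load(fh)
    params = InhibitorParams(**_translate(doc, _INHIBITOR_KEYS, "inhibitor"))
    return params, _regimen_from(doc)
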