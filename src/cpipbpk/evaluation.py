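"""Model-evaluation statistics: fold-error criteria, Guest limits, GMFE.

These are the standard acceptance statistics for PBPK DDI predictions:

* a k-fold error criterion, ``1/k <= pred/obs <= k`` (boundaries inclusive);
* the Guest limits, an acceptance band on predicted interaction ratios that
  narrows as the observed ratio approaches 1, so that no-interaction cases
  are not trivially "well predicted";
* the geometric mean fold error, ``10 ** mean(|log10(pred/obs)|)`` in its
  conventional absolute form, or without the absolute value as a signed
  bias measure (geometric mean ratio).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError

__all__ = [
    "PredObsPair",
    "within_fold",
    "guest_limits",
    "within_guest",
    "gmfe",
    "summarize",
]


@dataclass(frozen=True)
class PredObsPair:
    predicted: float
    observed: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.predicted <= 0 or self.observed <= 0:
            raise InvalidParameterError("predicted and observed must be > 0")


def within_fold(pair: PredObsPair, k: float) -> bool:
    """True iff ``1/k <= predicted/observed <= k`` (inclusive)."""
    if k <= 1:
        raise InvalidParameterError("fold criterion k must be > 1")
    r = pair.predicted / pair.observed
    return bool(1.0 / k <= r <= k)


def guest_limits(r_obs: float, delta: float = 1.0) -> tuple[float, float]:
    """Acceptable predicted-ratio range for an observed ratio ``r_obs``.

    ``L = (delta + 2*(r - 1)) / r`` evaluated at ``r = max(r_obs, 1/r_obs)``;
    the acceptable predicted range is ``[r_obs / L, r_obs * L]``.  With
    ``delta = 1`` the band collapses to the point ratio at ``r_obs = 1`` and
    approaches twofold for large observed ratios; ``delta = 1.25`` reproduces
    the bioequivalence band at ``r_obs = 1``.
    """
    if r_obs <= 0:
        raise InvalidParameterError("r_obs must be > 0")
    if delta < 1:
        raise InvalidParameterError("delta must be >= 1")
    r = max(r_obs, 1.0 / r_obs)
    limit = (delta + 2.0 * (r - 1.0)) / r
    return r_obs / limit, r_obs * limit


def within_guest(pair: PredObsPair, delta: float = 1.0) -> bool:
    lo, hi = guest_limits(pair.observed, delta)
    return bool(lo <= pair.predicted <= hi)


def gmfe(pairs: Iterable[PredObsPair], absolute: bool = True) -> float:
    """Geometric mean fold error of predicted vs observed.

    ``absolute=True`` (default) is the conventional GMFE on |log10| fold
    errors; ``absolute=False`` drops the absolute value and measures signed
    bias (geometric mean ratio).
    """
    logs = np.array(
        [np.log10(p.predicted / p.observed) for p in pairs], dtype=float
    )
    if logs.size == 0:
        raise InvalidParameterError("gmfe requires at least one pred/obs pair")
    if absolute:
        logs = np.abs(logs)
    return float(10.0 ** logs.mean())


def summarize(
    pairs: Sequence[PredObsPair],
    fold_criteria: Sequence[float] = (1.5, 2.0),
    guest_delta: float = 1.0,
) -> dict:
    """Summary statistics over a pred/obs table.

    Returns n, the percentage within each fold criterion and within the
    Guest limits, and both GMFE conventions.
    """
    n = len(pairs)
    if n == 0:
        raise InvalidParameterError("empty pair list")
    out: dict = {"n": n}
    for k in fold_criteria:
        out[f"pct_within_{k:g}fold"] = 100.0 * sum(
            within_fold(p, k) for p in pairs
        ) / n
    out["pct_within_guest"] = 100.0 * sum(
        within_guest(p, guest_delta) for p in pairs
    ) / n
    out["gmfe"] = gmfe(pairs, absolute=True)
    out["gm_ratio"] = gmfe(pairs, absolute=False)
    return out


def pairs_from_frame(df: pd.DataFrame) -> list[PredObsPair]:
    """Build pairs from a DataFrame with columns label/predicted/observed."""
    return [
        PredObsPair(float(r.predicted), float(r.observed), str(r.label))
        for r in df.itertuples()
    ]
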