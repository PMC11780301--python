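"""Health-instrument scoring and orientation.

Four instruments enter the analysis:

* self-rated health (SRH): single 5-level item, 5 = very healthy;
* activities of daily living (ADL): six items scored 1 (no difficulty)
  to 4 (cannot do), summed to 6-24 where 6 = fully independent;
* instrumental ADL (iADL): six items on the same 1-4 scheme, 6 = intact;
* cognition: a 0-30 Mini-Mental State Examination total, 30 = best.

Because the deprivation index requires a common "larger = healthier"
direction, every score is passed through :func:`orient`: ADL/iADL sums are
reflected as ``30 - x`` (a bijection of [6, 24] onto itself) while SRH and
cognition are already health-increasing and pass through unchanged.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "DIMENSIONS",
    "score_adl",
    "score_iadl",
    "orient",
    "score_table",
]

#: Health dimensions, in the order they are reported.
DIMENSIONS = ("srh", "adl", "iadl", "cognition")

_N_ITEMS = 6
_ITEM_MIN, _ITEM_MAX = 1, 4

#: Valid (inclusive) range of each score on its native scale.
SCORE_RANGES = {
    "srh": (1, 5),
    "adl": (6, 24),
    "iadl": (6, 24),
    "cognition": (0, 30),
}


def _score_items(items: Sequence[float], scale: str) -> int:
    items = list(items)
    if len(items) != _N_ITEMS:
        raise ValidationError(
            f"{scale}: expected {_N_ITEMS} items, got {len(items)}"
        )
    total = 0
    for i, v in enumerate(items):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise ValidationError(f"{scale}: item {i} is missing")
        iv = int(v)
        if iv != v or not (_ITEM_MIN <= iv <= _ITEM_MAX):
            raise ValidationError(
                f"{scale}: item {i} value {v!r} outside {{1,2,3,4}}"
            )
        total += iv
    return total


def score_adl(items: Sequence[float]) -> int:
    """Sum the six ADL difficulty items (each 1-4) to a 6-24 total.

    Raises
    ------
    ValidationError
        If the arity is not six or any item is missing/out of range;
        the message names the offending item index.
    """
    return _score_items(items, "adl")


def score_iadl(items: Sequence[float]) -> int:
    """Sum the six iADL items (each 1-4) to a 6-24 total; 6 = intact."""
    return _score_items(items, "iadl")


def orient(score, dimension: str):
    """Map a score onto the global higher-is-healthier orientation.

    ADL and iADL totals (where larger means more difficulty) are reflected
    as ``30 - x``, which maps [6, 24] bijectively onto [6, 24]; SRH and
    cognition are identity. Works on scalars or arrays.
    """
    if dimension in ("adl", "iadl"):
        return 30 - np.asarray(score) if np.ndim(score) else 30 - score
    if dimension in ("srh", "cognition"):
        return score
    raise ValidationError(f"unknown dimension {dimension!r}")


def score_table(
    cohort: pd.DataFrame,
    adl_cols: Iterable[str] | None = None,
    iadl_cols: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Append scored and oriented health columns to a cohort table.

    Expects ``srh``, ``mmse_total`` and six-item column sets ``adl_1..adl_6``
    and ``iadl_1..iadl_6`` (overridable). Rows with any missing item on a
    scale get a missing score for that scale and ``<dim>_complete = False``;
    they are excluded from that dimension's analysis downstream (listwise
    per dimension).

    Returns a copy with, per dimension, ``<dim>`` (native scale),
    ``oriented_<dim>`` and ``<dim>_complete`` columns.
    """
    adl_cols = list(adl_cols) if adl_cols else [f"adl_{i}" for i in range(1, 7)]
    iadl_cols = list(iadl_cols) if iadl_cols else [f"iadl_{i}" for i in range(1, 7)]

    out = cohort.copy()

    for scale, cols in (("adl", adl_cols), ("iadl", iadl_cols)):
        items = out[cols].to_numpy(dtype=float)
        bad = (items < _ITEM_MIN) | (items > _ITEM_MAX)
        if np.any(bad & ~np.isnan(items)):
            r, c = np.argwhere(bad & ~np.isnan(items))[0]
            raise ValidationError(
                f"{scale}: item {cols[c]} row {out.index[r]} value "
                f"{items[r, c]!r} outside {{1,2,3,4}}"
            )
        complete = ~np.isnan(items).any(axis=1)
        total = items.sum(axis=1)
        total[~complete] = np.nan
        out[scale] = total
        out[f"{scale}_complete"] = complete

    srh = out["srh"].to_numpy(dtype=float)
    if np.any(((srh < 1) | (srh > 5)) & ~np.isnan(srh)):
        raise ValidationError("srh outside {1..5}")
    out["srh_complete"] = ~np.isnan(srh)

    mmse = out["mmse_total"].to_numpy(dtype=float)
    if np.any(((mmse < 0) | (mmse > 30)) & ~np.isnan(mmse)):
        raise ValidationError("mmse_total outside [0, 30]")
    out["cognition"] = mmse
    out["cognition_complete"] = ~np.isnan(mmse)

    for dim in DIMENSIONS:
        vals = out[dim].to_numpy(dtype=float)
        if dim in ("adl", "iadl"):
            out[f"oriented_{dim}"] = 30.0 - vals
        else:
            out[f"oriented_{dim}"] = vals
    return out
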