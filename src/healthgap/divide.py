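"""Digital-divide indicators: access (binary) and use (0-3 count).

Access reflects physical connectivity: home broadband, smart devices
(e.g. smartphones), and other digital devices. A person has *access* if any
of the three indicators is positive.

Use reflects actual engagement with online services: social messaging
(WeChat), social posting (Moments) and mobile payment, each 0/1, summed to
a 0-3 capacity score. The three use items are only observed for people who
own at least one smart device; use-level analyses are restricted to records
with all three observed. For matched analyses the use score is binarized at
the sample median (strictly greater than the median -> 1; ties at the
median -> 0, a deterministic and conservative rule).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["derive_access", "derive_use", "binarize_use", "derive_table"]


def derive_access(broadband, n_smart, n_digital):
    """Binary access indicator: 1 iff any connectivity indicator is positive.

    Accepts scalars or equal-length arrays; counts must be nonnegative.
    """
    b = np.asarray(broadband)
    s = np.asarray(n_smart)
    d = np.asarray(n_digital)
    for name, a in (("broadband", b), ("n_smart", s), ("n_digital", d)):
        if np.any(a < 0):
            raise ValidationError(f"{name}: negative count")
    access = ((b >= 1) | (s >= 1) | (d >= 1)).astype(int)
    return int(access) if access.ndim == 0 else access


def derive_use(wechat, moments, mobile_pay):
    """Use-capacity score: sum of the three 0/1 use items, in [0, 3].

    All three items must be observed; a missing item makes the score
    undefined for that record (raises for scalars; see
    :func:`derive_table` for the vectorized flag-based handling).
    """
    vals = (wechat, moments, mobile_pay)
    names = ("wechat", "moments", "mobile_pay")
    total = 0
    for name, v in zip(names, vals):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise ValidationError(f"{name}: missing use item, score undefined")
        if v not in (0, 1):
            raise ValidationError(f"{name}: value {v!r} not in {{0,1}}")
        total += int(v)
    return total


def binarize_use(use_scores) -> np.ndarray:
    """Median-binarize use scores: 1 iff strictly above the sample median.

    Ties at the median are assigned 0. Raises on an empty vector.
    """
    y = np.asarray(use_scores, dtype=float)
    if y.size == 0:
        raise ValidationError("binarize_use: empty vector")
    if np.any(np.isnan(y)):
        raise ValidationError("binarize_use: undefined (missing) use scores")
    med = np.median(y)
    return (y > med).astype(int)


def derive_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Append divide indicator columns to a cohort table.

    Adds ``access`` (0/1), ``eligibility_use`` (all three use items
    observed), ``use_score`` (0-3 where eligible, else missing) and
    ``use_binary`` (median split computed over the eligible subsample,
    missing elsewhere).
    """
    out = cohort.copy()
    out["access"] = derive_access(
        out["broadband"].to_numpy(),
        out["n_smart_devices"].to_numpy(),
        out["n_digital_devices"].to_numpy(),
    )
    use_items = out[["wechat", "moments", "mobile_pay"]].to_numpy(dtype=float)
    eligible = ~np.isnan(use_items).any(axis=1)
    out["eligibility_use"] = eligible.astype(int)
    score = use_items.sum(axis=1)
    score[~eligible] = np.nan
    out["use_score"] = score
    use_binary = np.full(len(out), np.nan)
    if eligible.any():
        use_binary[eligible] = binarize_use(score[eligible])
    out["use_binary"] = use_binary
    return out
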