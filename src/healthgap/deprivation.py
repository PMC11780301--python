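r"""Kakwani relative-deprivation index of health.

For a sample of oriented health values :math:`y_1, \dots, y_n` with mean
:math:`\mu_Y`, the per-person deprivation is

.. math::

    RD_i \;=\; \frac{1}{n\,\mu_Y} \sum_j \max(y_j - y_i,\, 0)
          \;=\; \gamma_i \,\frac{\mu_i^+ - y_i}{\mu_Y},

where :math:`\gamma_i` is the fraction of the sample strictly healthier
than person *i* and :math:`\mu_i^+` the mean health of that subset. The
index is nonnegative, zero exactly at the sample maximum, dimensionless
(invariant under :math:`y \mapsto c\,y`, :math:`c > 0`), decreasing in own
health within a fixed sample, and its sample mean equals the Gini
coefficient of *y* — the identity used here as an internal consistency
oracle.

Ties are handled by the strict inequality: people at the same health level
do not deprive each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .scales import DIMENSIONS

__all__ = ["DeprivationVector", "kakwani_rd", "gini", "rd_table"]


@dataclass
class DeprivationVector:
    """Per-person deprivation values for one health dimension."""

    rd: np.ndarray                 #: RD_i, input order preserved
    n: int                         #: sample size used
    mu: float                      #: sample mean health
    frac_healthier: np.ndarray     #: gamma_i, share strictly healthier
    mean_healthier: np.ndarray     #: mu_i^+ (NaN at sample maxima)
    dimension: str | None = field(default=None)


def _validated(y) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if y.ndim != 1:
        y = y.ravel()
    if y.size == 0:
        raise ValidationError("deprivation index undefined on empty input")
    if not np.all(np.isfinite(y)):
        raise ValidationError("health values must be finite")
    return y


def kakwani_rd(y, dimension: str | None = None) -> DeprivationVector:
    """Compute the per-person Kakwani relative-deprivation vector.

    Parameters
    ----------
    y : array-like
        Oriented health values (higher = healthier); mean must be > 0.
    dimension : str, optional
        Label carried through to the result.

    Notes
    -----
    The O(n^2) double sum is evaluated in O(n log n) by sorting: with the
    sample sorted ascending, the deprivation sum for person *i* is the sum
    of values strictly above :math:`y_i` minus their count times
    :math:`y_i`, both read off suffix cumulative sums.
    """
    y = _validated(y)
    n = y.size
    mu = float(y.mean())
    if mu <= 0:
        raise ValidationError(
            f"deprivation index undefined: mean health {mu} <= 0"
        )

    ys = np.sort(y)
    suffix = np.concatenate([np.cumsum(ys[::-1])[::-1], [0.0]])
    # idx = count of values <= y_i; everything after is strictly healthier
    idx = np.searchsorted(ys, y, side="right")
    count_above = n - idx
    sum_above = suffix[idx]

    rd = (sum_above - count_above * y) / (n * mu)
    rd[count_above == 0] = 0.0  # exact zero at sample maxima

    gamma = count_above / n
    with np.errstate(invalid="ignore", divide="ignore"):
        mu_plus = np.where(count_above > 0, sum_above / np.maximum(count_above, 1), np.nan)

    return DeprivationVector(
        rd=rd, n=n, mu=mu, frac_healthier=gamma,
        mean_healthier=mu_plus, dimension=dimension,
    )


def gini(y) -> float:
    r"""Gini coefficient :math:`\sum_{ij}|y_i-y_j| / (2 n^2 \mu_Y)`.

    Computed from the sorted sample in O(n log n); equals the sample mean
    of :func:`kakwani_rd`.
    """
    y = _validated(y)
    n = y.size
    mu = float(y.mean())
    if mu <= 0:
        raise ValidationError(f"Gini undefined: mean health {mu} <= 0")
    ys = np.sort(y)
    i = np.arange(1, n + 1)
    return float(2.0 * np.sum(i * ys) / (n * ys.sum()) - (n + 1) / n)


def rd_table(
    scored: pd.DataFrame,
    dimensions: Iterable[str] = DIMENSIONS,
) -> tuple[pd.DataFrame, dict]:
    """Append ``rd_<dim>`` columns computed within the table's sample.

    For each dimension the index is computed over rows with a complete
    (observed) score for that dimension; other rows get a missing RD.
    Returns the augmented table and a per-dimension summary
    ``{dim: {"n": ..., "mu": ..., "gini": ...}}``.
    """
    out = scored.copy()
    summary: dict[str, dict] = {}
    for dim in dimensions:
        if dim not in DIMENSIONS:
            raise ValidationError(f"unknown dimension {dim!r}")
        mask = out[f"{dim}_complete"].to_numpy(dtype=bool)
        col = np.full(len(out), np.nan)
        if mask.any():
            dv = kakwani_rd(out.loc[mask, f"oriented_{dim}"].to_numpy(), dim)
            col[mask] = dv.rd
            summary[dim] = {"n": dv.n, "mu": dv.mu, "gini": float(dv.rd.mean())}
        else:
            summary[dim] = {"n": 0, "mu": float("nan"), "gini": float("nan")}
        out[f"rd_{dim}"] = col
    return out, summary
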