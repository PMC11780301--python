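"""Propensity-score matching sensitivity analysis.

Propensity scores come from a maximum-likelihood logistic regression of
the binary exposure on the control covariates. Treated units are matched
1:1 to controls by nearest-neighbor on the propensity score, greedily in
descending treated propensity order, without replacement; distance ties
go to the lowest control index, so matching is fully deterministic. An
optional caliper drops treated units with no control within the distance.

The average treatment effect on the treated (ATT) is the mean within-pair
outcome difference, with SE and two-tailed p from a paired t test.
Covariate balance is assessed by absolute standardized mean differences
(SMD) before matching (full arms) and after matching (matched samples);
post-match SMD below 0.20 (20%) is the conventional adequacy criterion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import RankDeficiencyError, SeparationError, ValidationError

__all__ = [
    "MatchOutput",
    "BalanceReport",
    "estimate_propensity",
    "match_nn",
    "estimate_att",
    "balance_table",
    "run_psm",
]


@dataclass
class MatchOutput:
    propensity: np.ndarray
    pairs: list[tuple[int, int]]        # (treated index, control index)
    att: float
    att_se: float
    att_p: float
    treated_mean: float
    control_mean: float
    dropped_treated: int
    n_pairs: int = 0

    def __post_init__(self):
        self.n_pairs = len(self.pairs)


@dataclass
class BalanceReport:
    table: pd.DataFrame                 # per covariate: smd_before, smd_after, flagged
    support: dict = field(default_factory=dict)
    density: pd.DataFrame | None = None


def estimate_propensity(D, X) -> np.ndarray:
    """Fit a logistic propensity model by maximum likelihood.

    Parameters
    ----------
    D : 0/1 array
        Treatment indicator; both arms must be nonempty.
    X : DataFrame or 2-D array
        Covariate matrix (a constant is added internally); must be full
        rank.

    Returns probabilities in (0, 1). Raises :class:`SeparationError` on
    perfect separation, with advice to reduce the covariate set.
    """
    D = np.asarray(D, dtype=float)
    if set(np.unique(D)) - {0.0, 1.0}:
        raise ValidationError("treatment indicator must be 0/1")
    if D.sum() == 0 or D.sum() == D.size:
        raise ValidationError("both treatment arms must be nonempty")
    Xarr = np.asarray(X, dtype=float)
    cols = list(X.columns) if isinstance(X, pd.DataFrame) else [
        f"x{i}" for i in range(Xarr.shape[1])
    ]
    sd = Xarr.std(axis=0)
    const = [c for c, s in zip(cols, sd) if s == 0]
    if const:
        raise RankDeficiencyError(f"constant columns: {const}")
    if np.linalg.matrix_rank(Xarr - Xarr.mean(axis=0)) < Xarr.shape[1]:
        raise RankDeficiencyError("covariate matrix is rank deficient")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(D, sm.add_constant(Xarr)).fit(disp=0)
        except Exception as exc:  # PerfectSeparationError and kin
            raise SeparationError(
                "propensity model failed (possible perfect separation); "
                f"consider reducing the covariate set: {exc}"
            ) from exc
    p = np.asarray(fit.predict(sm.add_constant(Xarr)))
    if np.any(p <= 0) or np.any(p >= 1):
        raise SeparationError(
            "degenerate propensity probabilities (perfect separation); "
            "consider reducing the covariate set"
        )
    return p


def match_nn(
    propensity, D, caliper: float | None = None
) -> tuple[list[tuple[int, int]], int]:
    """Greedy 1:1 nearest-neighbor matching without replacement.

    Treated units are processed in descending propensity order (ties by
    lowest treated index); each takes the unused control with the closest
    propensity, distance ties broken by lowest control index. With a
    caliper, treated units whose nearest available control is farther
    than the caliper are dropped. Without one, treated units beyond the
    control count are dropped with a warning.

    Returns ``(pairs, dropped_treated)`` with pairs as positional
    ``(treated, control)`` indices into the input vectors.
    """
    ps = np.asarray(propensity, dtype=float)
    D = np.asarray(D, dtype=float)
    t_idx = np.flatnonzero(D == 1)
    c_idx = np.flatnonzero(D == 0)
    if t_idx.size == 0:
        raise ValidationError("no treated units to match")
    if c_idx.size == 0:
        raise ValidationError("no control units available")
    if caliper is None and t_idx.size > c_idx.size:
        warnings.warn(
            f"{t_idx.size - c_idx.size} treated units beyond control count "
            "will be dropped"
        )
    # descending propensity, stable so equal propensities keep index order
    order = t_idx[np.lexsort((t_idx, -ps[t_idx]))]
    c_ps = ps[c_idx]
    available = np.ones(c_idx.size, dtype=bool)
    pairs: list[tuple[int, int]] = []
    dropped = 0
    for t in order:
        if not available.any():
            dropped += 1
            continue
        dist = np.abs(c_ps - ps[t])
        dist[~available] = np.inf
        j = int(np.argmin(dist))  # first minimum = lowest control index
        if caliper is not None and dist[j] > caliper:
            dropped += 1
            continue
        available[j] = False
        pairs.append((int(t), int(c_idx[j])))
    return pairs, dropped


def estimate_att(outcome, pairs) -> tuple[float, float, float, float, float]:
    """ATT over matched pairs with a paired two-tailed t test.

    Returns ``(att, se, p, treated_mean, control_mean)``. With zero
    variance of the within-pair differences the SE is 0 and p is reported
    as 0 (att != 0) or 1 (att == 0), with a warning.
    """
    if len(pairs) < 2:
        raise ValidationError("need at least 2 matched pairs")
    y = np.asarray(outcome, dtype=float)
    t = np.array([p[0] for p in pairs])
    c = np.array([p[1] for p in pairs])
    diffs = y[t] - y[c]
    att = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    k = diffs.size
    if sd == 0:
        warnings.warn("zero variance of within-pair differences")
        return att, 0.0, 0.0 if att != 0 else 1.0, float(y[t].mean()), float(y[c].mean())
    se = sd / np.sqrt(k)
    tstat = att / se
    p = float(2 * stats.t.sf(abs(tstat), df=k - 1))
    return att, float(se), p, float(y[t].mean()), float(y[c].mean())


def _smd(x_t: np.ndarray, x_c: np.ndarray) -> float:
    """|mean_T - mean_C| / sqrt((var_T + var_C)/2); 0 if both degenerate
    with equal means, NaN if degenerate with unequal means."""
    num = abs(float(x_t.mean()) - float(x_c.mean()))
    pooled = np.sqrt((x_t.var(ddof=1) + x_c.var(ddof=1)) / 2.0)
    if pooled == 0:
        return 0.0 if num == 0 else float("nan")
    return num / pooled


def balance_table(
    X: pd.DataFrame,
    D,
    pairs,
    propensity=None,
    threshold: float = 0.20,
) -> BalanceReport:
    """Standardized-mean-difference balance diagnostics.

    ``smd_before`` compares the full treated and control arms;
    ``smd_after`` compares the matched treated and matched control
    samples. Covariates with ``smd_after >= threshold`` are flagged.
    When propensity scores are supplied, the report also carries
    per-arm propensity support ranges and Gaussian-KDE summary
    statistics (Silverman bandwidth, fixed grid) before/after matching.
    """
    D = np.asarray(D, dtype=float)
    t_all = D == 1
    c_all = D == 0
    t_m = np.array([p[0] for p in pairs], dtype=int)
    c_m = np.array([p[1] for p in pairs], dtype=int)
    rows = []
    for col in X.columns:
        x = X[col].to_numpy(dtype=float)
        before = _smd(x[t_all], x[c_all])
        after = _smd(x[t_m], x[c_m])
        rows.append((col, before, after, after >= threshold))
    table = pd.DataFrame(
        rows, columns=["covariate", "smd_before", "smd_after", "flagged"]
    ).set_index("covariate")
    table["smd_before_pct"] = 100 * table["smd_before"]
    table["smd_after_pct"] = 100 * table["smd_after"]

    support: dict = {}
    density = None
    if propensity is not None:
        ps = np.asarray(propensity, dtype=float)
        support = {
            "treated_range": (float(ps[t_all].min()), float(ps[t_all].max())),
            "control_range": (float(ps[c_all].min()), float(ps[c_all].max())),
        }
        density = _density_summary(ps, t_all, c_all, t_m, c_m)
    return BalanceReport(table=table, support=support, density=density)


def _density_summary(ps, t_all, c_all, t_m, c_m) -> pd.DataFrame:
    """Summary statistics of the propensity distributions per arm, plus the
    peak location of a Silverman-bandwidth Gaussian KDE on a fixed grid."""
    grid = np.linspace(0.0, 1.0, 201)
    rows = []
    for label, sel in (
        ("treated_before", ps[t_all]),
        ("control_before", ps[c_all]),
        ("treated_after", ps[t_m]),
        ("control_after", ps[c_m]),
    ):
        q1, med, q3 = np.percentile(sel, [25, 50, 75])
        peak = float("nan")
        if sel.size > 1 and np.ptp(sel) > 0:
            kde = stats.gaussian_kde(sel)  # Silverman by default in scipy
            kde.set_bandwidth("silverman")
            peak = float(grid[np.argmax(kde(grid))])
        rows.append(
            (label, sel.size, float(sel.mean()), float(sel.std(ddof=1)),
             float(q1), float(med), float(q3), peak)
        )
    return pd.DataFrame(
        rows,
        columns=["arm", "n", "mean", "sd", "q1", "median", "q3", "kde_peak"],
    ).set_index("arm")


def run_psm(
    table: pd.DataFrame,
    outcome: str,
    exposure: str,
    covariates,
    caliper: float | None = None,
) -> tuple[MatchOutput, BalanceReport]:
    """Full matching analysis on a listwise-complete block of ``table``.

    Builds the covariate matrix (same expansion as the outcome models),
    fits the propensity model, matches, and returns ATT and balance.
    """
    from .inference import _prepare_covariates

    cov = _prepare_covariates(table)
    block = pd.concat(
        [table[[outcome, exposure]].astype(float), cov[list(covariates)]],
        axis=1,
    ).dropna()
    y = block[outcome].to_numpy()
    D = block[exposure].to_numpy()
    X = block[list(covariates)]
    ps = estimate_propensity(D, X)
    pairs, dropped = match_nn(ps, D, caliper)
    att, se, p, tm, cm = estimate_att(y, pairs)
    out = MatchOutput(
        propensity=ps, pairs=pairs, att=att, att_se=se, att_p=p,
        treated_mean=tm, control_mean=cm, dropped_treated=dropped,
    )
    bal = balance_table(X.reset_index(drop=True), D, pairs, propensity=ps)
    return out, bal
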