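"""Covariate-adjusted models of health deprivation on digital exposure.

The outcome model is an ordinary least-squares regression of a per-person
deprivation index on the digital exposure (access 0/1 or use 0-3) and the
standard control set: sex, age, hukou, education dummies, marital status,
insurance dummies, chronic disease, disability, outpatient visits,
intergenerational support, log household income (winsorized bilaterally
before the log), and region dummies (eastern = reference). Reported
coefficients are fully standardized: the outcome and every regressor —
dummies included — are z-scored before fitting, so a beta is the expected
SD change in deprivation per SD change in the regressor. Standard errors
are classical (homoskedastic).

Also provided: univariate screening (chi-square for categoricals, t test
or Wilcoxon rank-sum for continuous variables depending on a Shapiro
normality check), interaction-based moderation, and subgroup fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import RankDeficiencyError, ValidationError

__all__ = [
    "DesignMatrix",
    "ModelResult",
    "trim_and_log_income",
    "build_design",
    "fit_outcome_model",
    "fit_moderation",
    "subgroup_fit",
    "univariate_screen",
    "DEFAULT_COVARIATES",
]

#: Design-matrix covariate columns, in reporting order. Education reference
#: is "no formal education", insurance reference "other medical insurance",
#: region reference "eastern".
DEFAULT_COVARIATES = (
    "sex",
    "age",
    "hukou",
    "edu_elementary",
    "edu_junior_plus",
    "marital",
    "ins_employee",
    "ins_resident",
    "chronic",
    "disability",
    "outpatient_visits",
    "intergenerational_support",
    "log_income",
    "region_central",
    "region_western",
    "region_northeast",
)


@dataclass
class DesignMatrix:
    """Listwise-complete outcome/exposure/covariate block for one model."""

    y: pd.Series
    X: pd.DataFrame           # exposure first, then covariates
    exposure: str
    outcome: str
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.y)


@dataclass
class ModelResult:
    """Standardized OLS fit for one outcome model."""

    terms: pd.DataFrame       # index: term; columns: beta, se, p
    n: int
    r_squared: float
    outcome: str
    exposure: str
    subgroup: str | None = None

    def beta(self, term: str) -> float:
        return float(self.terms.loc[term, "beta"])

    def se(self, term: str) -> float:
        return float(self.terms.loc[term, "se"])

    def p(self, term: str) -> float:
        return float(self.terms.loc[term, "p"])


def trim_and_log_income(
    income, limits: tuple[float, float] = (0.01, 0.01)
) -> np.ndarray:
    """Winsorize income at the 1st/99th percentiles then log10(x + 1).

    ``limits`` are the lower/upper tail fractions clipped to the
    corresponding percentile value. Missing entries stay missing.
    """
    x = np.asarray(income, dtype=float)
    obs = x[~np.isnan(x)]
    if obs.size == 0:
        raise ValidationError("income: all values missing")
    if np.any(obs < 0):
        raise ValidationError("income: negative values")
    lo = np.percentile(obs, 100 * limits[0])
    hi = np.percentile(obs, 100 * (1 - limits[1]))
    return np.log10(np.clip(x, lo, hi) + 1.0)


def _prepare_covariates(
    table: pd.DataFrame, winsor_limits: tuple[float, float] = (0.01, 0.01)
) -> pd.DataFrame:
    """Expand raw cohort columns into the dummy-coded covariate block."""
    cov = pd.DataFrame(index=table.index)
    for col in ("sex", "age", "hukou", "marital", "chronic", "disability",
                "outpatient_visits", "intergenerational_support"):
        cov[col] = table[col].astype(float)
    edu = table["education"].astype(float)
    cov["edu_elementary"] = (edu == 1).astype(float)
    cov["edu_junior_plus"] = (edu == 2).astype(float)
    ins = table["insurance"].astype(float)
    cov["ins_employee"] = (ins == 1).astype(float)
    cov["ins_resident"] = (ins == 2).astype(float)
    cov["log_income"] = trim_and_log_income(
        table["income"].to_numpy(), winsor_limits
    )
    region = table["region"].astype(float)
    cov["region_central"] = (region == 1).astype(float)
    cov["region_western"] = (region == 2).astype(float)
    cov["region_northeast"] = (region == 3).astype(float)
    return cov


def build_design(
    table: pd.DataFrame,
    outcome: str,
    exposure: str,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    winsor_limits: tuple[float, float] = (0.01, 0.01),
) -> DesignMatrix:
    """Assemble the listwise-deleted design matrix for one outcome model.

    ``outcome`` and ``exposure`` name columns of ``table`` (e.g. an
    ``rd_<dim>`` column and ``access``); covariates are drawn from the
    expanded control block. Rows with any missing cell among the model's
    variables are dropped.
    """
    cov = _prepare_covariates(table, winsor_limits)
    missing = [c for c in covariates if c not in cov.columns]
    if missing:
        raise ValidationError(f"unknown covariates: {missing}")
    block = pd.concat(
        [table[[outcome, exposure]].astype(float), cov[list(covariates)]],
        axis=1,
    )
    block = block.dropna()
    y = block[outcome]
    X = block[[exposure, *covariates]]
    return DesignMatrix(y=y, X=X, exposure=exposure, outcome=outcome)


def _zscore(a: np.ndarray) -> np.ndarray:
    sd = a.std(axis=0, ddof=1)
    return (a - a.mean(axis=0)) / sd


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    sd = arr.std(axis=0, ddof=0)
    const = [c for c, s in zip(X.columns, sd) if s == 0]
    if const:
        raise RankDeficiencyError(f"constant columns: {const}")
    if np.linalg.matrix_rank(arr - arr.mean(axis=0)) < arr.shape[1]:
        corr = np.corrcoef(arr, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
        raise RankDeficiencyError(
            f"collinear columns (|r|={abs(corr[i, j]):.4f}): "
            f"{X.columns[i]}, {X.columns[j]}"
        )


def fit_outcome_model(dm: DesignMatrix) -> ModelResult:
    """Fit the standardized OLS outcome model with classical SEs."""
    if dm.n <= dm.X.shape[1] + 1:
        raise ValidationError(
            f"n={dm.n} too small for {dm.X.shape[1]} terms"
        )
    _check_rank(dm.X)
    Z = _zscore(dm.X.to_numpy(dtype=float))
    zy = _zscore(dm.y.to_numpy(dtype=float))
    fit = sm.OLS(zy, sm.add_constant(Z)).fit()
    terms = pd.DataFrame(
        {
            "beta": fit.params[1:],
            "se": fit.bse[1:],
            "p": fit.pvalues[1:],
        },
        index=list(dm.X.columns),
    )
    return ModelResult(
        terms=terms,
        n=dm.n,
        r_squared=float(fit.rsquared),
        outcome=dm.outcome,
        exposure=dm.exposure,
    )


def fit_moderation(dm: DesignMatrix, moderator: str) -> ModelResult:
    """Add a centered exposure-by-moderator interaction and refit.

    The exposure and the moderator are mean-centered before forming the
    product, so main effects keep their interpretation at the sample
    means. The interaction term is reported as
    ``<exposure>:<moderator>``.
    """
    if moderator == dm.exposure:
        raise ValidationError("moderator identical to exposure")
    if moderator not in dm.X.columns:
        raise ValidationError(f"moderator {moderator!r} not in design")
    d = dm.X[dm.exposure].to_numpy(dtype=float)
    m = dm.X[moderator].to_numpy(dtype=float)
    if m.std(ddof=0) == 0:
        raise ValidationError(f"moderator {moderator!r} is constant")
    inter = (d - d.mean()) * (m - m.mean())
    X2 = dm.X.copy()
    X2[f"{dm.exposure}:{moderator}"] = inter
    dm2 = DesignMatrix(
        y=dm.y, X=X2, exposure=dm.exposure, outcome=dm.outcome, meta=dm.meta
    )
    return fit_outcome_model(dm2)


#: Canonical subgroup splits: column name -> level labels.
def _split_levels(table: pd.DataFrame, split: str) -> dict[str, pd.DataFrame]:
    if split == "sex":
        return {"female": table[table.sex == 0], "male": table[table.sex == 1]}
    if split == "age60":
        return {
            "age<60": table[table.age < 60],
            "age>=60": table[table.age >= 60],
        }
    if split == "hukou":
        return {
            "urban": table[table.hukou == 0],
            "rural": table[table.hukou == 1],
        }
    if split == "education":
        return {
            "no_formal": table[table.education == 0],
            "elementary": table[table.education == 1],
            "junior_plus": table[table.education == 2],
        }
    if split == "region":
        labels = ["eastern", "central", "western", "northeast"]
        return {lab: table[table.region == k] for k, lab in enumerate(labels)}
    raise ValidationError(f"unknown subgroup split {split!r}")


#: Covariates to drop when a split makes them constant within levels.
_SPLIT_DROPS = {
    "sex": ("sex",),
    "age60": (),
    "hukou": ("hukou",),
    "education": ("edu_elementary", "edu_junior_plus"),
    "region": ("region_central", "region_western", "region_northeast"),
}


def subgroup_fit(
    table: pd.DataFrame,
    split: str,
    outcome: str,
    exposure: str,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    min_size: int = 50,
) -> dict[str, ModelResult]:
    """Fit the outcome model within each level of a canonical split.

    Splits: ``sex``, ``age60`` (< 60 vs >= 60), ``hukou``, ``education``,
    ``region``. The splitting variable (and its dummies) is removed from
    the covariate set. Levels smaller than ``min_size`` rows are skipped
    with a warning.
    """
    drops = set(_SPLIT_DROPS[split]) if split in _SPLIT_DROPS else set()
    covs = [c for c in covariates if c not in drops]
    results: dict[str, ModelResult] = {}
    for label, sub in _split_levels(table, split).items():
        if len(sub) < min_size:
            warnings.warn(
                f"subgroup {split}={label} has {len(sub)} rows "
                f"(< {min_size}); skipped"
            )
            continue
        dm = build_design(sub, outcome, exposure, covs)
        if dm.n < min_size:
            warnings.warn(
                f"subgroup {split}={label} has {dm.n} complete rows "
                f"(< {min_size}); skipped"
            )
            continue
        try:
            res = fit_outcome_model(dm)
        except RankDeficiencyError as exc:
            # e.g. a reference category absent within the level
            warnings.warn(f"subgroup {split}={label} skipped: {exc}")
            continue
        res.subgroup = f"{split}={label}"
        results[label] = res
    return results


def univariate_screen(
    table: pd.DataFrame,
    group: str,
    variables: Mapping[str, str],
    alpha: float = 0.05,
    shapiro_max_n: int = 5000,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-variable association tests against a binary grouping.

    ``variables`` maps column name to ``"categorical"`` or
    ``"continuous"``. Categorical variables get an (uncorrected)
    chi-square test of independence. Continuous variables get a two-sample
    t test when a Shapiro-Wilk check (on a subsample of at most
    ``shapiro_max_n`` per group) does not reject normality in either group
    at ``alpha``, else a Wilcoxon rank-sum test. Degenerate contingency
    tables (a zero margin) are skipped with a warning.

    Returns a tidy frame with columns ``variable, test, statistic, p``.
    """
    rng = rng or np.random.default_rng(0)
    g = table[group].to_numpy(dtype=float)
    levels = np.unique(g[~np.isnan(g)])
    if len(levels) != 2:
        raise ValidationError(f"group {group!r} is not binary")
    rows = []
    for var, kind in variables.items():
        pair = table[[var, group]].dropna()
        x = pair[var].to_numpy(dtype=float)
        gg = pair[group].to_numpy(dtype=float)
        if kind == "categorical":
            tab = pd.crosstab(x, gg)
            if (tab.shape[0] < 2 or tab.shape[1] < 2
                    or (tab.sum(axis=0) == 0).any()
                    or (tab.sum(axis=1) == 0).any()):
                warnings.warn(f"{var}: degenerate contingency table; skipped")
                continue
            chi2, p, _, _ = stats.chi2_contingency(
                tab.to_numpy(), correction=False
            )
            rows.append((var, "chi-square", float(chi2), float(p)))
        elif kind == "continuous":
            a = x[gg == levels[0]]
            b = x[gg == levels[1]]
            normal = True
            for arm in (a, b):
                sub = arm
                if sub.size > shapiro_max_n:
                    sub = rng.choice(sub, shapiro_max_n, replace=False)
                if sub.size < 3 or np.ptp(sub) == 0:
                    normal = False
                    break
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    if stats.shapiro(sub).pvalue < alpha:
                        normal = False
                        break
            if normal:
                t, p = stats.ttest_ind(a, b)
                rows.append((var, "t test", float(t), float(p)))
            else:
                u, p = stats.ranksums(a, b)
                rows.append((var, "wilcoxon rank-sum", float(u), float(p)))
        else:
            raise ValidationError(f"{var}: unknown variable kind {kind!r}")
    return pd.DataFrame(rows, columns=["variable", "test", "statistic", "p"])
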