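import numpy as np
import pandas as pd
import pytest

import healthgap as hg
from healthgap.errors import RankDeficiencyError, ValidationError
from healthgap.inference import DEFAULT_COVARIATES

from conftest import process


# ---------------------------------------------------------------- income

def test_trim_and_log_income_constant_vector_is_noop():
    out = hg.trim_and_log_income(np.full(50, 9.0))
    np.testing.assert_allclose(out, np.log10(10.0))


def test_trim_and_log_income_zero_maps_to_zero():
    out = hg.trim_and_log_income(np.array([0.0] * 200))
    assert out[0] == 0.0


def test_trim_and_log_income_winsorizes_extreme_outlier(rng):
    x = rng.uniform(1, 10, size=500)
    x[0] = 1e9
    out = hg.trim_and_log_income(x)
    hi = np.percentile(x, 99)  # percentile oracle on the raw vector
    assert out[0] == pytest.approx(np.log10(hi + 1))
    assert np.all(np.isfinite(out))


def test_trim_and_log_income_all_missing():
    with pytest.raises(ValidationError, match="missing"):
        hg.trim_and_log_income(np.array([np.nan, np.nan]))


# ---------------------------------------------------------------- OLS

def ols_oracle(X, y):
    """Normal-equations oracle (X'X)^-1 X'y on the standardized design."""
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    zy = (y - y.mean()) / y.std(ddof=1)
    Z1 = np.column_stack([np.ones(len(y)), Z])
    return np.linalg.solve(Z1.T @ Z1, Z1.T @ zy)[1:]


def test_fit_matches_normal_equations(processed_2018):
    dm = hg.build_design(processed_2018, "rd_cognition", "access")
    res = hg.fit_outcome_model(dm)
    expected = ols_oracle(dm.X.to_numpy(dtype=float), dm.y.to_numpy())
    np.testing.assert_allclose(res.terms["beta"].to_numpy(), expected, atol=1e-8)
    assert res.n == dm.n
    assert 0 <= res.r_squared <= 1
    assert ((res.terms["p"] >= 0) & (res.terms["p"] <= 1)).all()


def test_perfect_linear_fit():
    rng = np.random.default_rng(0)
    n = 200
    d = rng.integers(0, 2, n).astype(float)
    df = pd.DataFrame({"y": 2.0 + 3.0 * d, "d": d})
    dm = hg.DesignMatrix(y=df["y"], X=df[["d"]], exposure="d", outcome="y")
    res = hg.fit_outcome_model(dm)
    assert res.beta("d") == pytest.approx(1.0, abs=1e-10)
    assert res.r_squared == pytest.approx(1.0, abs=1e-10)


def test_permuted_exposure_is_null(processed_2018, rng):
    table = processed_2018.copy()
    table["access"] = rng.permutation(table["access"].to_numpy())
    res = hg.fit_outcome_model(hg.build_design(table, "rd_cognition", "access"))
    assert abs(res.beta("access")) < 3 * res.se("access")


def test_standardized_beta_invariant_to_covariate_rescaling(processed_2018):
    t1 = processed_2018.copy()
    res1 = hg.fit_outcome_model(hg.build_design(t1, "rd_cognition", "access"))
    t2 = processed_2018.copy()
    t2["age"] = 12.0 * t2["age"] - 300.0  # affine rescale (months, shifted)
    res2 = hg.fit_outcome_model(hg.build_design(t2, "rd_cognition", "access"))
    assert res1.beta("access") == pytest.approx(res2.beta("access"), abs=1e-10)
    assert abs(res1.beta("age")) == pytest.approx(abs(res2.beta("age")), abs=1e-10)


def test_rank_deficiency_lists_columns(processed_2018):
    dm = hg.build_design(processed_2018, "rd_cognition", "access")
    X = dm.X.copy()
    X["age_copy"] = X["age"]
    dm2 = hg.DesignMatrix(y=dm.y, X=X, exposure="access", outcome="rd_cognition")
    with pytest.raises(RankDeficiencyError, match="age"):
        hg.fit_outcome_model(dm2)


# ---------------------------------------------------------------- moderation

def test_moderation_null_interaction(processed_2018):
    # generator tau is homogeneous here: interaction with sex ~ 0
    dm = hg.build_design(processed_2018, "rd_cognition", "access")
    res = hg.fit_moderation(dm, "sex")
    term = "access:sex"
    assert abs(res.beta(term)) < 3 * res.se(term)


def test_moderation_detects_sex_specific_effect():
    # tau larger for men -> negative access x sex interaction on deprivation
    hits = 0
    for s in range(25):
        cfg = hg.SyntheticConfig(
            n=3000, seed=6000 + s, confounding_strength=0.5,
            treatment_effect_tau=0.2, tau_heterogeneity={"sex": 0.8},
        )
        t = process(cfg)
        dm = hg.build_design(t, "rd_cognition", "access")
        res = hg.fit_moderation(dm, "sex")
        hits += res.beta("access:sex") < 0
    assert hits >= 24  # sign recovered in >= 95% of runs


def test_moderation_degenerate_inputs(processed_2018):
    dm = hg.build_design(processed_2018, "rd_cognition", "access")
    with pytest.raises(ValidationError, match="identical"):
        hg.fit_moderation(dm, "access")
    X = dm.X.copy()
    X["const_col"] = 1.0
    dm2 = hg.DesignMatrix(y=dm.y, X=X, exposure="access", outcome="rd_cognition")
    with pytest.raises((ValidationError, RankDeficiencyError)):
        hg.fit_moderation(dm2, "const_col")


# ---------------------------------------------------------------- subgroups

def test_subgroup_partition_conserves_n(processed_2018):
    full = hg.fit_outcome_model(
        hg.build_design(processed_2018, "rd_cognition", "access")
    )
    for split in ("sex", "age60", "hukou"):
        subs = hg.subgroup_fit(
            processed_2018, split, "rd_cognition", "access", min_size=10
        )
        assert sum(r.n for r in subs.values()) == full.n


def test_subgroup_small_level_skipped(processed_2018):
    with pytest.warns(UserWarning, match="skipped"):
        subs = hg.subgroup_fit(
            processed_2018, "region", "rd_cognition", "access", min_size=10**6
        )
    assert subs == {}


def test_subgroup_labels_recorded(processed_2018):
    subs = hg.subgroup_fit(processed_2018, "hukou", "rd_cognition", "access")
    assert set(subs) == {"urban", "rural"}
    assert subs["rural"].subgroup == "hukou=rural"


# ---------------------------------------------------------------- univariate

def test_chi_square_independence_and_perfect_association():
    # balanced 2x2 -> chi2 = 0, p = 1
    df = pd.DataFrame({
        "g": [0] * 20 + [1] * 20,
        "x": [0] * 10 + [1] * 10 + [0] * 10 + [1] * 10,
    })
    rep = hg.univariate_screen(df, "g", {"x": "categorical"})
    assert rep.statistic[0] == pytest.approx(0.0, abs=1e-12)
    assert rep.p[0] == pytest.approx(1.0)
    # diagonal 2x2 ((20,0),(0,20)) -> uncorrected chi2 = 40
    df2 = pd.DataFrame({"g": [0] * 20 + [1] * 20, "x": [0] * 20 + [1] * 20})
    rep2 = hg.univariate_screen(df2, "g", {"x": "categorical"})
    assert rep2.statistic[0] == pytest.approx(40.0)
    assert rep2.p[0] < 0.001


def test_identical_continuous_samples_null(rng):
    x = rng.normal(size=200)
    df = pd.DataFrame({"g": [0] * 200 + [1] * 200, "x": np.concatenate([x, x])})
    rep = hg.univariate_screen(df, "g", {"x": "continuous"})
    assert rep.p[0] > 0.99


def test_degenerate_category_skipped():
    df = pd.DataFrame({"g": [0, 0, 1, 1], "x": [1, 1, 1, 1]})
    with pytest.warns(UserWarning, match="degenerate"):
        rep = hg.univariate_screen(df, "g", {"x": "categorical"})
    assert rep.empty


def test_screen_on_cohort(processed_2018):
    rep = hg.univariate_screen(
        processed_2018, "access",
        {"education": "categorical", "age": "continuous"},
    )
    assert set(rep.variable) == {"education", "age"}
    # both are genuine confounders of access: strongly associated
    assert (rep.p < 0.01).all()
    assert rep.loc[rep.variable == "education", "test"].item() == "chi-square"
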