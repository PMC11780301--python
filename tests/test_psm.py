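import numpy as np
import pandas as pd
import pytest

import healthgap as hg
from healthgap.errors import RankDeficiencyError, SeparationError, ValidationError
from healthgap.inference import DEFAULT_COVARIATES

from conftest import process


# ------------------------------------------------------------ propensity

def test_null_propensity_concentrates_at_treated_share(rng):
    n = 2000
    D = (rng.random(n) < 0.3).astype(float)
    X = pd.DataFrame({"x1": rng.normal(size=n), "x2": rng.normal(size=n)})
    p = hg.estimate_propensity(D, X)
    assert np.all((p > 0) & (p < 1))
    assert abs(p.mean() - D.mean()) < 0.01
    assert p.std() < 0.05  # no real signal


def test_logit_coefficient_recovery(rng):
    # single strong covariate with known coefficients
    n, b0, b1 = 4000, -0.5, 1.2
    x = rng.normal(size=n)
    p_true = 1 / (1 + np.exp(-(b0 + b1 * x)))
    D = (rng.random(n) < p_true).astype(float)
    import statsmodels.api as sm

    fit = sm.Logit(D, sm.add_constant(x)).fit(disp=0)
    assert abs(fit.params[1] - b1) < 3 * fit.bse[1]
    # package path produces the same probabilities
    p = hg.estimate_propensity(D, pd.DataFrame({"x": x}))
    np.testing.assert_allclose(p, fit.predict(sm.add_constant(x)), atol=1e-8)


def test_propensity_degenerate_inputs(rng):
    D = np.array([0, 1] * 20, dtype=float)
    with pytest.raises(RankDeficiencyError, match="constant"):
        hg.estimate_propensity(D, pd.DataFrame({"c": np.ones(40)}))
    with pytest.raises(ValidationError, match="nonempty"):
        hg.estimate_propensity(np.ones(10), pd.DataFrame({"x": rng.normal(size=10)}))
    # perfectly separating covariate
    x = np.concatenate([np.zeros(20), np.ones(20)])
    with pytest.raises(SeparationError):
        hg.estimate_propensity(x, pd.DataFrame({"x": x}))


# ------------------------------------------------------------ matching

def test_nearest_neighbor_picks_closest():
    ps = np.array([0.8, 0.1, 0.79])
    D = np.array([1, 0, 0])
    pairs, dropped = hg.match_nn(ps, D)
    assert pairs == [(0, 2)] and dropped == 0


def test_tie_broken_by_lowest_control_index():
    ps = np.array([0.5, 0.5, 0.5, 0.5])
    D = np.array([1, 1, 0, 0])
    pairs, dropped = hg.match_nn(ps, D)
    assert pairs == [(0, 2), (1, 3)] and dropped == 0


def test_caliper_drops_distant_treated():
    ps = np.array([0.5, 0.55])
    D = np.array([1, 0])
    pairs, dropped = hg.match_nn(ps, D, caliper=0.01)
    assert pairs == [] and dropped == 1


def test_excess_treated_dropped_with_warning():
    ps = np.array([0.6, 0.5, 0.4])
    D = np.array([1, 1, 0])
    with pytest.warns(UserWarning, match="beyond control count"):
        pairs, dropped = hg.match_nn(ps, D)
    assert len(pairs) == 1 and dropped == 1
    assert pairs == [(0, 2)]  # highest propensity treated matched first


def test_matching_deterministic(processed_2018):
    m1, _ = hg.run_psm(processed_2018, "rd_cognition", "access", DEFAULT_COVARIATES)
    m2, _ = hg.run_psm(processed_2018, "rd_cognition", "access", DEFAULT_COVARIATES)
    assert m1.pairs == m2.pairs
    assert m1.att == m2.att


def test_every_treated_once_every_partner_a_control(processed_2018):
    m, _ = hg.run_psm(processed_2018, "rd_cognition", "access", DEFAULT_COVARIATES)
    treated = [t for t, _ in m.pairs]
    controls = [c for _, c in m.pairs]
    assert len(set(treated)) == len(treated)
    assert len(set(controls)) == len(controls)


# ------------------------------------------------------------ ATT

def test_att_identity_and_constant_differences():
    y = np.array([3.0, 1.0, 5.0, 3.0, 7.0, 5.0])
    pairs = [(0, 1), (2, 3), (4, 5)]
    with pytest.warns(UserWarning, match="zero variance"):
        att, se, p, tm, cm = hg.estimate_att(y, pairs)
    assert att == 2.0 and se == 0.0 and p == 0.0
    assert att == pytest.approx(tm - cm, abs=1e-12)


def test_att_equals_mean_pair_difference(processed_2018):
    m, _ = hg.run_psm(processed_2018, "rd_cognition", "access", DEFAULT_COVARIATES)
    assert m.att == pytest.approx(m.treated_mean - m.control_mean, abs=1e-12)
    assert 0 <= m.att_p <= 1


def test_att_needs_two_pairs():
    with pytest.raises(ValidationError, match="2 matched pairs"):
        hg.estimate_att(np.arange(4.0), [(0, 1)])


def test_randomized_design_att_matches_naive_difference():
    # unconfounded assignment: matching should reproduce the naive
    # difference-in-means within Monte-Carlo error
    atts, naives = [], []
    for s in range(20):
        cfg = hg.SyntheticConfig(
            n=1500, seed=7000 + s, confounding_strength=0.0,
            treatment_effect_tau=0.5,
        )
        t = process(cfg)
        m, _ = hg.run_psm(t, "rd_cognition", "access", DEFAULT_COVARIATES)
        sub = t.dropna(subset=["rd_cognition"])
        naives.append(
            sub.rd_cognition[sub.access == 1].mean()
            - sub.rd_cognition[sub.access == 0].mean()
        )
        atts.append(m.att)
    assert np.mean(atts) == pytest.approx(np.mean(naives), abs=0.005)


# ------------------------------------------------------------ balance

def test_smd_direct_formula(rng):
    x = np.concatenate([rng.normal(1, 1, 500), rng.normal(0, 1, 500)])
    D = np.array([1] * 500 + [0] * 500)
    pairs = list(zip(range(500), range(500, 1000)))
    rep = hg.balance_table(pd.DataFrame({"x": x}), D, pairs)
    mt, mc = x[:500], x[500:]
    expected = abs(mt.mean() - mc.mean()) / np.sqrt(
        (mt.var(ddof=1) + mc.var(ddof=1)) / 2
    )
    assert rep.table.loc["x", "smd_before"] == pytest.approx(expected)
    assert rep.table.loc["x", "smd_before_pct"] == pytest.approx(100 * expected)


def test_identical_distributions_zero_smd():
    x = np.tile(np.arange(10.0), 4)
    D = np.array([1] * 20 + [0] * 20)
    pairs = list(zip(range(20), range(20, 40)))
    rep = hg.balance_table(pd.DataFrame({"x": x}), D, pairs)
    assert rep.table.loc["x", "smd_before"] == 0.0
    assert rep.table.loc["x", "smd_after"] == 0.0


def test_balance_report_support_and_density(processed_2018):
    m, rep = hg.run_psm(processed_2018, "rd_cognition", "access", DEFAULT_COVARIATES)
    lo, hi = rep.support["treated_range"]
    assert 0 < lo <= hi < 1
    assert set(rep.density.index) == {
        "treated_before", "control_before", "treated_after", "control_after"
    }
    assert (rep.density["n"] > 0).all()
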