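"""Synthetic CHARLS-like cohort generator.

Emulates a national ageing-survey cohort (respondents aged 50+) with the
demographic, digital-connectivity and health-instrument columns the
pipeline consumes, under a known ground-truth structure so every
downstream stage can be tested without restricted microdata:

* covariates are drawn from wave-specific marginal prevalences loosely
  calibrated to the 2018 and 2020 survey waves (e.g. household broadband
  ~39% in 2018 vs ~57% in 2020);
* digital connectivity (broadband, smart devices, other digital devices)
  is confounded with education, age, hukou and income through a shared
  linear index whose weight is ``confounding_strength``;
* latent health is a linear index of covariates plus the same confounder
  index, shifted by ``treatment_effect_tau`` for digitally connected
  (access = 1) respondents, plus Gaussian noise; each instrument (SRH,
  ADL, iADL, MMSE) is a monotone discretization of its own noisy copy of
  the latent, so a positive tau improves every oriented score on average;
* the three use items (WeChat, Moments, mobile payment) are observed only
  for smart-device owners, mirroring the survey's "unknown" pattern.

The generator is deterministic: identical configurations produce
byte-identical tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError

__all__ = ["SyntheticConfig", "generate_cohort", "write_cohort", "calibrate_tau"]


#: Wave-specific marginal parameters (survey-calibrated, loose +-5 pts).
WAVE_PARAMS = {
    2018: dict(
        p_male=0.4859,
        age_mean=65.11, age_sd=10.02,
        p_married=0.7331,
        p_education=(0.2508, 0.4427, 0.3065),      # none / elementary / junior+
        p_rural=0.8437,
        p_insurance=(0.1025, 0.1147, 0.7828),      # employee / resident / other
        p_chronic=0.4643,
        p_disability=0.1421,
        p_support=0.6217,
        p_region=(0.2733, 0.3168, 0.3456, 0.0643),  # east/central/west/northeast
        log_income_mean=0.71, log_income_sd=0.35,
        outpatient_lambda=0.39,
        p_broadband=0.3922,
        p_smart_any=0.1050, p_smart_two=0.1893,     # P(>=2 | any)
        p_digital_any=0.0198,
        p_wechat=0.9328, p_moments=0.6849, p_pay=0.5181,  # given smart owner
        mmse_center=23.0,
    ),
    2020: dict(
        p_male=0.4848,
        age_mean=63.97, age_sd=9.20,
        p_married=0.8101,
        p_education=(0.2377, 0.4293, 0.3330),
        p_rural=0.7768,
        p_insurance=(0.1360, 0.8387, 0.0253),
        p_chronic=0.4031,
        p_disability=0.1469,
        p_support=0.4346,
        p_region=(0.3096, 0.3026, 0.3292, 0.0586),
        log_income_mean=0.72, log_income_sd=0.33,
        outpatient_lambda=0.49,
        p_broadband=0.5729,
        p_smart_any=0.3550, p_smart_two=0.0930,
        p_digital_any=0.0330,
        p_wechat=0.8940, p_moments=0.5073, p_pay=0.5735,
        mmse_center=20.0,
    ),
}

_MIN_AGE = 50.0
_MAX_AGE = 110.0

# Fixed structural coefficients of the latent-health index. The confounder
# index u loads on education (+), age (-), rural hukou (-) and log income
# (+); its raw scale is normalized by _U_SCALE so confounding_strength is
# roughly in SD units of the index.
_U_EDU, _U_AGE, _U_RURAL, _U_INC = 0.6, -0.4, -0.6, 0.3
_U_SCALE = 0.70
_H_SEX, _H_CHRONIC, _H_DISAB = 0.10, -0.40, -0.50
_H_NOISE = 0.80          # shared latent noise SD
_DIM_NOISE = 0.80        # per-instrument noise SD


@dataclass(frozen=True)
class SyntheticConfig:
    """Configuration of one synthetic cohort draw.

    Parameters
    ----------
    n : int
        Number of respondents (>= 1).
    seed : int
        RNG seed; identical configs are byte-identical.
    treatment_effect_tau : float
        Additive shift of latent health for digitally connected
        respondents (positive = health-increasing), in latent SD-ish
        units.
    confounding_strength : float
        Nonnegative weight of the shared education/age/hukou/income index
        on both connectivity propensity and latent health. 0 = randomized
        connectivity.
    missing_rate : float
        Per-cell probability of item-level missingness on SRH, the twelve
        ADL/iADL items and the MMSE total, in [0, 1].
    wave : int
        2018 or 2020; selects the marginal prevalences.
    tau_heterogeneity : mapping, optional
        Extra treatment effect by binary covariate, e.g.
        ``{"hukou": 0.5}`` adds 0.5 to tau for rural respondents
        (enables effect-modification test beds).
    """

    n: int
    seed: int = 0
    treatment_effect_tau: float = 0.0
    confounding_strength: float = 0.5
    missing_rate: float = 0.0
    wave: int = 2018
    tau_heterogeneity: dict = field(default_factory=dict)

    def __post_init__(self):
        if not isinstance(self.n, (int, np.integer)) or self.n < 1:
            raise ConfigurationError(f"n: must be a positive integer, got {self.n!r}")
        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigurationError(f"seed: must be an integer, got {self.seed!r}")
        if not np.isfinite(self.treatment_effect_tau):
            raise ConfigurationError("treatment_effect_tau: must be finite")
        if self.confounding_strength < 0:
            raise ConfigurationError(
                f"confounding_strength: must be >= 0, got {self.confounding_strength}"
            )
        if not (0.0 <= self.missing_rate <= 1.0):
            raise ConfigurationError(
                f"missing_rate: must be in [0, 1], got {self.missing_rate}"
            )
        if self.wave not in WAVE_PARAMS:
            raise ConfigurationError(
                f"wave: must be one of {sorted(WAVE_PARAMS)}, got {self.wave!r}"
            )
        for k in self.tau_heterogeneity:
            if k not in ("sex", "hukou", "chronic", "disability",
                         "marital", "intergenerational_support"):
                raise ConfigurationError(
                    f"tau_heterogeneity: unsupported covariate {k!r}"
                )


def _logit(p: float) -> float:
    return float(np.log(p / (1 - p)))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_cohort(config: SyntheticConfig) -> pd.DataFrame:
    """Draw one cohort table under the configured ground truth.

    Returns one row per respondent with demographic, digital and raw
    health-item columns (see :data:`COLUMN_DICTIONARY`). Ground-truth
    arrays (confounder index, latent health, individual tau) are attached
    in ``DataFrame.attrs["truth"]`` for test use; they are not part of
    the observable table and are not written by :func:`write_cohort`.
    """
    w = WAVE_PARAMS[config.wave]
    n = int(config.n)
    rng = np.random.default_rng(config.seed)
    conf = float(config.confounding_strength)

    sex = (rng.random(n) < w["p_male"]).astype(int)
    a, b = (_MIN_AGE - w["age_mean"]) / w["age_sd"], (_MAX_AGE - w["age_mean"]) / w["age_sd"]
    age = stats.truncnorm.rvs(a, b, loc=w["age_mean"], scale=w["age_sd"],
                              size=n, random_state=rng)
    age = np.round(age, 1)
    marital = (rng.random(n) < w["p_married"]).astype(int)
    education = rng.choice(3, size=n, p=w["p_education"])
    hukou = (rng.random(n) < w["p_rural"]).astype(int)
    insurance = rng.choice([1, 2, 3], size=n, p=w["p_insurance"])
    chronic = (rng.random(n) < w["p_chronic"]).astype(int)
    disability = (rng.random(n) < w["p_disability"]).astype(int)
    support = (rng.random(n) < w["p_support"]).astype(int)
    region = rng.choice(4, size=n, p=w["p_region"])
    zl, zu = (0.0 - w["log_income_mean"]) / w["log_income_sd"], np.inf
    log_inc = stats.truncnorm.rvs(zl, zu, loc=w["log_income_mean"],
                                  scale=w["log_income_sd"], size=n,
                                  random_state=rng)
    income = np.round(np.power(10.0, log_inc) - 1.0, 4)
    outpatient = np.minimum(rng.poisson(w["outpatient_lambda"], size=n), 30)

    # shared confounder index (education +, age -, rural -, income +)
    age_z = (age - w["age_mean"]) / w["age_sd"]
    inc_z = (log_inc - w["log_income_mean"]) / w["log_income_sd"]
    u = (_U_EDU * (education - 1.0) + _U_AGE * age_z
         + _U_RURAL * (hukou - 0.5) + _U_INC * inc_z)
    u = (u - u.mean()) / _U_SCALE

    broadband = (rng.random(n) < _sigmoid(_logit(w["p_broadband"]) + conf * u)).astype(int)
    smart_any = rng.random(n) < _sigmoid(_logit(w["p_smart_any"]) + conf * u)
    n_smart = smart_any.astype(int) + (
        smart_any & (rng.random(n) < w["p_smart_two"])
    ).astype(int)
    digital_any = rng.random(n) < _sigmoid(_logit(w["p_digital_any"]) + conf * u)
    n_digital = digital_any.astype(int) + (
        digital_any & (rng.random(n) < 0.1)
    ).astype(int)

    # use items observed only for smart-device owners
    wechat = np.where(smart_any, (rng.random(n) < _sigmoid(
        _logit(w["p_wechat"]) + 0.5 * conf * u)).astype(float), np.nan)
    moments = np.where(smart_any, (rng.random(n) < _sigmoid(
        _logit(w["p_moments"]) + 0.5 * conf * u)).astype(float), np.nan)
    mobile_pay = np.where(smart_any, (rng.random(n) < _sigmoid(
        _logit(w["p_pay"]) + 0.5 * conf * u)).astype(float), np.nan)

    D = ((broadband >= 1) | (n_smart >= 1) | (n_digital >= 1)).astype(int)
    tau_i = np.full(n, float(config.treatment_effect_tau))
    cov_map = {"sex": sex, "hukou": hukou, "chronic": chronic,
               "disability": disability, "marital": marital,
               "intergenerational_support": support}
    for k, extra in config.tau_heterogeneity.items():
        tau_i = tau_i + float(extra) * cov_map[k]

    latent = (conf * u + _H_SEX * sex + _H_CHRONIC * chronic
              + _H_DISAB * disability + tau_i * D
              + rng.normal(0.0, _H_NOISE, size=n))

    # each instrument discretizes its own noisy copy, monotone in latent
    srh_latent = latent + rng.normal(0.0, _DIM_NOISE, size=n)
    srh = (np.digitize(srh_latent, [-1.5, -0.5, 0.5, 1.5]) + 1).astype(float)

    adl_latent = latent + rng.normal(0.0, _DIM_NOISE, size=n)
    adl_items = np.clip(np.round(
        1.35 - 0.55 * adl_latent[:, None] + 0.55 * rng.normal(size=(n, 6))
    ), 1, 4)
    iadl_latent = latent + rng.normal(0.0, _DIM_NOISE, size=n)
    iadl_items = np.clip(np.round(
        1.55 - 0.60 * iadl_latent[:, None] + 0.60 * rng.normal(size=(n, 6))
    ), 1, 4)
    mmse_latent = latent + rng.normal(0.0, _DIM_NOISE, size=n)
    mmse = np.clip(np.round(w["mmse_center"] + 3.2 * mmse_latent), 0, 30)

    df = pd.DataFrame({
        "sex": sex, "age": age, "marital": marital, "education": education,
        "hukou": hukou, "insurance": insurance, "chronic": chronic,
        "disability": disability, "intergenerational_support": support,
        "region": region, "income": income, "outpatient_visits": outpatient,
        "broadband": broadband, "n_smart_devices": n_smart,
        "n_digital_devices": n_digital, "wechat": wechat,
        "moments": moments, "mobile_pay": mobile_pay, "srh": srh,
    })
    for j in range(6):
        df[f"adl_{j + 1}"] = adl_items[:, j]
    for j in range(6):
        df[f"iadl_{j + 1}"] = iadl_items[:, j]
    df["mmse_total"] = mmse

    if config.missing_rate > 0:
        item_cols = (["srh"] + [f"adl_{j}" for j in range(1, 7)]
                     + [f"iadl_{j}" for j in range(1, 7)] + ["mmse_total"])
        mask = rng.random((n, len(item_cols))) < config.missing_rate
        for k, col in enumerate(item_cols):
            vals = df[col].to_numpy(dtype=float)
            vals[mask[:, k]] = np.nan
            df[col] = vals

    df.attrs["truth"] = {
        "confounder_index": u,
        "latent_health": latent,
        "tau_individual": tau_i,
        "access": D,
    }
    df.attrs["config"] = config
    return df


#: Machine-readable column dictionary written as a JSON sidecar.
COLUMN_DICTIONARY = {
    "sex": "0 = female, 1 = male",
    "age": "age in years (>= 50)",
    "marital": "0 = unmarried (incl. separated/divorced/widowed), 1 = married",
    "education": "0 = no formal education, 1 = elementary, 2 = junior high and above",
    "hukou": "household registration: 0 = urban, 1 = rural",
    "insurance": "1 = urban employee, 2 = urban-rural resident, 3 = other",
    "chronic": "any chronic disease, 0/1",
    "disability": "any disability, 0/1",
    "intergenerational_support": "strong contact with children, 0/1",
    "region": "0 = eastern, 1 = central, 2 = western, 3 = northeast",
    "income": "annual household income (nonnegative, arbitrary units)",
    "outpatient_visits": "outpatient visits per month, integer 0-30",
    "broadband": "household broadband, 0/1",
    "n_smart_devices": "smart devices owned, integer >= 0",
    "n_digital_devices": "other digital devices owned, integer >= 0",
    "wechat": "uses WeChat messaging, 0/1; missing if no smart device",
    "moments": "posts on WeChat Moments, 0/1; missing if no smart device",
    "mobile_pay": "uses mobile payment, 0/1; missing if no smart device",
    "srh": "self-rated health, 1 (very poor) to 5 (very good)",
    "adl_1..adl_6": "ADL items, 1 (no difficulty) to 4 (cannot do)",
    "iadl_1..iadl_6": "iADL items, 1 (no difficulty) to 4 (cannot do)",
    "mmse_total": "MMSE cognition total, 0-30",
}


def write_cohort(df: pd.DataFrame, path) -> Path:
    """Write a cohort CSV plus a ``<name>.dict.json`` column dictionary."""
    path = Path(path)
    df.to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".dict.json")
    with open(sidecar, "w") as fh:
        json.dump(COLUMN_DICTIONARY, fh, indent=2)
    return path


def calibrate_tau(
    target_std_beta: float,
    base_config: SyntheticConfig,
    dimension: str = "cognition",
    n_cal: int = 60_000,
    probe_tau: float = 0.2,
    n_iter: int = 2,
) -> float:
    """Find tau giving a target standardized exposure-deprivation beta.

    The standardized coefficient of the access exposure on the Kakwani
    deprivation outcome is smooth and monotone in tau (a positive tau
    improves treated health, so deprivation betas are negative), but
    mildly sublinear, so a secant search is used: betas are evaluated on
    one large common-random-numbers cohort of ``n_cal`` respondents at
    tau = 0 and ``probe_tau``, then the secant is refined ``n_iter``
    times through the two most recent points.
    """
    from dataclasses import replace

    from .deprivation import rd_table
    from .divide import derive_table
    from .inference import build_design, fit_outcome_model
    from .scales import score_table

    def beta_at(tau: float) -> float:
        cfg = replace(base_config, n=n_cal, treatment_effect_tau=tau)
        table = derive_table(score_table(generate_cohort(cfg)))
        table, _ = rd_table(table, [dimension])
        res = fit_outcome_model(build_design(table, f"rd_{dimension}", "access"))
        return res.beta("access")

    t0, b0 = 0.0, beta_at(0.0)
    t1, b1 = probe_tau, beta_at(probe_tau)
    for _ in range(n_iter):
        if b1 == b0:
            raise ConfigurationError(
                "treatment_effect_tau: calibration failed (flat response)"
            )
        t2 = t1 + (target_std_beta - b1) * (t1 - t0) / (b1 - b0)
        t0, b0 = t1, b1
        t1, b1 = t2, beta_at(t2)
    return t1
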