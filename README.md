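# healthgap

Does the digital divide — unequal access to and use of the internet — go
hand in hand with health inequality among older adults? `healthgap` is a
tested, reusable pipeline for that question on person-level ageing-survey
tables (one row per respondent, CHARLS-style column dictionary). It is
aimed at epidemiologists and health economists who want the full chain —
scale scoring, an individual-level inequality index, adjusted regression,
and a matched sensitivity analysis — reproducible from a single seed,
plus a synthetic-cohort generator with known ground truth so every stage
can be validated without restricted survey microdata.

## The model

Health is measured on four instruments, each oriented so larger = healthier:
self-rated health (1–5), activities of daily living (six items, sum 6–24,
reflected as 30 − x), instrumental ADL (likewise), and an MMSE cognition
total (0–30). Per dimension, individual health inequality is the **Kakwani
relative-deprivation index**: for person *i* in a sample y₁…yₙ with mean
μ_Y,

```
RD_i = γ_i (μ_i⁺ − y_i) / μ_Y = (1 / n μ_Y) Σ_j max(y_j − y_i, 0)
```

where γ_i is the share of the sample strictly healthier than *i* and μ_i⁺
their mean health. RD_i ≥ 0, is zero at the sample maximum, is scale-free,
and its sample mean equals the Gini coefficient of y — an identity the test
suite exploits as an oracle.

Deprivation is then regressed on the digital exposure — binary **access**
(any of broadband, smart device, other digital device) or the 0–3 **use**
score (WeChat messaging + Moments posting + mobile payment, observed only
for smart-device owners) — with the standard controls (sex, age, hukou,
education, marital status, insurance, chronic disease, disability,
outpatient visits, intergenerational support, winsorized log income,
region dummies). Coefficients are fully standardized; SEs are classical.
A propensity-score analysis (logit scores, greedy 1:1 nearest-neighbor
matching without replacement, paired-t ATT, SMD balance diagnostics)
serves as the sensitivity check, and subgroup/moderation fits probe
effect heterogeneity.

## Worked example

```python
import healthgap as hg

cfg = hg.SyntheticConfig(n=7644, seed=1, wave=2018,
                         confounding_strength=0.5, treatment_effect_tau=0.3)
table = hg.derive_table(hg.score_table(hg.generate_cohort(cfg)))
table, summary = hg.rd_table(table)
print(f"broadband prevalence: {100*table.broadband.mean():.2f}%")
print(f"internet access:      {100*table.access.mean():.2f}%")
for dim in hg.DIMENSIONS:
    res = hg.fit_outcome_model(hg.build_design(table, f"rd_{dim}", "access"))
    print(f"{dim:>9}: Gini={summary[dim]['gini']:.4f}  "
          f"beta_access={res.beta('access'):+.4f} "
          f"(SE {res.se('access'):.4f}, p={res.p('access'):.2e})  "
          f"R2={res.r_squared:.3f}")
```

prints

```
broadband prevalence: 39.43%
internet access:      46.95%
      srh: Gini=0.2268  beta_access=-0.1000 (SE 0.0107, p=1.11e-20)  R2=0.191
      adl: Gini=0.0860  beta_access=-0.0765 (SE 0.0110, p=3.31e-12)  R2=0.149
     iadl: Gini=0.1076  beta_access=-0.0875 (SE 0.0110, p=1.67e-15)  R2=0.150
cognition: Gini=0.0993  beta_access=-0.0957 (SE 0.0108, p=7.02e-19)  R2=0.182
```

The 2018-wave generator reproduces its calibrated broadband prevalence
(~39%); the Gini values are the mean per-person deprivation per dimension;
and because the cohort was generated with a health-*increasing* effect of
connectivity (tau = 0.3), the standardized access coefficients on
deprivation are negative: connected respondents sit higher in the health
distribution and feel less relative deprivation. The same objects drive
the matched analysis:

```python
m, bal = hg.run_psm(table, "rd_cognition", "use_binary",
                    hg.inference.DEFAULT_COVARIATES)
```

which returns the ATT with SE/p over matched pairs and a pre/post-match
SMD balance table.

A `healthgap` console command exposes the stages (`synth`, `score`,
`derive-divide`, `deprivation`, `fit`, `psm`) and a one-shot `run` driven
by a YAML config that writes per-stage CSV/JSON artifacts plus a manifest;
reruns with the same config and seed are byte-identical.

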