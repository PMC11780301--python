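"""End-to-end pipeline: cohort -> scores -> divide -> deprivation ->
univariate screen -> adjusted models (+ subgroups) -> matching.

Every stage writes a plain-text artifact (CSV/JSON) into the output
directory and records itself in ``manifest.json`` (stage name, rows in /
out, elapsed seconds). Reruns with the same configuration and seed are
byte-identical for all deterministic artifacts. Randomness (the synthetic
cohort, the Shapiro subsample) is derived from the single top-level seed
by spawning one child ``SeedSequence`` per consuming stage, in stage
order.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import deprivation, divide, inference, psm, scales
from .errors import ConfigurationError
from .synthetic import SyntheticConfig, generate_cohort, write_cohort

__all__ = ["PipelineConfig", "run_pipeline", "exclusion_report"]

log = logging.getLogger("healthgap")

#: Key-variable columns whose missingness triggers exclusion.
KEY_VARIABLES = (
    "srh", "mmse_total",
    *(f"adl_{i}" for i in range(1, 7)),
    *(f"iadl_{i}" for i in range(1, 7)),
)


@dataclass
class PipelineConfig:
    """Validated configuration of one full run.

    Either ``input_csv`` (an existing cohort table) or ``synthetic``
    (keyword arguments for :class:`SyntheticConfig`, minus the seed,
    which flows from the top-level ``seed``) must be given.
    """

    out_dir: str
    seed: int = 0
    input_csv: str | None = None
    synthetic: dict | None = None
    dimensions: tuple = tuple(scales.DIMENSIONS)
    exposures: tuple = ("access", "use_score")
    covariates: tuple = tuple(inference.DEFAULT_COVARIATES)
    subgroup_splits: tuple = ("sex", "age60", "hukou", "education", "region")
    winsor_limits: tuple = (0.01, 0.01)
    min_age: float = 50.0
    psm_caliper: float | None = None
    psm_exposures: tuple = ("access", "use_binary")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dc_fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(
                f"unknown configuration keys: {sorted(unknown)}"
            )
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, dict):
            raise ConfigurationError("configuration file must be a mapping")
        return cls.from_dict(d)

    def __post_init__(self):
        if self.input_csv is None and self.synthetic is None:
            raise ConfigurationError(
                "input_csv / synthetic: exactly one input source required"
            )
        for dim in self.dimensions:
            if dim not in scales.DIMENSIONS:
                raise ConfigurationError(f"dimensions: unknown {dim!r}")


def exclusion_report(table: pd.DataFrame, min_age: float = 50.0) -> dict:
    """Sequential exclusion counts: under-age first, then missing key
    variables.

    Percentages are reported against the initial N (the survey-flow
    convention) and, for reference, against each step's own denominator.
    """
    n0 = len(table)
    under = table["age"] < min_age if n0 else pd.Series(dtype=bool)
    n_under = int(under.sum())
    stage1 = table[~under] if n0 else table
    key_cols = [c for c in KEY_VARIABLES if c in table.columns]
    missing = stage1[key_cols].isna().any(axis=1) if len(stage1) else pd.Series(dtype=bool)
    n_missing = int(missing.sum())
    retained = len(stage1) - n_missing

    def pct(x, denom):
        return round(100.0 * x / denom, 2) if denom else 0.0

    return {
        "initial_n": n0,
        "excluded_under_age": {
            "n": n_under,
            "pct_of_initial": pct(n_under, n0),
            "pct_of_stage": pct(n_under, n0),
        },
        "excluded_missing_key": {
            "n": n_missing,
            "pct_of_initial": pct(n_missing, n0),
            "pct_of_stage": pct(n_missing, len(stage1)),
        },
        "retained": {"n": retained, "pct_of_initial": pct(retained, n0)},
    }


#: Variables screened univariately, with their test family.
_SCREEN_VARS = {
    "sex": "categorical", "marital": "categorical", "education": "categorical",
    "hukou": "categorical", "insurance": "categorical", "chronic": "categorical",
    "disability": "categorical", "intergenerational_support": "categorical",
    "region": "categorical", "age": "continuous", "income": "continuous",
    "outpatient_visits": "continuous",
}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and return the manifest dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).spawn(2)
    manifest: dict = {"seed": config.seed, "stages": []}

    def stage(name, fn, n_in):
        t0 = time.monotonic()
        try:
            result, n_out = fn()
        except Exception:
            manifest["stages"].append(
                {"stage": name, "status": "failed", "rows_in": n_in}
            )
            _write_manifest(out, manifest)
            raise
        manifest["stages"].append({
            "stage": name, "status": "ok", "rows_in": n_in,
            "rows_out": n_out, "seconds": round(time.monotonic() - t0, 3),
        })
        log.info("stage %-12s rows %s -> %s", name, n_in, n_out)
        return result

    # 1. ingest / generate
    def _ingest():
        if config.input_csv is not None:
            df = pd.read_csv(config.input_csv)
        else:
            syn = SyntheticConfig(
                seed=int(seeds[0].generate_state(1)[0] % (2**31)),
                **config.synthetic,
            )
            df = generate_cohort(syn)
        write_cohort(df, out / "cohort.csv")
        return df, len(df)

    cohort = stage("ingest", _ingest, 0)

    excl = exclusion_report(cohort, config.min_age)
    manifest["exclusions"] = excl
    cohort = cohort[cohort["age"] >= config.min_age].reset_index(drop=True)

    # 2. score health instruments
    def _score():
        df = scales.score_table(cohort)
        df.to_csv(out / "scored.csv", index=False)
        return df, len(df)

    scored = stage("score", _score, len(cohort))

    # 3. digital-divide indicators
    def _divide():
        df = divide.derive_table(scored)
        df.to_csv(out / "divided.csv", index=False)
        return df, len(df)

    divided = stage("divide", _divide, len(scored))

    # 4. deprivation index
    def _depriv():
        df, summary = deprivation.rd_table(divided, config.dimensions)
        df.to_csv(out / "deprivation.csv", index=False)
        with open(out / "deprivation_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        return df, len(df)

    table = stage("deprivation", _depriv, len(divided))

    # 5. univariate screen against access
    def _screen():
        rng = np.random.default_rng(seeds[1].generate_state(1)[0] % (2**31))
        rep = inference.univariate_screen(table, "access", _SCREEN_VARS, rng=rng)
        rep.to_csv(out / "univariate.csv", index=False)
        return rep, len(rep)

    stage("univariate", _screen, len(table))

    # 6. adjusted models (+ subgroups)
    def _models():
        rows = []
        for dim in config.dimensions:
            for exposure in config.exposures:
                dm = inference.build_design(
                    table, f"rd_{dim}", exposure, config.covariates,
                    config.winsor_limits,
                )
                res = inference.fit_outcome_model(dm)
                rows.extend(_tidy(res))
                for split in config.subgroup_splits:
                    subs = inference.subgroup_fit(
                        table, split, f"rd_{dim}", exposure,
                        config.covariates,
                    )
                    for r in subs.values():
                        rows.extend(_tidy(r))
        df = pd.DataFrame(rows)
        df.to_csv(out / "models.csv", index=False)
        return df, len(df)

    stage("models", _models, len(table))

    # 7. propensity-matched sensitivity analysis
    def _psm():
        att: dict = {}
        balance_frames = []
        for exposure in config.psm_exposures:
            att[exposure] = {}
            for dim in config.dimensions:
                m, bal = psm.run_psm(
                    table, f"rd_{dim}", exposure, config.covariates,
                    caliper=config.psm_caliper,
                )
                att[exposure][dim] = {
                    "treated_mean": m.treated_mean,
                    "control_mean": m.control_mean,
                    "att": m.att, "se": m.att_se, "p": m.att_p,
                    "n_pairs": m.n_pairs,
                    "dropped_treated": m.dropped_treated,
                }
                b = bal.table.reset_index()
                b.insert(0, "dimension", dim)
                b.insert(0, "exposure", exposure)
                balance_frames.append(b)
        with open(out / "psm_att.json", "w") as fh:
            json.dump(att, fh, indent=2, sort_keys=True)
        pd.concat(balance_frames).to_csv(out / "psm_balance.csv", index=False)
        return att, len(balance_frames)

    stage("psm", _psm, len(table))

    _write_manifest(out, manifest)
    return manifest


def _tidy(res: inference.ModelResult) -> list[dict]:
    rows = []
    for term, row in res.terms.iterrows():
        rows.append({
            "outcome": res.outcome, "exposure": res.exposure,
            "subgroup": res.subgroup or "all", "term": term,
            "beta": row["beta"], "se": row["se"], "p": row["p"],
            "r_squared": res.r_squared, "n": res.n,
        })
    return rows


def _write_manifest(out: Path, manifest: dict) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
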