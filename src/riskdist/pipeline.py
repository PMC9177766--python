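"""End-to-end orchestration: simulate -> preprocess -> fit -> predict ->
validate, driven by a YAML run configuration with a single master seed.

``run_fit`` produces a self-contained model bundle (Winsor thresholds,
pooled lab imputers, the pooled risk GAM, variable specs and a config
hash) that predicts prospectively without the training data.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import gam
from .evaluate import (BaselineConfig, ScoreReport, make_split_plan,
                       run_validation)
from .exceptions import ConfigError, RiskdistError
from .impute import (ImputationConfig, LabImputerModel, impute_cohort,
                     LAB_VARIABLES)
from .predict import RiskDistribution, density_curve, predict_distribution, summarize
from .preprocess import (WinsorThresholds, add_missingness_indicators,
                         apply_winsor, fit_winsor_thresholds,
                         redact_implausible)
from .schema import Cohort, apply_exclusions, default_variable_specs, read_cohort
from .synthetic import GeneratorConfig, case_study_fixture, generate_cohort, inject_missingness

logger = logging.getLogger("riskdist")

__all__ = ["RunConfig", "ModelBundle", "run_simulate", "run_fit",
           "run_validate", "run_case_study", "load_or_simulate_cohort"]

_KNOWN_KEYS = {
    "cohort_csv": None,
    "output_dir": None,
    "seed": None,
    "log_level": None,
    "generator": {"n_cases", "n_hospitals", "prevalence_target",
                  "missingness_rates", "missingness_mechanism",
                  "hospital_sd", "seed"},
    "imputation": {"m_mice", "k_lab", "n_chained_cycles",
                   "include_outcome_in_mice", "include_outcome_in_lab",
                   "lab_residual_noise", "lab_coefficient_uncertainty",
                   "lactate_log_scale", "n_coef_draws", "seed"},
    "gam": {"variables", "interactions", "penalty_multiplier"},
    "validation": {"n_splits", "train_frac"},
    "sensitivity": {"exclude_outcome_from_lab_imputers", "drop_albumin"},
}


@dataclass
class RunConfig:
    """Master run configuration; every default matches the published study
    configuration (m from the percent-incomplete rule, k_lab=3, five
    coefficient draws, 120 splits at an 80% train fraction)."""

    cohort_csv: str | None = None
    output_dir: str = "riskdist_output"
    seed: int = 0
    log_level: str = "INFO"
    generator: dict = field(default_factory=dict)
    imputation: dict = field(default_factory=dict)
    gam: dict = field(default_factory=dict)
    validation: dict = field(default_factory=dict)
    sensitivity: dict = field(default_factory=dict)

    def __post_init__(self):
        sens = {"exclude_outcome_from_lab_imputers": True,
                "drop_albumin": False}
        sens.update(self.sensitivity or {})
        self.sensitivity = sens

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        for key, value in data.items():
            if key not in _KNOWN_KEYS:
                raise ConfigError(f"unknown configuration key {key!r}")
            sub = _KNOWN_KEYS[key]
            if sub is not None and isinstance(value, Mapping):
                for k in value:
                    if k not in sub:
                        raise ConfigError(f"unknown configuration key "
                                          f"{key}.{k}")
        cfg = cls(**data)
        for k, v in cfg.sensitivity.items():
            if not isinstance(v, bool):
                raise ConfigError(f"sensitivity.{k} must be boolean")
        return cfg

    def imputation_config(self) -> ImputationConfig:
        kw = dict(self.imputation)
        kw.setdefault("seed", self.seed + 1)
        kw["include_outcome_in_lab"] = not self.sensitivity[
            "exclude_outcome_from_lab_imputers"]
        return ImputationConfig(**kw)

    def generator_config(self) -> GeneratorConfig:
        kw = dict(self.generator)
        kw.setdefault("seed", self.seed)
        return GeneratorConfig(**kw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ModelBundle:
    """Everything needed for prospective prediction, with no training data:
    clamp thresholds, pooled lab imputers, the pooled risk model, and
    provenance (seeds, imputation counts, config hash)."""

    thresholds: WinsorThresholds
    lab_imputers: dict[str, LabImputerModel]
    model: gam.PooledGam
    imputation: ImputationConfig
    config_hash: str
    counts: dict

    def save(self, path: str | Path) -> None:
        payload = {
            "thresholds": json.loads(self.thresholds.to_json()),
            "lab_imputers": {k: v.to_dict() for k, v in self.lab_imputers.items()},
            "model": gam.pooled_to_dict(self.model),
            "imputation": asdict(self.imputation),
            "config_hash": self.config_hash,
            "counts": self.counts,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "ModelBundle":
        d = json.loads(Path(path).read_text())
        return cls(
            thresholds=WinsorThresholds(lower=d["thresholds"]["lower"],
                                        upper=d["thresholds"]["upper"]),
            lab_imputers={k: LabImputerModel.from_dict(v)
                          for k, v in d["lab_imputers"].items()},
            model=gam.pooled_from_dict(d["model"]),
            imputation=ImputationConfig(**d["imputation"]),
            config_hash=d["config_hash"],
            counts=d["counts"],
        )

    def predict_case(self, case: pd.Series,
                     seed: int | None = None) -> RiskDistribution:
        case = case.copy()
        for name in self.thresholds.upper:
            if name in case.index and not pd.isna(case[name]):
                case[name] = float(self.thresholds.clamp(
                    name, np.asarray([case[name]], float))[0])
        return predict_distribution(case, self.model, self.lab_imputers,
                                    self.imputation, seed=seed)


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except RiskdistError as exc:
        raise type(exc)(f"[stage {name}] {exc}") from exc


def load_or_simulate_cohort(config: RunConfig) -> Cohort:
    if config.cohort_csv:
        return _stage("read", read_cohort, config.cohort_csv,
                      default_variable_specs())
    gen_cfg = config.generator_config()
    cohort, _, _ = _stage("simulate", generate_cohort, gen_cfg)
    return _stage("inject-missingness", inject_missingness, cohort, gen_cfg)


def run_simulate(config: RunConfig, out_csv: str | Path,
                 true_risk_csv: str | Path | None = None) -> Cohort:
    """Generate a synthetic cohort and write it (plus a true-risk side-car)."""
    from .schema import write_cohort
    gen_cfg = config.generator_config()
    cohort, true_risks, _ = generate_cohort(gen_cfg)
    observed = inject_missingness(cohort, gen_cfg)
    write_cohort(observed, out_csv)
    if true_risk_csv is not None:
        pd.DataFrame({"case_id": cohort.df["case_id"],
                      "true_risk": true_risks}).to_csv(true_risk_csv, index=False)
    return observed


def _risk_spec(config: RunConfig, specs, columns) -> gam.GamSpec:
    variables = config.gam.get("variables")
    if variables is None:
        variables = [v for v in specs if v != "died" and v in columns]
    variables = list(variables)
    if config.sensitivity["drop_albumin"]:
        variables = [v for v in variables
                     if v not in ("albumin", "albumin_missing")]
    interactions = config.gam.get("interactions", gam.DEFAULT_INTERACTIONS)
    interactions = [tuple(x) for x in interactions]
    spec = gam.default_risk_terms(specs, variables, interactions)
    mult = config.gam.get("penalty_multiplier")
    if isinstance(mult, (int, float)):
        spec = spec.scale_penalties(float(mult))
    return spec


def run_fit(config: RunConfig, cohort: Cohort | None = None) -> ModelBundle:
    """Fit the production model on all study data and return the bundle.

    Stages: eligibility exclusions, implausible-value redaction,
    Winsorization, missingness indicators, two-stage multiple imputation,
    one GAM fit per completed dataset, Rubin's-rules pooling.
    """
    if cohort is None:
        cohort = load_or_simulate_cohort(config)
    cohort, excl = _stage("exclusions", apply_exclusions, cohort)
    logger.info("exclusions: %s", excl.reasons)
    cohort, redactions = _stage("redact", redact_implausible, cohort)
    thresholds = _stage("winsorize", fit_winsor_thresholds, cohort)
    cohort = apply_winsor(add_missingness_indicators(cohort), thresholds)
    imp_cfg = config.imputation_config()
    completed, lab_imputers = _stage("impute", impute_cohort, cohort,
                                     imp_cfg, thresholds)
    if config.sensitivity["drop_albumin"]:
        lab_imputers = {k: v for k, v in lab_imputers.items() if k != "albumin"}
    spec = _risk_spec(config, cohort.specs, cohort.df.columns)
    if config.gam.get("penalty_multiplier") == "gcv":
        _, spec = _stage("gcv", gam.choose_penalty_multiplier,
                         completed[0].df, spec, variable_specs=cohort.specs)
    info = gam.fit_design_info(completed[0].df, spec, cohort.specs)
    fits = [_stage("fit-gam", gam.fit_binomial_gam, c.df, spec, info=info)
            for c in completed]
    pooled = _stage("pool", gam.pool_fits, fits)
    m_mice = max(c.mice_index for c in completed) + 1
    # Resolved first-stage count is carried into the bundle so prospective
    # prediction reproduces the full m x k x s draw grid.
    imp_resolved = replace(imp_cfg, m_mice=m_mice)
    counts = {"m_mice": m_mice, "k_lab": imp_cfg.k_lab,
              "n_completed_datasets": len(completed),
              "n_coef_draws": imp_cfg.n_coef_draws,
              "samples_per_case": m_mice * imp_cfg.k_lab * imp_cfg.n_coef_draws,
              "redactions": redactions}
    logger.info("fit complete: %s", counts)
    return ModelBundle(thresholds, lab_imputers, pooled, imp_resolved,
                       config.config_hash(), counts)


def run_validate(config: RunConfig, cohort: Cohort | None = None,
                 gam_spec: gam.GamSpec | None = None) -> ScoreReport:
    """Grouped repeated cross-validation under the run configuration."""
    if cohort is None:
        cohort = load_or_simulate_cohort(config)
    cohort, _ = _stage("exclusions", apply_exclusions, cohort)
    cohort, _ = _stage("redact", redact_implausible, cohort)
    plan = make_split_plan(cohort.df["hospital_id"],
                           n_splits=config.validation.get("n_splits", 120),
                           train_frac=config.validation.get("train_frac", 0.8),
                           seed=config.seed + 7)
    if gam_spec is None:
        gam_spec = _risk_spec(config, cohort.specs, cohort.df.columns)
    report = _stage("validate", run_validation, cohort,
                    config.imputation_config(), BaselineConfig(), plan,
                    gam_spec=gam_spec)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report.per_split.to_csv(out_dir / "scores_per_split.csv", index=False)
    (out_dir / "score_report.json").write_text(json.dumps(report.to_json(),
                                                          default=float))
    if report.rdr_strata is not None:
        report.rdr_strata.to_csv(out_dir / "rdr_strata.csv", index=False)
    return report


def run_case_study(bundle: ModelBundle, seed: int = 0,
                   imputation: ImputationConfig | None = None) -> dict:
    """Predict the worked vignette before and after the labs are measured.

    Returns both distributions with summaries and density curves; the
    post-measurement case uses the measured labs directly (no lab draws).
    ``imputation`` overrides the bundle's draw budget (e.g. for a denser
    sample grid).
    """
    pre, post = case_study_fixture()
    work = bundle
    if imputation is not None:
        work = replace(bundle, imputation=imputation)
    d_pre = work.predict_case(pre, seed=seed)
    d_post = work.predict_case(post, seed=seed + 1)
    g_pre, f_pre = density_curve(d_pre)
    g_post, f_post = density_curve(d_post)
    return {
        "pre": {**summarize(d_pre), "density": (g_pre, f_pre),
                "distribution": d_pre},
        "post": {**summarize(d_post), "density": (g_post, f_post),
                 "distribution": d_post},
    }
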