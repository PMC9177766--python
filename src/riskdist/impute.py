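"""Two-stage multiple imputation.

Stage 1 — routinely-measured covariates. These are assumed missing at
random and are only imputed during model fitting, so the outcome may be
included in their conditional models without biasing downstream
coefficients. Chained equations run over the routine numeric covariates
(Bayesian linear-regression draws for continuous/ordinal, normal-approx
posterior logistic draws for binary, visit order of increasing
missingness, 10 cycles), followed by probabilistic draws from multinomial
conditional models for the nominal variables.

Stage 2 — the infrequently-measured labs (lactate, albumin). Gaussian
GAM sub-models are fitted per completed dataset on the cases where the
lab was observed, and each completed dataset receives ``k_lab``
imputations drawn from the sub-model's posterior predictive (a
coefficient draw from the approximate posterior plus residual noise).
Because these sub-models need only routinely-available inputs, they also
run prospectively at prediction time. By default the outcome is excluded
from their covariates so prospective use is possible before the outcome
exists.

A cohort with ``m_mice`` first-stage imputations and ``k_lab`` lab draws
per completed dataset yields ``m_mice * k_lab`` completed datasets.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from . import gam
from .exceptions import FitError, ImputationError
from .preprocess import WinsorThresholds
from .schema import Cohort, VariableSpec

__all__ = [
    "ImputationConfig", "CompletedDataset", "LabImputerModel",
    "choose_n_imputations", "run_mice", "impute_categoricals",
    "fit_lab_imputer", "draw_lab_imputations", "impute_cohort",
    "LAB_VARIABLES",
]

LAB_VARIABLES = ("lactate", "albumin")


@dataclass(frozen=True)
class ImputationConfig:
    """Counts and toggles for the two imputation stages.

    ``m_mice=None`` derives the first-stage count from the fraction of
    incomplete cases via :func:`choose_n_imputations`.
    """

    m_mice: int | None = None
    k_lab: int = 3
    n_chained_cycles: int = 10
    include_outcome_in_mice: bool = True
    include_outcome_in_lab: bool = False
    lab_residual_noise: bool = True
    lab_coefficient_uncertainty: bool = True
    lactate_log_scale: bool = True
    n_coef_draws: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.m_mice is not None and self.m_mice < 1:
            raise ValueError("m_mice must be >= 1")
        if self.k_lab < 1:
            raise ValueError("k_lab must be >= 1")


@dataclass
class CompletedDataset:
    """One fully-imputed copy of a cohort with draw provenance."""

    df: pd.DataFrame
    mice_index: int
    lab_index: int | None = None

    @property
    def provenance(self) -> tuple:
        return (self.mice_index, self.lab_index)


def choose_n_imputations(frac_incomplete: float) -> int:
    """Number of imputations from the fraction of incomplete cases.

    Implements the percent-incomplete rule: ceiling of 100 x fraction,
    with a minimum of one (a fully-observed cohort needs a single copy).
    """
    if not 0 <= frac_incomplete <= 1:
        raise ValueError("frac_incomplete must lie in [0, 1]")
    return max(1, math.ceil(100 * frac_incomplete))


def _routine_numeric_variables(specs: Mapping[str, VariableSpec],
                               columns) -> list[str]:
    out = []
    for name, spec in specs.items():
        if name in LAB_VARIABLES or name == "died":
            continue
        if name.endswith("_missing"):
            continue
        if spec.is_numeric and name in columns:
            out.append(name)
    return out


def _nominal_variables(specs: Mapping[str, VariableSpec], columns) -> list[str]:
    return [n for n, s in specs.items() if s.kind == "nominal" and n in columns]


def _bayes_linear_draw(X: np.ndarray, y: np.ndarray, X_mis: np.ndarray,
                       rng: np.random.Generator) -> np.ndarray:
    """Proper imputation draw under a Bayesian linear regression: draw
    sigma^2 from its scaled inverse-chi-square posterior, beta from
    N(beta_hat, sigma^2 (X'X)^-1), then the missing values from the
    resulting predictive normal."""
    n, p = X.shape
    A = X.T @ X + 1e-6 * np.eye(p)
    beta_hat = np.linalg.solve(A, X.T @ y)
    resid = y - X @ beta_hat
    dof = max(n - p, 2)
    sigma2 = float(resid @ resid) / rng.chisquare(dof)
    L = np.linalg.cholesky(np.linalg.inv(A) * sigma2 + 1e-12 * np.eye(p))
    beta = beta_hat + L @ rng.standard_normal(p)
    return X_mis @ beta + math.sqrt(sigma2) * rng.standard_normal(len(X_mis))


def _logistic_draw(X: np.ndarray, y: np.ndarray, X_mis: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """Posterior-approximate logistic draw: beta ~ N(beta_hat, inverse
    penalized information), then Bernoulli draws at the implied
    probabilities. A small ridge keeps separation in check."""
    n, p = X.shape
    beta = np.zeros(p)
    ridge = 1e-3 * np.eye(p)
    mu = np.clip((y + 0.5) / 2, 1e-9, 1 - 1e-9)
    eta = np.log(mu / (1 - mu))
    A = None
    for _ in range(50):
        w = np.clip(mu * (1 - mu), 1e-9, None)
        z = eta + (y - mu) / w
        A = X.T @ (X * w[:, None]) + ridge
        new = np.linalg.solve(A, X.T @ (w * z))
        if np.max(np.abs(new - beta)) < 1e-8:
            beta = new
            break
        beta = new
        eta = X @ beta
        mu = np.clip(expit(eta), 1e-9, 1 - 1e-9)
    cov = np.linalg.inv(A)
    L = np.linalg.cholesky(0.5 * (cov + cov.T) + 1e-12 * np.eye(p))
    bdraw = beta + L @ rng.standard_normal(p)
    return (rng.random(len(X_mis)) < expit(X_mis @ bdraw)).astype(float)


def run_mice(cohort: Cohort, config: ImputationConfig,
             ) -> list[CompletedDataset]:
    """Chained-equations imputation of the routine numeric covariates.

    Returns ``m_mice`` completed datasets in which lactate, albumin and
    the nominal variables are still missing. Observed cells are never
    modified; the draws differ across datasets whenever any value was
    missing; everything is deterministic given the config seed.
    """
    specs = cohort.specs
    targets = _routine_numeric_variables(specs, cohort.df.columns)
    if cohort.df["died"].isna().any():
        raise ImputationError("outcome must be non-missing for every case")
    for name in targets:
        if cohort.df[name].isna().all():
            raise ImputationError(f"variable {name!r} is 100% missing; "
                                  "nothing to condition on")
    missing_frac = {n: cohort.missing_fraction(n) for n in targets}
    incomplete = [n for n in targets if missing_frac[n] > 0]
    visit_order = sorted(incomplete, key=lambda n: missing_frac[n])
    m = config.m_mice
    if m is None:
        # the percent-incomplete rule counts cases incomplete for ANY
        # routinely-collected variable, nominal ones included
        routine = targets + _nominal_variables(specs, cohort.df.columns)
        any_missing = cohort.df[routine].isna().any(axis=1)
        m = choose_n_imputations(float(any_missing.mean()))

    base = cohort.df
    out: list[CompletedDataset] = []
    for imp in range(m):
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 11, imp]))
        work = base.copy()
        if not visit_order:
            out.append(CompletedDataset(work, mice_index=imp))
            continue
        # initial fill: resample from the observed marginal
        for name in visit_order:
            obs = base[name].dropna().to_numpy(float)
            mask = work[name].isna()
            work.loc[mask, name] = rng.choice(obs, size=int(mask.sum()))
        predictors = list(targets)
        if config.include_outcome_in_mice:
            predictors.append("died")
        for name in base.columns:
            if name.endswith("_missing"):
                predictors.append(name)
        for _ in range(config.n_chained_cycles):
            for name in visit_order:
                mask = base[name].isna().to_numpy()
                others = [p for p in predictors if p != name]
                M = np.column_stack(
                    [np.ones(len(work))] + [work[p].to_numpy(float) for p in others])
                y_obs = base[name].to_numpy(float)[~mask]
                draws = _dispatch_conditional(
                    specs[name], M[~mask], y_obs, M[mask], rng)
                work.loc[mask, name] = draws
        out.append(CompletedDataset(work, mice_index=imp))
    return out


def _dispatch_conditional(spec: VariableSpec, X, y, X_mis, rng) -> np.ndarray:
    if spec.kind == "binary":
        return _logistic_draw(X, y, X_mis, rng)
    draws = _bayes_linear_draw(X, y, X_mis, rng)
    if spec.kind == "ordinal":
        cats = np.asarray(spec.allowed_categories, float)
        draws = np.clip(np.round(draws), cats.min(), cats.max())
    elif spec.plausible_range is not None:
        draws = np.clip(draws, *spec.plausible_range)
    return draws


def impute_categoricals(completed: CompletedDataset,
                        specs: Mapping[str, VariableSpec],
                        config: ImputationConfig) -> CompletedDataset:
    """Probabilistic imputation of the nominal variables (surgical
    indication, peritoneal soiling, malignancy).

    A multinomial logistic model on the (now complete) numeric covariates
    supplies per-case category probabilities; imputed levels are drawn
    from them, not set to the mode.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.preprocessing import StandardScaler

    df = completed.df.copy()
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 23, completed.mice_index]))
    numeric = _routine_numeric_variables(specs, df.columns)
    predictors = numeric + (["died"] if config.include_outcome_in_mice else [])
    for name in _nominal_variables(specs, df.columns):
        mask = df[name].isna()
        if not mask.any():
            continue
        obs_y = df.loc[~mask, name].astype(str)
        levels = sorted(obs_y.unique())
        if len(levels) == 1:
            df.loc[mask, name] = levels[0]
            continue
        X = df[predictors].to_numpy(float)
        scaler = StandardScaler().fit(X[~mask.to_numpy()])
        clf = LogisticRegression(max_iter=200, C=1.0)
        clf.fit(scaler.transform(X[~mask.to_numpy()]), obs_y)
        probs = clf.predict_proba(scaler.transform(X[mask.to_numpy()]))
        cum = probs.cumsum(axis=1)
        u = rng.random(len(cum))
        idx = (u[:, None] > cum).sum(axis=1)
        df.loc[mask, name] = np.asarray(clf.classes_, object)[idx]
    return CompletedDataset(df, completed.mice_index, completed.lab_index)


#: Default covariates of the lab imputation sub-models.
LAB_IMPUTER_CONTINUOUS = ("age", "heart_rate", "systolic_bp", "sodium",
                          "potassium", "wcc", "creatinine", "bun", "gcs")
LAB_IMPUTER_DISCRETE = ("asa", "cardio_status", "resp_status", "arrhythmia",
                        "ct_performed", "soiling", "malignancy", "indication")


@dataclass
class LabImputerModel:
    """A Gaussian GAM predicting one infrequently-measured lab.

    Carries the fitted (or pooled) coefficients with their approximate
    posterior covariance and the residual scale, so prospective imputation
    needs no training data. Lactate is modelled on the log scale and
    back-transformed on draw. Drawn values are clamped to the training
    Winsor thresholds of the target.
    """

    target: str
    model: gam.FittedGam | gam.PooledGam
    log_scale: bool
    includes_outcome: bool
    clamp: tuple[float | None, float | None] = (None, None)

    def predictive_draw(self, df: pd.DataFrame, rng: np.random.Generator,
                        coefficient_uncertainty: bool = True,
                        residual_noise: bool = True) -> np.ndarray:
        if coefficient_uncertainty:
            coef = gam.sample_coefficients(self.model, 1, rng)[0]
        else:
            coef = self.model.coef
        pred = self.model.linear_predictor(df, coef)
        if residual_noise:
            pred = pred + self.model.residual_scale * rng.standard_normal(len(pred))
        if self.log_scale:
            pred = np.exp(pred)
        lo, hi = self.clamp
        if lo is not None:
            pred = np.maximum(pred, lo)
        if hi is not None:
            pred = np.minimum(pred, hi)
        return pred

    def to_dict(self) -> dict:
        model = self.model
        if isinstance(model, gam.FittedGam):
            model = gam.pool_fits([model])
        d = gam.pooled_to_dict(model)
        d.update(target=self.target, log_scale=self.log_scale,
                 includes_outcome=self.includes_outcome,
                 clamp=list(self.clamp))
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "LabImputerModel":
        model = gam.pooled_from_dict(d)
        clamp = tuple(None if v is None else float(v) for v in d["clamp"])
        return cls(d["target"], model, d["log_scale"], d["includes_outcome"],
                   clamp)


def lab_imputer_terms(target: str, specs: Mapping[str, VariableSpec],
                      include_outcome: bool, columns) -> gam.GamSpec:
    terms = []
    for name in LAB_IMPUTER_CONTINUOUS:
        if name in columns and name != target:
            terms.append(gam.GamTermSpec("spline", (name,)))
    for name in LAB_IMPUTER_DISCRETE:
        if name in columns:
            terms.append(gam.GamTermSpec("categorical", (name,),
                                         penalty=gam.DEFAULT_CATEGORICAL_PENALTY))
    if include_outcome:
        terms.append(gam.GamTermSpec("categorical", ("died",),
                                     penalty=gam.DEFAULT_CATEGORICAL_PENALTY))
    return gam.GamSpec(tuple(terms), outcome=target)


def fit_lab_imputer(completed: CompletedDataset, target: str,
                    config: ImputationConfig,
                    specs: Mapping[str, VariableSpec],
                    thresholds: WinsorThresholds | None = None,
                    ) -> LabImputerModel:
    """Fit the Gaussian GAM for one lab on the cases where it was observed.

    The outcome enters the covariate list only when
    ``include_outcome_in_lab`` is on (off by default so the model can run
    prospectively).
    """
    if target not in LAB_VARIABLES:
        raise ValueError(f"lab imputers cover {LAB_VARIABLES}, not {target!r}")
    df = completed.df
    obs = df[df[target].notna()].copy()
    if len(obs) == 0:
        raise FitError(f"{target!r} is never observed; cannot fit its imputer")
    if len(obs) < 500:
        warnings.warn(f"only {len(obs)} observed {target!r} values; "
                      "lab imputer may be unstable")
    log_scale = config.lactate_log_scale and target == "lactate"
    fit_frame = obs
    spec = lab_imputer_terms(target, specs, config.include_outcome_in_lab,
                             df.columns)
    if log_scale:
        fit_frame = obs.copy()
        fit_frame[target] = np.log(fit_frame[target].to_numpy(float))
    fitted = gam.fit_gaussian_gam(fit_frame, target, spec,
                                  variable_specs=specs)
    clamp = (None, None)
    if thresholds is not None:
        clamp = (thresholds.lower.get(target), thresholds.upper.get(target))
    return LabImputerModel(target, fitted, log_scale,
                           config.include_outcome_in_lab, clamp)


def draw_lab_imputations(models: LabImputerModel | Sequence[LabImputerModel],
                         completed: CompletedDataset, k: int,
                         seed: int | np.random.Generator,
                         coefficient_uncertainty: bool = True,
                         residual_noise: bool = True,
                         ) -> list[CompletedDataset]:
    """Produce ``k`` lab-completed copies of one dataset.

    Each draw samples a coefficient vector from the sub-model posterior and
    then each missing value from the implied predictive distribution;
    observed values are untouched, and a dataset with no missing targets
    comes back as ``k`` identical copies.
    """
    if isinstance(models, LabImputerModel):
        models = [models]
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    out = []
    for j in range(k):
        df = completed.df.copy()
        for model in models:
            mask = df[model.target].isna()
            if mask.any():
                draws = model.predictive_draw(
                    df.loc[mask], rng,
                    coefficient_uncertainty=coefficient_uncertainty,
                    residual_noise=residual_noise)
                df.loc[mask, model.target] = draws
        out.append(CompletedDataset(df, completed.mice_index, lab_index=j))
    return out


def impute_cohort(cohort: Cohort, config: ImputationConfig,
                  thresholds: WinsorThresholds | None = None,
                  ) -> tuple[list[CompletedDataset], dict[str, LabImputerModel]]:
    """Run the full two-stage pipeline on a development cohort.

    Returns the ``m_mice * k_lab`` completed datasets plus pooled
    (Rubin's-rules) lactate/albumin imputers for prospective use.
    """
    stage1 = run_mice(cohort, config)
    stage1 = [impute_categoricals(c, cohort.specs, config) for c in stage1]
    lab_fits: dict[str, list[gam.FittedGam]] = {t: [] for t in LAB_VARIABLES
                                                if t in cohort.df.columns}
    completed: list[CompletedDataset] = []
    for c in stage1:
        models = []
        for target in lab_fits:
            m = fit_lab_imputer(c, target, config, cohort.specs, thresholds)
            lab_fits[target].append(m.model)
            models.append(m)
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 37, c.mice_index]))
        completed.extend(draw_lab_imputations(
            models, c, config.k_lab, rng,
            coefficient_uncertainty=config.lab_coefficient_uncertainty,
            residual_noise=config.lab_residual_noise))
    pooled: dict[str, LabImputerModel] = {}
    for target, fits in lab_fits.items():
        log_scale = config.lactate_log_scale and target == "lactate"
        clamp = (None, None)
        if thresholds is not None:
            clamp = (thresholds.lower.get(target), thresholds.upper.get(target))
        pooled[target] = LabImputerModel(
            target, gam.pool_fits(fits), log_scale,
            config.include_outcome_in_lab, clamp)
    return completed, pooled
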