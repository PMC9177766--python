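"""Seeded synthetic multi-hospital cohorts with a known risk function.

The real registry data cannot be shared, so every downstream stage is
exercised on cohorts drawn from this generator. It emulates:

* the study covariate set with marginal medians/IQRs matching the published
  cohort summary (log-normal for right-skewed labs, normal otherwise,
  latent-threshold ordinals/nominals);
* correlation between covariates through a latent per-case "severity"
  factor (loading on ASA, lactate, GCS, heart rate, ...), which is what
  makes missing-at-random imputation informative;
* a known logistic data-generating risk with smooth nonlinearities
  (U-shaped sodium and potassium, log-linear lactate), one
  heart-rate-by-arrhythmia and one urea-by-creatinine interaction, and
  small per-hospital intercept offsets;
* per-variable missingness at configurable rates, either completely at
  random or, for the two infrequently-measured labs, dependent on observed
  severity covariates only (sicker patients are more likely to have lactate
  and albumin measured, so their missingness decreases with severity).

Everything is reproducible from a single master seed, which streams
per-purpose child seeds (generation vs missingness injection).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .exceptions import ConfigError
from .schema import (
    Cohort,
    INDICATION_CATEGORIES,
    MALIGNANCY_CATEGORIES,
    SOILING_CATEGORIES,
    default_variable_specs,
)

__all__ = ["GeneratorConfig", "TrueModel", "generate_cohort",
           "inject_missingness", "case_study_fixture"]

# (distribution, median, spread, severity loading, renal loading)
# spread is the SD of the underlying normal (log-scale SD for "lognormal");
# derived from published median/IQR via IQR = 1.349 * SD.
CONTINUOUS_MARGINALS: dict[str, tuple[str, float, float, float, float]] = {
    "age":         ("normal",    66.0, 17.8, 0.15, 0.0),
    "heart_rate":  ("normal",    90.0, 17.0, 0.35, 0.0),
    "systolic_bp": ("normal",   125.0, 22.0, -0.30, 0.0),
    "sodium":      ("normal",   137.0, 4.45, -0.15, 0.0),
    "potassium":   ("normal",     4.1, 0.52, 0.15, 0.0),
    "wcc":         ("lognormal", 11.1, 0.504, 0.25, 0.0),
    "creatinine":  ("lognormal", 0.86, 0.379, 0.30, 0.50),
    "bun":         ("lognormal", 17.4, 0.590, 0.30, 0.50),
    "lactate":     ("lognormal",  1.5, 0.609, 0.50, 0.0),
    "albumin":     ("normal",    35.0, 8.90, -0.40, 0.0),
}

ASA_PROBS = (0.08, 0.34, 0.40, 0.14, 0.04)
CARDIO_PROBS = (0.730, 0.15, 0.08, 0.040)
RESP_PROBS = (0.726, 0.15, 0.08, 0.044)
GCS_PROBS = (0.92, 0.025, 0.012, 0.008, 0.006, 0.005, 0.005,
             0.004, 0.004, 0.004, 0.003, 0.002, 0.002)  # 15 down to 3
SOILING_PROBS = (0.39, 0.28, 0.15, 0.18)
MALIGNANCY_PROBS = (0.778, 0.10, 0.06, 0.062)
INDICATION_PROBS = (0.236, 0.11, 0.10, 0.08, 0.06, 0.05, 0.03, 0.03,
                    0.04, 0.035, 0.05, 0.04, 0.019, 0.12)

DEFAULT_MISSINGNESS: dict[str, float] = {
    "lactate": 0.364,
    "albumin": 0.593,
    "indication": 0.226,
    "cardio_status": 0.005,
    "resp_status": 0.005,
    "heart_rate": 0.011,
    "arrhythmia": 0.007,
    "systolic_bp": 0.014,
    "sodium": 0.003,
    "potassium": 0.005,
    "wcc": 0.004,
    "creatinine": 0.015,
    "bun": 0.019,
    "gcs": 0.007,
    "ct_performed": 0.010,
    "soiling": 0.003,
    "malignancy": 0.003,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters for cohort simulation."""

    n_cases: int = 20_000
    n_hospitals: int = 186
    prevalence_target: float = 0.113
    missingness_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MISSINGNESS))
    missingness_mechanism: str = "MAR-on-severity"
    hospital_sd: float = 0.10
    seed: int = 0

    def __post_init__(self):
        if self.n_hospitals > self.n_cases:
            raise ConfigError("n_hospitals must not exceed n_cases")
        if not 0 < self.prevalence_target < 1:
            raise ConfigError("prevalence_target must be in (0, 1)")
        if self.missingness_mechanism not in ("MCAR", "MAR-on-severity"):
            raise ConfigError(f"unknown missingness mechanism "
                              f"{self.missingness_mechanism!r}")
        for name, rate in self.missingness_rates.items():
            if not 0 <= rate <= 1:
                raise ConfigError(f"missingness rate for {name!r} outside [0,1]")


@dataclass
class TrueModel:
    """The generative logistic risk model, exposed for recovery tests.

    ``linear_predictor`` evaluates the population-level logit (hospital
    offset excluded); per-case true risks add the offset of the case's
    hospital before the inverse-logit.
    """

    intercept: float
    hospital_offsets: dict[str, float]

    soiling_effects = dict(zip(SOILING_CATEGORIES, (0.0, 0.15, 0.35, 0.60)))
    malignancy_effects = dict(zip(MALIGNANCY_CATEGORIES, (0.0, 0.15, 0.30, 0.50)))
    indication_effects = dict(zip(INDICATION_CATEGORIES,
                                  (0.0, 0.10, 0.35, 0.30, 0.50, 0.40, 0.20,
                                   0.25, 0.10, 0.20, -0.10, 0.0, 0.10, 0.10)))

    def linear_predictor(self, df: pd.DataFrame) -> np.ndarray:
        ln = np.log
        zb = (ln(df["bun"].to_numpy(float)) - ln(17.4)) / 0.590
        zc = (ln(df["creatinine"].to_numpy(float)) - ln(0.86)) / 0.379
        hr = df["heart_rate"].to_numpy(float)
        arr = df["arrhythmia"].to_numpy(float)
        eta = (
            self.intercept
            + 0.55 * (df["asa"].to_numpy(float) - 3.0)
            + 0.030 * (df["age"].to_numpy(float) - 66.0)
            + 0.006 * (df["sodium"].to_numpy(float) - 137.0) ** 2
            + 0.12 * (df["potassium"].to_numpy(float) - 4.1) ** 2
            + 0.60 * (ln(df["lactate"].to_numpy(float)) - ln(1.5))
            - 0.045 * (df["albumin"].to_numpy(float) - 35.0)
            - 0.12 * (df["gcs"].to_numpy(float) - 15.0)
            + 0.010 * (hr - 90.0)
            + 0.25 * arr + 0.008 * (hr - 90.0) * arr
            - 0.008 * (df["systolic_bp"].to_numpy(float) - 125.0)
            + 0.05 * (ln(df["wcc"].to_numpy(float)) - ln(11.1)) / 0.504
            + 0.25 * zb + 0.10 * zc + 0.12 * zb * zc
            + 0.10 * (df["cardio_status"].to_numpy(float))
            + 0.10 * (df["resp_status"].to_numpy(float))
            - 0.10 * df["ct_performed"].to_numpy(float)
            + np.vectorize(self.soiling_effects.get)(df["soiling"].to_numpy(object))
            + np.vectorize(self.malignancy_effects.get)(df["malignancy"].to_numpy(object))
            + np.vectorize(self.indication_effects.get)(df["indication"].to_numpy(object))
        )
        return np.asarray(eta, float)

    def risk(self, df: pd.DataFrame, include_hospital: bool = True) -> np.ndarray:
        eta = self.linear_predictor(df)
        if include_hospital:
            offs = df["hospital_id"].map(self.hospital_offsets).to_numpy(float)
            eta = eta + offs
        return expit(eta)


def _mixed_driver(rng, z: np.ndarray, loading: float,
                  renal: np.ndarray | None = None, renal_loading: float = 0.0):
    """Standard-normal driver correlated with severity (and optionally a
    shared renal factor) — the mixing preserves the N(0,1) marginal exactly."""
    resid_var = 1.0 - loading**2 - renal_loading**2
    eps = rng.standard_normal(z.shape)
    out = loading * z + np.sqrt(resid_var) * eps
    if renal is not None and renal_loading:
        out = out + renal_loading * renal
    return out


def _ordinal_from_latent(latent: np.ndarray, probs, categories) -> np.ndarray:
    from scipy.stats import norm
    cuts = norm.ppf(np.cumsum(probs)[:-1])
    idx = np.searchsorted(cuts, latent)
    return np.asarray(categories, object)[idx]


def generate_cohort(config: GeneratorConfig) -> tuple[Cohort, pd.Series, TrueModel]:
    """Draw a fully-observed cohort plus its per-case true risks.

    Returns ``(cohort, true_risks, true_model)``; outcomes are Bernoulli
    draws from the true risks and the generative intercept is calibrated by
    root-finding so that the expected prevalence matches the target.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    n = config.n_cases
    z = rng.standard_normal(n)          # latent severity
    renal = rng.standard_normal(n)      # shared urea/creatinine factor

    df = pd.DataFrame(index=np.arange(n))
    df["case_id"] = [f"c{i:07d}" for i in range(n)]

    # hospital structure with uneven sizes; every hospital contributes >= 1 case
    hosp_probs = rng.dirichlet(np.full(config.n_hospitals, 5.0))
    hosp_idx = rng.choice(config.n_hospitals, size=n, p=hosp_probs)
    hosp_idx[:config.n_hospitals] = rng.permutation(config.n_hospitals)
    df["hospital_id"] = np.array([f"h{j:03d}" for j in range(config.n_hospitals)],
                                 object)[hosp_idx]

    for name, (dist, med, sd, load, rload) in CONTINUOUS_MARGINALS.items():
        u = _mixed_driver(rng, z, load, renal, rload)
        if dist == "normal":
            df[name] = med + sd * u
        else:
            df[name] = np.exp(np.log(med) + sd * u)
    df["age"] = df["age"].clip(18, 109)
    df["systolic_bp"] = df["systolic_bp"].clip(40)
    df["albumin"] = df["albumin"].clip(6)

    df["asa"] = _ordinal_from_latent(_mixed_driver(rng, z, 0.60),
                                     ASA_PROBS, range(1, 6)).astype(float)
    df["cardio_status"] = _ordinal_from_latent(_mixed_driver(rng, z, 0.35),
                                               CARDIO_PROBS, range(4)).astype(float)
    df["resp_status"] = _ordinal_from_latent(_mixed_driver(rng, z, 0.30),
                                             RESP_PROBS, range(4)).astype(float)
    df["gcs"] = _ordinal_from_latent(_mixed_driver(rng, z, 0.55),
                                     GCS_PROBS, range(15, 2, -1)).astype(float)
    from scipy.stats import norm
    df["arrhythmia"] = (_mixed_driver(rng, z, 0.30) > norm.ppf(1 - 0.191)).astype(float)
    df["ct_performed"] = (rng.random(n) < 0.859).astype(float)
    df["soiling"] = _ordinal_from_latent(_mixed_driver(rng, z, 0.30),
                                         SOILING_PROBS, SOILING_CATEGORIES)
    df["malignancy"] = _ordinal_from_latent(_mixed_driver(rng, z, 0.10),
                                            MALIGNANCY_PROBS, MALIGNANCY_CATEGORIES)
    df["indication"] = rng.choice(np.asarray(INDICATION_CATEGORIES, object),
                                  size=n, p=INDICATION_PROBS)
    df["lactate_missing"] = 0.0
    df["albumin_missing"] = 0.0

    offsets = {f"h{j:03d}": float(v) for j, v in enumerate(
        rng.normal(0.0, config.hospital_sd, config.n_hospitals))}
    model = TrueModel(intercept=0.0, hospital_offsets=offsets)

    eta = model.linear_predictor(df)
    eta = eta + df["hospital_id"].map(offsets).to_numpy(float)

    def prevalence_gap(b0):
        return float(np.mean(expit(eta + b0))) - config.prevalence_target

    try:
        b0 = brentq(prevalence_gap, -15.0, 15.0)
    except ValueError as exc:
        raise ConfigError("prevalence target unattainable under the "
                          "generative coefficients") from exc
    model.intercept = b0

    risks = expit(eta + b0)
    df["died"] = (rng.random(n) < risks).astype(float)

    cohort = Cohort(df, default_variable_specs(),
                    provenance=f"synthetic cohort, seed={config.seed}")
    true_risks = pd.Series(risks, index=df.index, name="true_risk")
    return cohort, true_risks, model


def _severity_proxy(df: pd.DataFrame) -> np.ndarray:
    """Observed-covariate severity score used by the MAR mechanism.

    Depends only on ASA, heart rate and GCS — never on a lab's own value."""
    z = lambda s, m, sd: (s.to_numpy(float) - m) / sd  # noqa: E731
    return (0.6 * z(df["asa"], 2.8, 0.9)
            + 0.3 * z(df["heart_rate"], 90.0, 17.0)
            - 0.4 * z(df["gcs"], 14.7, 1.0))


def inject_missingness(cohort: Cohort, config: GeneratorConfig) -> Cohort:
    """Blank out values at the configured per-variable rates.

    Under ``MAR-on-severity``, lactate/albumin missingness probability is a
    decreasing function of the observed severity proxy (unwell patients are
    more likely to be measured), calibrated by root-finding so the marginal
    rate still matches the configured target. All other variables, and all
    variables under ``MCAR``, are blanked completely at random.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    df = cohort.df.copy()
    proxy = _severity_proxy(df)
    slope = -0.8
    for name, rate in config.missingness_rates.items():
        if rate <= 0 or name not in df.columns:
            continue
        if (config.missingness_mechanism == "MAR-on-severity"
                and name in ("lactate", "albumin")):
            def gap(a):
                return float(np.mean(expit(a + slope * proxy))) - rate
            a0 = brentq(gap, -20, 20)
            p_miss = expit(a0 + slope * proxy)
        else:
            p_miss = np.full(len(df), rate)
        mask = rng.random(len(df)) < p_miss
        df.loc[mask, name] = np.nan
    out = cohort.copy()
    out.df = df
    out.provenance += f" + missingness({config.missingness_mechanism})"
    return out


def case_study_fixture() -> tuple[pd.Series, pd.Series]:
    """The worked clinical vignette: an 81-year-old admitted with small
    bowel obstruction, mildly raised blood urea nitrogen (24.4 mg/dL).

    Returns ``(pre, post)`` case records: at first assessment lactate and
    albumin are not yet measured; post-measurement they are found deranged
    (albumin 25 g/L, lactate 3.2 mmol/L).
    """
    pre = pd.Series({
        "case_id": "case_study_pre",
        "hospital_id": "h000",
        "age": 81.0, "asa": 3.0,
        "cardio_status": 1.0,   # on cardiovascular medication (hypertension)
        "resp_status": 0.0,
        "heart_rate": 95.0, "arrhythmia": 0.0,
        "systolic_bp": 135.0, "sodium": 136.0, "potassium": 4.3,
        "wcc": 12.5, "creatinine": 1.1, "bun": 24.4,
        "lactate": np.nan, "albumin": np.nan,
        "gcs": 15.0, "ct_performed": 1.0,
        "soiling": "none", "malignancy": "none",
        "indication": "small_bowel_obstruction",
        "lactate_missing": 1.0, "albumin_missing": 1.0,
        "died": np.nan,
    })
    post = pre.copy()
    post["case_id"] = "case_study_post"
    post["lactate"] = 3.2
    post["albumin"] = 25.0
    post["lactate_missing"] = 0.0
    post["albumin_missing"] = 0.0
    return pre, post
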