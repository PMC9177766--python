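"""Per-case mortality-risk distributions.

Prediction composes two sources of uncertainty. For each of
``m_mice x k_lab`` completed versions of the case, any missing lactate or
albumin value is drawn from its imputation sub-model's posterior
predictive; then ``n_coef_draws`` risks are computed from coefficient
vectors sampled from the pooled model's approximate posterior. A case
with both labs missing under the published configuration
(m_mice=28, k_lab=3, 5 coefficient draws) therefore receives
28 x 3 x 5 = 420 sampled risks. Complete cases run through the same
sample grid (with duplicated completed versions) so sample counts are
uniform across cases; their spread then reflects coefficient uncertainty
alone.

The sample set is summarised by its median (the point estimate), the
2.5th-97.5th percentile span (the "risk distribution range"), and a
Gaussian kernel density with boundary reflection at 0 and 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import gaussian_kde

from . import gam
from .exceptions import PredictionError
from .impute import ImputationConfig, LAB_VARIABLES, LabImputerModel

__all__ = ["RiskDistribution", "predict_matrix", "predict_distribution",
           "summarize", "density_curve"]


@dataclass
class RiskDistribution:
    """Sampled risks for one case plus provenance and summaries.

    ``provenance`` holds one ``(mice_index, lab_index, coef_index)`` triple
    per sample; the triples enumerate the full draw grid exactly once.
    """

    case_id: str
    samples: np.ndarray
    provenance: np.ndarray   # (n_samples, 3) int

    def __post_init__(self):
        self.samples = np.asarray(self.samples, float)

    @property
    def median(self) -> float:
        return float(np.median(self.samples))

    @property
    def p2_5(self) -> float:
        return float(np.percentile(self.samples, 2.5))

    @property
    def p97_5(self) -> float:
        return float(np.percentile(self.samples, 97.5))

    @property
    def rdr(self) -> float:
        """Risk distribution range: the 2.5th-97.5th percentile span."""
        return self.p97_5 - self.p2_5


def _check_routine_complete(df: pd.DataFrame, model: gam.PooledGam) -> None:
    for name in model.info.spec.variables:
        if name in LAB_VARIABLES:
            continue
        col = df[name] if name in df.columns else None
        if col is None:
            raise PredictionError(f"case lacks covariate {name!r}")
        if col.isna().any():
            raise PredictionError(
                f"routine covariate {name!r} is missing; prospective "
                "imputation covers only lactate and albumin")


def predict_matrix(cases: pd.DataFrame, model: gam.PooledGam,
                   lab_imputers: Mapping[str, LabImputerModel],
                   config: ImputationConfig,
                   seed: int | np.random.Generator | None = None,
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Sampled risks for a batch of cases.

    Returns ``(risks, provenance)`` where risks has shape
    ``(n_cases, m_mice * k_lab * n_coef_draws)``. Per completed version one
    lab-coefficient vector is drawn (shared across cases, with per-case
    residual noise), mirroring the per-dataset draws used at fit time.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(config.seed if seed is None else seed))
    _check_routine_complete(cases, model)
    m = config.m_mice or 1
    k = config.k_lab
    s = config.n_coef_draws
    n_versions = m * k
    n_cases = len(cases)
    risks = np.empty((n_cases, n_versions * s))
    prov = np.empty((n_versions * s, 3), int)
    for v in range(n_versions):
        df_v = cases.copy()
        for name, imputer in lab_imputers.items():
            mask = df_v[name].isna()
            if mask.any():
                df_v.loc[mask, name] = imputer.predictive_draw(
                    df_v.loc[mask], rng,
                    coefficient_uncertainty=config.lab_coefficient_uncertainty,
                    residual_noise=config.lab_residual_noise)
        X = gam.build_design(df_v, model.info)
        coef_draws = gam.sample_coefficients(model, s, rng)
        risks[:, v * s:(v + 1) * s] = expit(X @ coef_draws.T)
        prov[v * s:(v + 1) * s, 0] = v // k
        prov[v * s:(v + 1) * s, 1] = v % k
        prov[v * s:(v + 1) * s, 2] = np.arange(s)
    return risks, prov


def predict_distribution(case: pd.Series | pd.DataFrame, model: gam.PooledGam,
                         lab_imputers: Mapping[str, LabImputerModel],
                         config: ImputationConfig,
                         seed: int | np.random.Generator | None = None,
                         ) -> RiskDistribution:
    """Predict the mortality-risk distribution for a single case.

    All covariates except lactate/albumin must be observed; missing labs
    are imputed ``m_mice x k_lab`` times and each completed version
    receives ``n_coef_draws`` sampled risks.
    """
    if isinstance(case, pd.Series):
        frame = case.to_frame().T
    else:
        frame = case
        if len(frame) != 1:
            raise ValueError("predict_distribution takes a single case")
    for col in frame.columns:
        if col not in ("case_id", "hospital_id", "soiling", "malignancy",
                       "indication"):
            try:
                frame[col] = pd.to_numeric(frame[col])
            except (ValueError, TypeError):
                pass
    risks, prov = predict_matrix(frame, model, lab_imputers, config, seed)
    case_id = str(frame["case_id"].iloc[0]) if "case_id" in frame else "case"
    return RiskDistribution(case_id, risks[0], prov)


def summarize(dist: RiskDistribution | np.ndarray) -> dict:
    """Median, 2.5th/97.5th percentiles and the risk distribution range."""
    samples = dist.samples if isinstance(dist, RiskDistribution) else np.asarray(dist)
    if samples.size == 0:
        raise ValueError("empty risk distribution")
    if samples.size < 2:
        raise ValueError("summarize needs at least 2 samples")
    p2_5, med, p97_5 = np.percentile(samples, [2.5, 50, 97.5])
    return {"median": float(med), "p2.5": float(p2_5), "p97.5": float(p97_5),
            "rdr": float(p97_5 - p2_5)}


def density_curve(dist: RiskDistribution | np.ndarray,
                  bandwidth: float | None = None,
                  n_grid: int = 512) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-kernel density of the sampled risks on a grid over [0, 1].

    Kernel mass that would leak past 0 or 1 is reflected back so the
    density integrates to one on the unit interval. The bandwidth defaults
    to Scott's plug-in rule.
    """
    samples = dist.samples if isinstance(dist, RiskDistribution) else np.asarray(dist)
    if samples.size < 10:
        raise ValueError("density_curve needs at least 10 samples")
    grid = np.linspace(0.0, 1.0, n_grid)
    if np.ptp(samples) == 0:
        warnings.warn("all risk samples identical; rendering a spike")
        dens = np.zeros(n_grid)
        i = int(np.argmin(np.abs(grid - samples[0])))
        dens[i] = 1.0 / (grid[1] - grid[0])
        return grid, dens
    kde = gaussian_kde(samples, bw_method=bandwidth)
    dens = kde(grid) + kde(-grid) + kde(2.0 - grid)
    return grid, dens
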