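"""Penalized generalized additive models on B-spline bases.

The risk model is a binomial-logit GAM: each continuous covariate enters
through 10 second-degree B-splines with linearly-spaced knots over the
training range, discrete covariates are dummy-coded with the base category
excluded, and selected covariate pairs enter as tensor-product
interactions (column-wise products of the marginal bases).

Smoothness of each spline term is controlled by a penalty on its second
derivative (a P-spline second-difference penalty on the coefficients);
inter-category differences are limited by an L2 penalty. Fitting is
penalized maximum likelihood by iteratively reweighted least squares; the
inverse of the penalized information matrix at convergence is kept as an
approximate (Gaussian) posterior covariance over the coefficients, which
downstream prediction samples from. Fits on multiply-imputed datasets are
combined with Rubin's rules.

The same machinery with an identity link and Gaussian errors backs the
lactate/albumin imputation sub-models.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit, logit

from .exceptions import (DegenerateOutcomeError, DesignError, FitError,
                         PoolingError)
from .schema import Cohort, VariableSpec

__all__ = [
    "GamTermSpec", "GamSpec", "DesignInfo", "FittedGam", "PooledGam",
    "bspline_basis", "fit_design_info", "build_design", "fit_binomial_gam",
    "fit_gaussian_gam", "pool_fits", "sample_coefficients",
    "backward_eliminate", "partial_dependence", "predict_risk",
    "choose_penalty_multiplier", "default_risk_terms",
]

DEFAULT_N_SPLINES = 10
DEFAULT_DEGREE = 2
DEFAULT_SPLINE_PENALTY = 10.0
DEFAULT_CATEGORICAL_PENALTY = 1.0
DEFAULT_TENSOR_PENALTY = 10.0


@dataclass(frozen=True)
class GamTermSpec:
    """One model term: a spline, a dummy-coded categorical, or a tensor
    product of two marginal bases."""

    kind: str                       # "spline" | "categorical" | "tensor"
    variables: tuple[str, ...]
    n_splines: int = DEFAULT_N_SPLINES
    degree: int = DEFAULT_DEGREE
    penalty: float = DEFAULT_SPLINE_PENALTY

    def __post_init__(self):
        object.__setattr__(self, "variables", tuple(self.variables))
        if self.kind not in ("spline", "categorical", "tensor"):
            raise FitError(f"unknown term kind {self.kind!r}")
        if self.kind == "tensor" and len(self.variables) != 2:
            raise FitError("tensor terms reference exactly 2 variables")
        if self.kind in ("spline", "categorical") and len(self.variables) != 1:
            raise FitError(f"{self.kind} terms reference exactly 1 variable")
        if self.penalty < 0:
            raise FitError("penalty weights must be >= 0")

    @property
    def label(self) -> str:
        return f"{self.kind}({'*'.join(self.variables)})"


@dataclass(frozen=True)
class GamSpec:
    """Ordered term list with a logit link and binomial errors."""

    terms: tuple[GamTermSpec, ...]
    outcome: str = "died"

    def __post_init__(self):
        object.__setattr__(self, "terms", tuple(self.terms))
        labels = [t.label for t in self.terms]
        if len(set(labels)) != len(labels):
            raise FitError("duplicate terms in GAM specification")

    @property
    def variables(self) -> tuple[str, ...]:
        seen: list[str] = []
        for t in self.terms:
            for v in t.variables:
                if v not in seen:
                    seen.append(v)
        return tuple(seen)

    def drop_variable(self, name: str) -> "GamSpec":
        kept = tuple(t for t in self.terms if name not in t.variables)
        if not kept:
            raise ValueError("dropping this variable would empty the model")
        return GamSpec(kept, self.outcome)

    def scale_penalties(self, multiplier: float) -> "GamSpec":
        return GamSpec(tuple(replace(t, penalty=t.penalty * multiplier)
                             for t in self.terms), self.outcome)


#: The six default covariate interactions of the risk model.
DEFAULT_INTERACTIONS = (
    ("heart_rate", "arrhythmia"),
    ("bun", "creatinine"),
    ("cardio_status", "resp_status"),
    ("ct_performed", "soiling"),
    ("ct_performed", "malignancy"),
    ("ct_performed", "indication"),
)


def default_risk_terms(specs: Mapping[str, VariableSpec],
                       variables: Iterable[str] | None = None,
                       interactions: Iterable[tuple[str, str]] = DEFAULT_INTERACTIONS,
                       ) -> GamSpec:
    """The study's default risk-model specification over a variable set.

    Continuous variables become spline terms, discrete ones categorical
    terms; interactions among the included variables become tensor terms.
    """
    if variables is None:
        variables = [n for n in specs if n != "died"]
    variables = [v for v in variables]
    terms = []
    for name in variables:
        spec = specs[name]
        if spec.kind == "continuous":
            terms.append(GamTermSpec("spline", (name,)))
        else:
            terms.append(GamTermSpec("categorical", (name,),
                                     penalty=DEFAULT_CATEGORICAL_PENALTY))
    for a, b in interactions:
        if a in variables and b in variables:
            terms.append(GamTermSpec("tensor", (a, b),
                                     penalty=DEFAULT_TENSOR_PENALTY))
    return GamSpec(tuple(terms))


# ---------------------------------------------------------------------------
# basis construction


def bspline_basis(x: np.ndarray, lo: float, hi: float,
                  n_splines: int = DEFAULT_N_SPLINES,
                  degree: int = DEFAULT_DEGREE) -> np.ndarray:
    """Evaluate a B-spline basis with linearly-spaced knots on [lo, hi].

    Inputs outside the knot range are clamped to it (consistent with the
    Winsorization of training data). Rows sum to 1 everywhere in range
    (partition of unity).
    """
    if not hi > lo:
        raise FitError("degenerate spline range: upper knot must exceed lower")
    inner = np.linspace(lo, hi, n_splines - degree + 1)
    t = np.concatenate([np.full(degree, lo), inner, np.full(degree, hi)])
    xc = np.clip(np.asarray(x, float), lo, hi)
    return BSpline.design_matrix(xc, t, degree, extrapolate=False).toarray()


def _second_difference_penalty(k: int) -> np.ndarray:
    """P-spline curvature penalty D2' D2 for k spline coefficients."""
    if k < 3:
        return np.zeros((k, k))
    D = np.diff(np.eye(k), n=2, axis=0)
    return D.T @ D


@dataclass
class _MarginalEncoding:
    """How one variable maps to design columns inside a term."""

    variable: str
    kind: str                              # "spline" | "dummy"
    lo: float = 0.0
    hi: float = 1.0
    n_splines: int = DEFAULT_N_SPLINES
    degree: int = DEFAULT_DEGREE
    categories: tuple = ()
    base: object = None

    @property
    def n_columns(self) -> int:
        if self.kind == "spline":
            return self.n_splines
        return len(self.categories) - 1

    def basis(self, values: pd.Series) -> np.ndarray:
        arr = values.to_numpy()
        if pd.isna(arr).any():
            bad = values.index[pd.isna(arr)][0]
            raise DesignError(f"missing value for {self.variable!r} "
                              f"(case index {bad})")
        if self.kind == "spline":
            return bspline_basis(arr.astype(float), self.lo, self.hi,
                                 self.n_splines, self.degree)
        nonbase = [c for c in self.categories if c != self.base]
        cols = np.zeros((len(arr), len(nonbase)))
        known = set(self.categories)
        for j, cat in enumerate(nonbase):
            cols[:, j] = np.asarray([v == cat for v in arr], float)
        for v in arr:
            if v not in known:
                raise DesignError(f"unknown level {v!r} for {self.variable!r}")
        return cols

    def unit_penalty(self) -> np.ndarray:
        if self.kind == "spline":
            return _second_difference_penalty(self.n_columns)
        return np.eye(self.n_columns)


def _fit_marginal(df: pd.DataFrame, name: str, spec: VariableSpec | None,
                  term: GamTermSpec) -> _MarginalEncoding:
    is_cont = spec is not None and spec.kind == "continuous"
    if spec is None:
        is_cont = pd.api.types.is_float_dtype(df[name]) and df[name].nunique() > 10
    if is_cont:
        vals = df[name].dropna().to_numpy(float)
        if vals.size == 0:
            raise FitError(f"no observed values to place knots for {name!r}")
        lo, hi = float(vals.min()), float(vals.max())
        if not hi > lo:
            raise FitError(f"constant variable {name!r} cannot carry a spline")
        return _MarginalEncoding(name, "spline", lo, hi,
                                 term.n_splines, term.degree)
    if spec is not None and spec.allowed_categories is not None:
        cats = tuple(spec.allowed_categories)
        base = spec.base_category if spec.base_category is not None else cats[0]
    else:
        cats = tuple(sorted(df[name].dropna().unique(), key=str))
        base = cats[0]
    # ordinal levels live as floats in the frame
    if spec is not None and spec.kind in ("ordinal", "binary"):
        cats = tuple(float(c) for c in cats)
        base = float(base)
    return _MarginalEncoding(name, "dummy", categories=cats, base=base)


@dataclass
class _TermEncoding:
    term: GamTermSpec
    marginals: tuple[_MarginalEncoding, ...]
    sl: slice = field(default_factory=lambda: slice(0, 0))

    @property
    def n_columns(self) -> int:
        n = 1
        for m in self.marginals:
            n *= m.n_columns
        return n

    def build(self, df: pd.DataFrame) -> np.ndarray:
        blocks = [m.basis(df[m.variable]) for m in self.marginals]
        if len(blocks) == 1:
            return blocks[0]
        a, b = blocks
        return np.einsum("ij,ik->ijk", a, b).reshape(len(df), -1)

    def penalty(self) -> np.ndarray:
        w = self.term.penalty
        if len(self.marginals) == 1:
            return w * self.marginals[0].unit_penalty()
        p1 = self.marginals[0].unit_penalty()
        p2 = self.marginals[1].unit_penalty()
        i1, i2 = np.eye(p1.shape[0]), np.eye(p2.shape[0])
        return w * (np.kron(p1, i2) + np.kron(i1, p2))


@dataclass
class DesignInfo:
    """Frozen training-data encoding: knots, category maps, column layout,
    block penalty, and reference values for partial dependence."""

    spec: GamSpec
    encodings: tuple[_TermEncoding, ...]
    reference: dict
    n_columns: int

    def column_labels(self) -> list[str]:
        labels = ["intercept"]
        for enc in self.encodings:
            labels += [f"{enc.term.label}[{j}]" for j in range(enc.n_columns)]
        return labels

    def variable_columns(self, name: str) -> np.ndarray:
        """Indices of all design columns whose term involves ``name``
        (marginal and tensor blocks alike)."""
        idx: list[int] = []
        for enc in self.encodings:
            if name in enc.term.variables:
                idx.extend(range(enc.sl.start, enc.sl.stop))
        return np.asarray(idx, int)

    def penalty_matrix(self) -> np.ndarray:
        P = np.zeros((self.n_columns, self.n_columns))
        for enc in self.encodings:
            P[enc.sl, enc.sl] = enc.penalty()
        return P

    def reference_frame(self, n: int = 1) -> pd.DataFrame:
        return pd.DataFrame({k: [v] * n for k, v in self.reference.items()})


def fit_design_info(df: pd.DataFrame, spec: GamSpec,
                    variable_specs: Mapping[str, VariableSpec] | None = None,
                    ) -> DesignInfo:
    """Freeze the design encoding on training data: knot ranges from the
    training range of each continuous variable, category maps from the
    variable specs, reference values at the median (continuous) or base
    category (discrete)."""
    variable_specs = variable_specs or {}
    marg_cache: dict[str, _MarginalEncoding] = {}
    encs: list[_TermEncoding] = []
    col = 1  # column 0 is the intercept
    for term in spec.terms:
        margs = []
        for v in term.variables:
            if v not in marg_cache:
                marg_cache[v] = _fit_marginal(df, v, variable_specs.get(v), term)
            margs.append(marg_cache[v])
        enc = _TermEncoding(term, tuple(margs))
        enc.sl = slice(col, col + enc.n_columns)
        col += enc.n_columns
        encs.append(enc)
    reference = {}
    for v, m in marg_cache.items():
        if m.kind == "spline":
            reference[v] = float(df[v].dropna().median())
        else:
            reference[v] = m.base
    return DesignInfo(spec, tuple(encs), reference, col)


def build_design(df: pd.DataFrame, info: DesignInfo) -> np.ndarray:
    """Evaluate the design matrix (intercept + all term blocks) on a frame
    with no missing values among the model covariates."""
    X = np.empty((len(df), info.n_columns))
    X[:, 0] = 1.0
    for enc in info.encodings:
        X[:, enc.sl] = enc.build(df)
    return X


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FittedGam:
    """One penalized fit: coefficients plus approximate posterior covariance
    (inverse penalized information), with the frozen design."""

    info: DesignInfo
    coef: np.ndarray
    cov: np.ndarray
    loglik: float
    converged: bool
    family: str = "binomial"
    residual_scale: float | None = None   # gaussian fits only
    edof: float | None = None

    def linear_predictor(self, df: pd.DataFrame,
                         coef: np.ndarray | None = None) -> np.ndarray:
        X = build_design(df, self.info)
        return X @ (self.coef if coef is None else coef)


@dataclass
class PooledGam:
    """Rubin's-rules combination of fits on multiply-imputed datasets."""

    info: DesignInfo
    coef: np.ndarray
    cov: np.ndarray
    m: int
    within_cov: np.ndarray
    between_cov: np.ndarray
    family: str = "binomial"
    residual_scale: float | None = None

    def linear_predictor(self, df: pd.DataFrame,
                         coef: np.ndarray | None = None) -> np.ndarray:
        X = build_design(df, self.info)
        return X @ (self.coef if coef is None else coef)


def _solve_spd(A: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, tuple]:
    jitter = 0.0
    for _ in range(6):
        try:
            c = cho_factor(A + jitter * np.eye(A.shape[0]), lower=True)
            return cho_solve(c, b), c
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10, 1e-8 * np.trace(A) / A.shape[0])
    raise FitError("penalized information matrix is numerically singular")


_MU_EPS = 1e-10
IRLS_MAX_ITER = 100
IRLS_TOL = 1e-6


def _binomial_loglik(y: np.ndarray, mu: np.ndarray) -> float:
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    return float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))


def fit_binomial_gam(data: pd.DataFrame | Cohort, spec: GamSpec,
                     info: DesignInfo | None = None,
                     variable_specs: Mapping[str, VariableSpec] | None = None,
                     ) -> FittedGam:
    """Penalized IRLS fit of the binomial-logit GAM on a completed dataset.

    Requires both outcome classes; convergence is declared when the relative
    change in penalized log-likelihood falls below 1e-6 within 100
    iterations (a non-converged fit is returned flagged, with a warning).
    """
    if isinstance(data, Cohort):
        variable_specs = variable_specs or data.specs
        df = data.df
    else:
        df = data
    y = df[spec.outcome].to_numpy(float)
    if pd.isna(y).any():
        raise DesignError(f"outcome {spec.outcome!r} has missing values")
    if len(np.unique(y)) < 2:
        raise DegenerateOutcomeError(
            f"outcome {spec.outcome!r} has a single class; cannot fit")
    if info is None:
        info = fit_design_info(df, spec, variable_specs)
    X = build_design(df, info)
    P = info.penalty_matrix()
    P = P + 1e-8 * np.eye(P.shape[0])

    mu = np.clip((y + 0.5) / 2, _MU_EPS, 1 - _MU_EPS)
    eta = logit(mu)
    beta = np.zeros(X.shape[1])
    pen_ll_old = -np.inf
    converged = False
    A = None
    for _ in range(IRLS_MAX_ITER):
        w = np.clip(mu * (1 - mu), _MU_EPS, None)
        z = eta + (y - mu) / w
        Xw = X * w[:, None]
        A = X.T @ Xw + P
        beta, _ = _solve_spd(A, X.T @ (w * z))
        eta = X @ beta
        mu = np.clip(expit(eta), _MU_EPS, 1 - _MU_EPS)
        pen_ll = _binomial_loglik(y, mu) - 0.5 * beta @ P @ beta
        if abs(pen_ll - pen_ll_old) / (abs(pen_ll) + 0.1) < IRLS_TOL:
            converged = True
            break
        pen_ll_old = pen_ll
    if not converged:
        warnings.warn("binomial GAM did not converge within "
                      f"{IRLS_MAX_ITER} IRLS iterations")
    cov = np.linalg.inv(A)
    cov = 0.5 * (cov + cov.T)
    edof = float(np.trace(cov @ (A - P)))
    return FittedGam(info, beta, cov, _binomial_loglik(y, mu), converged,
                     family="binomial", edof=edof)


def fit_gaussian_gam(df: pd.DataFrame, target: str, spec: GamSpec,
                     info: DesignInfo | None = None,
                     variable_specs: Mapping[str, VariableSpec] | None = None,
                     ) -> FittedGam:
    """Penalized least-squares fit with identity link and Gaussian errors
    (used by the lactate/albumin imputation sub-models).

    The approximate coefficient posterior is N(beta, sigma^2 (X'X + P)^-1)
    with sigma^2 the residual variance on effective degrees of freedom.
    """
    y = df[target].to_numpy(float)
    if pd.isna(y).any():
        raise DesignError(f"target {target!r} has missing values in the fit frame")
    if np.std(y) == 0:
        raise FitError(f"zero-variance target {target!r}")
    if info is None:
        info = fit_design_info(df, spec, variable_specs)
    X = build_design(df, info)
    P = info.penalty_matrix() + 1e-8 * np.eye(info.n_columns)
    A = X.T @ X + P
    beta, _ = _solve_spd(A, X.T @ y)
    Ainv = np.linalg.inv(A)
    edof = float(np.trace(Ainv @ (X.T @ X)))
    resid = y - X @ beta
    dof = max(len(y) - edof, 1.0)
    sigma2 = float(resid @ resid / dof)
    cov = sigma2 * Ainv
    cov = 0.5 * (cov + cov.T)
    ll = -0.5 * len(y) * np.log(2 * np.pi * sigma2) - 0.5 * resid @ resid / sigma2
    return FittedGam(info, beta, cov, float(ll), True, family="gaussian",
                     residual_scale=float(np.sqrt(sigma2)), edof=edof)


def pool_fits(fits: Sequence[FittedGam]) -> PooledGam:
    """Rubin's rules: pooled coefficient = mean of component coefficients;
    pooled covariance = mean within-fit covariance + (1 + 1/m) x between-fit
    coefficient covariance."""
    if len(fits) == 0:
        raise PoolingError("need at least one fit to pool")
    labels0 = fits[0].info.column_labels()
    for f in fits[1:]:
        if f.info.column_labels() != labels0:
            raise PoolingError("cannot pool fits with different term maps")
    m = len(fits)
    coefs = np.stack([f.coef for f in fits])
    qbar = coefs.mean(axis=0)
    W = np.mean([f.cov for f in fits], axis=0)
    if m > 1:
        dev = coefs - qbar
        B = dev.T @ dev / (m - 1)
    else:
        B = np.zeros_like(W)
    T = W + (1 + 1 / m) * B
    scale = None
    if fits[0].family == "gaussian":
        scale = float(np.sqrt(np.mean([f.residual_scale ** 2 for f in fits])))
    return PooledGam(fits[0].info, qbar, 0.5 * (T + T.T), m, W, B,
                     family=fits[0].family, residual_scale=scale)


def sample_coefficients(model: PooledGam | FittedGam, n_draws: int,
                        seed: int | np.random.Generator = 0) -> np.ndarray:
    """Multivariate-normal draws from the approximate coefficient posterior.

    Returns an ``(n_draws, p)`` array; with a zero covariance every draw
    equals the posterior mean.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    cov = model.cov
    if not np.any(cov):
        return np.tile(model.coef, (n_draws, 1))
    p = cov.shape[0]
    jitter = 0.0
    for _ in range(8):
        try:
            L = np.linalg.cholesky(cov + jitter * np.eye(p))
            break
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10, 1e-12 * np.trace(cov) / p)
    else:
        raise FitError("coefficient covariance is not positive semi-definite")
    zs = rng.standard_normal((n_draws, p))
    return model.coef[None, :] + zs @ L.T


def predict_risk(model: PooledGam | FittedGam, df: pd.DataFrame,
                 coef: np.ndarray | None = None) -> np.ndarray:
    """Predicted event probability under the logit link; always in (0,1)."""
    return expit(model.linear_predictor(df, coef))


def _wald_stat(fit: FittedGam, cols: np.ndarray) -> float:
    b = fit.coef[cols]
    V = fit.cov[np.ix_(cols, cols)]
    x, _ = _solve_spd(V, b)
    return float(b @ x)


def backward_eliminate(candidates: GamSpec, data: pd.DataFrame | Cohort,
                       n_remove: int,
                       variable_specs: Mapping[str, VariableSpec] | None = None,
                       ) -> GamSpec:
    """Iteratively drop the candidate variable most weakly associated with
    the outcome in multivariable modelling.

    At each step the model is refit and the variable with the smallest
    joint Wald chi-square over all of its design columns (marginal and
    tensor blocks together) is removed. Deterministic given the data.
    """
    if isinstance(data, Cohort):
        variable_specs = variable_specs or data.specs
        data = data.df
    spec = candidates
    if n_remove >= len(spec.variables):
        raise ValueError("n_remove must be smaller than the number of "
                         "candidate variables")
    for _ in range(n_remove):
        fit = fit_binomial_gam(data, spec, variable_specs=variable_specs)
        stats = {}
        for v in spec.variables:
            cols = fit.info.variable_columns(v)
            stats[v] = _wald_stat(fit, cols) / max(len(cols), 1)
        weakest = min(stats, key=stats.get)
        spec = spec.drop_variable(weakest)
    return spec


DEFAULT_CONFIDENCE_LEVELS = (95, 70, 45, 20)


def partial_dependence(model: PooledGam | FittedGam, variable: str,
                       grid: np.ndarray | Sequence | None = None,
                       confidence_levels: Sequence[float] = DEFAULT_CONFIDENCE_LEVELS,
                       n_draws: int = 400, seed: int = 0) -> dict:
    """Predicted-risk profile over one covariate with the others held at
    reference values (continuous at the training median, discrete at the
    base category), with nested posterior confidence bands.

    Returns ``{"grid", "median", "bands": {level: (lo, hi)}}``; the bands
    are risk quantiles across coefficient draws and are nested by
    construction (20% inside 45% inside 70% inside 95%).
    """
    enc = None
    for e in model.info.encodings:
        if e.term.variables == (variable,):
            enc = e.marginals[0]
            break
    if enc is None:
        for e in model.info.encodings:
            if variable in e.term.variables:
                enc = next(m for m in e.marginals if m.variable == variable)
                break
    if enc is None:
        raise ValueError(f"variable {variable!r} is not in the model")
    if grid is None:
        if enc.kind == "spline":
            grid = np.linspace(enc.lo, enc.hi, 100)
        else:
            grid = list(enc.categories)
    grid = np.asarray(grid, object if enc.kind == "dummy" else float)
    frame = model.info.reference_frame(len(grid))
    frame[variable] = grid
    X = build_design(frame, model.info)
    draws = sample_coefficients(model, n_draws, seed)
    risks = expit(X @ draws.T)             # (grid, draws)
    out = {"grid": grid, "median": np.median(risks, axis=1), "bands": {}}
    for level in confidence_levels:
        alpha = (1 - level / 100) / 2
        lo = np.quantile(risks, alpha, axis=1)
        hi = np.quantile(risks, 1 - alpha, axis=1)
        out["bands"][level] = (lo, hi)
    return out


def choose_penalty_multiplier(df: pd.DataFrame, spec: GamSpec,
                              multipliers: Sequence[float] = (0.1, 1.0, 10.0, 100.0),
                              variable_specs: Mapping[str, VariableSpec] | None = None,
                              ) -> tuple[float, GamSpec]:
    """Pick a global penalty multiplier by generalized cross-validation.

    GCV score = n * deviance / (n - edof)^2, minimised over the grid; the
    per-term relative penalty scales stay fixed. Returns the winning
    multiplier and the rescaled specification.
    """
    n = len(df)
    best, best_score = None, np.inf
    for mlt in multipliers:
        fit = fit_binomial_gam(df, spec.scale_penalties(mlt),
                               variable_specs=variable_specs)
        dev = -2 * fit.loglik
        score = n * dev / (n - fit.edof) ** 2
        if score < best_score:
            best, best_score = mlt, score
    return best, spec.scale_penalties(best)


# ---------------------------------------------------------------------------
# serialization


def _encoding_to_dict(m: _MarginalEncoding) -> dict:
    d = {"variable": m.variable, "kind": m.kind}
    if m.kind == "spline":
        d.update(lo=m.lo, hi=m.hi, n_splines=m.n_splines, degree=m.degree)
    else:
        d.update(categories=list(m.categories), base=m.base)
    return d


def _encoding_from_dict(d: dict) -> _MarginalEncoding:
    if d["kind"] == "spline":
        return _MarginalEncoding(d["variable"], "spline", d["lo"], d["hi"],
                                 d["n_splines"], d["degree"])
    cats = tuple(d["categories"])
    return _MarginalEncoding(d["variable"], "dummy", categories=cats,
                             base=d["base"])


def pooled_to_dict(model: PooledGam) -> dict:
    info = model.info
    return {
        "family": model.family,
        "outcome": info.spec.outcome,
        "m": model.m,
        "residual_scale": model.residual_scale,
        "terms": [{"kind": t.kind, "variables": list(t.variables),
                   "n_splines": t.n_splines, "degree": t.degree,
                   "penalty": t.penalty} for t in info.spec.terms],
        "encodings": [[_encoding_to_dict(m) for m in e.marginals]
                      for e in info.encodings],
        "reference": {k: (v if not isinstance(v, np.floating) else float(v))
                      for k, v in info.reference.items()},
        "coef": model.coef.tolist(),
        "cov": model.cov.tolist(),
        "within_cov_diag": np.diag(model.within_cov).tolist(),
        "between_cov_diag": np.diag(model.between_cov).tolist(),
    }


def pooled_from_dict(d: dict) -> PooledGam:
    terms = tuple(GamTermSpec(t["kind"], tuple(t["variables"]), t["n_splines"],
                              t["degree"], t["penalty"]) for t in d["terms"])
    spec = GamSpec(terms, d["outcome"])
    encs = []
    col = 1
    for term, margs in zip(terms, d["encodings"]):
        enc = _TermEncoding(term, tuple(_encoding_from_dict(m) for m in margs))
        enc.sl = slice(col, col + enc.n_columns)
        col += enc.n_columns
        encs.append(enc)
    info = DesignInfo(spec, tuple(encs), dict(d["reference"]), col)
    coef = np.asarray(d["coef"], float)
    cov = np.asarray(d["cov"], float)
    p = len(coef)
    W = np.diag(np.asarray(d["within_cov_diag"], float))
    B = np.diag(np.asarray(d["between_cov_diag"], float))
    return PooledGam(info, coef, cov, int(d["m"]), W, B,
                     family=d["family"], residual_scale=d.get("residual_scale"))
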