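"""Validation machinery: probabilistic scores, smooth calibration,
hospital-grouped repeated cross-validation, and a complete-case logistic
baseline comparator.

Development/validation splitting is grouped by hospital (80% of hospitals
train, the rest test, repeated 120 times by default) so that validation
approximates deployment at unseen centres. Every round re-fits the
Winsor thresholds, the imputation sub-models and the risk model on the
development cases alone. Scores are summarised across rounds by their
median and 2.5th/97.5th percentiles, and model comparisons are paired
within rounds before aggregation.

For a distributional model the point scores are computed per sampled-risk
column and averaged across columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import rankdata

from . import gam
from .exceptions import EvaluationError, SplitError
from .impute import ImputationConfig, LAB_VARIABLES, impute_cohort
from .predict import predict_matrix
from .preprocess import add_missingness_indicators, apply_winsor, fit_winsor_thresholds
from .schema import Cohort, VariableSpec

__all__ = [
    "SplitPlan", "ScoreReport", "BaselineConfig", "make_split_plan",
    "score_predictions", "score_distribution_model", "calibration_curve",
    "aggregate_cv", "fit_baseline", "run_validation", "SCORE_NAMES",
]

SCORE_NAMES = ("auroc", "tjur", "log_loss", "brier", "mace")

DEFAULT_N_SPLITS = 120
DEFAULT_TRAIN_FRAC = 0.8


@dataclass
class SplitPlan:
    """Hospital-grouped repeated train/test partitions."""

    splits: list[tuple[frozenset, frozenset]]
    train_frac: float
    seed: int

    @property
    def n_splits(self) -> int:
        return len(self.splits)


def make_split_plan(hospital_ids: Sequence, n_splits: int = DEFAULT_N_SPLITS,
                    train_frac: float = DEFAULT_TRAIN_FRAC,
                    seed: int = 0) -> SplitPlan:
    """Randomly partition hospitals into train/test sets, repeatedly.

    Within each split the hospital sets are disjoint and jointly
    exhaustive; case membership follows the case's hospital. Duplicate
    test sets are re-drawn (best effort) so splits differ across indices.
    """
    hospitals = sorted(set(map(str, hospital_ids)))
    if len(hospitals) < 2:
        raise SplitError("grouped splitting needs at least 2 hospitals")
    n_train = int(round(train_frac * len(hospitals)))
    n_train = min(max(n_train, 1), len(hospitals) - 1)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 404]))
    splits: list[tuple[frozenset, frozenset]] = []
    seen: set[frozenset] = set()
    for _ in range(n_splits):
        for _attempt in range(100):
            perm = rng.permutation(hospitals)
            test = frozenset(perm[n_train:])
            if test not in seen:
                break
        seen.add(test)
        splits.append((frozenset(perm[:n_train]), test))
    return SplitPlan(splits, train_frac, seed)


def _check_binary(outcomes: np.ndarray) -> None:
    if len(np.unique(outcomes)) < 2:
        raise EvaluationError("outcomes contain a single class; "
                              "discrimination is undefined")


def auroc_score(risks: np.ndarray, outcomes: np.ndarray) -> float:
    """Pairwise concordance probability with ties counted 1/2
    (the rank-statistic form of the area under the ROC curve)."""
    _check_binary(outcomes)
    r = rankdata(risks)
    n1 = int(outcomes.sum())
    n0 = len(outcomes) - n1
    return float((r[outcomes == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def score_predictions(risks: np.ndarray, outcomes: np.ndarray) -> dict:
    """Point-prediction scores: AUROC, Tjur's discrimination coefficient,
    log loss (natural log, probabilities clipped to [1e-15, 1-1e-15]) and
    the Brier score."""
    risks = np.asarray(risks, float)
    outcomes = np.asarray(outcomes, float)
    if risks.shape != outcomes.shape:
        raise EvaluationError("risks and outcomes must have equal length")
    _check_binary(outcomes)
    p = np.clip(risks, 1e-15, 1 - 1e-15)
    return {
        "auroc": auroc_score(risks, outcomes),
        "tjur": float(risks[outcomes == 1].mean() - risks[outcomes == 0].mean()),
        "log_loss": float(-np.mean(outcomes * np.log(p)
                                   + (1 - outcomes) * np.log(1 - p))),
        "brier": float(np.mean((risks - outcomes) ** 2)),
    }


def score_distribution_model(sample_matrix: np.ndarray, outcomes: np.ndarray,
                             include_mace: bool = False) -> dict:
    """Score each sampled-risk column as a point prediction and average
    the scores across columns."""
    M = np.asarray(sample_matrix, float)
    if M.ndim != 2 or M.shape[0] != len(outcomes):
        raise EvaluationError("sample matrix must be (n_cases, n_samples)")
    per_col = [score_predictions(M[:, j], outcomes) for j in range(M.shape[1])]
    out = {k: float(np.mean([d[k] for d in per_col])) for k in per_col[0]}
    if include_mace:
        out["mace"] = float(np.mean(
            [calibration_curve(M[:, j], outcomes)["mace"]
             for j in range(M.shape[1])]))
    return out


CALIBRATION_SPLINE_PENALTY = 1.0


def calibration_curve(risks: np.ndarray, outcomes: np.ndarray,
                      n_grid: int = 100) -> dict:
    """Smooth calibration curve and mean absolute calibration error.

    The curve is a logistic regression of the outcome on a penalized
    B-spline basis of logit(risk). The error is the mean absolute gap
    between the curve and the identity line over an equally-spaced grid
    spanning the central 99% of the predictions, weighted by the
    empirical density of the predictions (calibration where predictions
    are dense dominates; the sparse extreme tails, where calibration
    cannot be assessed reliably, are excluded).
    """
    risks = np.asarray(risks, float)
    outcomes = np.asarray(outcomes, float)
    if len(risks) < 100:
        raise EvaluationError("calibration needs at least 100 cases")
    _check_binary(outcomes)
    p_lo, p_hi = np.percentile(risks, [0.5, 99.5])
    if p_hi - p_lo < 1e-8:
        raise EvaluationError("predictions are near-constant; "
                              "calibration curve is degenerate")
    lp = logit(np.clip(risks, 1e-12, 1 - 1e-12))
    frame = pd.DataFrame({"lp": lp, "event": outcomes})
    spec = gam.GamSpec((gam.GamTermSpec("spline", ("lp",),
                                        penalty=CALIBRATION_SPLINE_PENALTY),),
                       outcome="event")
    fit = gam.fit_binomial_gam(frame, spec)
    grid = np.linspace(p_lo, p_hi, n_grid)
    grid_frame = pd.DataFrame({"lp": logit(np.clip(grid, 1e-12, 1 - 1e-12))})
    curve = expit(fit.linear_predictor(grid_frame))
    edges = np.concatenate([[grid[0] - (grid[1] - grid[0]) / 2],
                            (grid[1:] + grid[:-1]) / 2,
                            [grid[-1] + (grid[1] - grid[0]) / 2]])
    weights, _ = np.histogram(risks, bins=edges)
    weights = weights / max(weights.sum(), 1)
    mace = float(np.sum(weights * np.abs(curve - grid)))
    return {"grid": grid, "curve": curve, "mace": mace}


@dataclass
class ScoreReport:
    """Per-split scores with percentile summaries and paired differences."""

    per_split: pd.DataFrame          # columns: split, model, <scores>
    summary: pd.DataFrame            # index (model, metric): median/p2.5/p97.5
    differences: pd.DataFrame | None = None   # per split, model minus baseline
    diff_summary: pd.DataFrame | None = None
    rdr_strata: pd.DataFrame | None = None
    artifacts: list | None = None             # per-split fitted parameters

    def to_json(self) -> dict:
        out = {"summary": self.summary.reset_index().to_dict(orient="records")}
        if self.diff_summary is not None:
            out["diff_summary"] = (self.diff_summary.reset_index()
                                   .to_dict(orient="records"))
        if self.rdr_strata is not None:
            out["rdr_strata"] = self.rdr_strata.to_dict(orient="records")
        return out


def aggregate_cv(per_split: pd.DataFrame,
                 baseline_model: str | None = "baseline") -> ScoreReport:
    """Median and 2.5/97.5 percentile summaries per model and metric, plus
    within-split paired differences against the baseline model.

    Invariant to the order of the split rows.
    """
    if per_split["split"].nunique() < 2:
        warnings.warn("aggregating fewer than 2 splits; intervals are degenerate")
    metrics = [c for c in per_split.columns if c not in ("split", "model")]
    rows = []
    for model, grp in per_split.groupby("model"):
        for metric in metrics:
            vals = grp[metric].dropna().to_numpy(float)
            if vals.size == 0:
                continue
            med, lo, hi = np.percentile(vals, [50, 2.5, 97.5])
            rows.append({"model": model, "metric": metric, "median": med,
                         "p2.5": lo, "p97.5": hi})
    summary = pd.DataFrame(rows).set_index(["model", "metric"]).sort_index()
    differences = diff_summary = None
    models = sorted(per_split["model"].unique())
    if baseline_model in models and len(models) > 1:
        wide = per_split.set_index(["split", "model"])[metrics].sort_index()
        diff_rows = []
        for model in models:
            if model == baseline_model:
                continue
            d = (wide.xs(model, level="model")
                 - wide.xs(baseline_model, level="model"))
            d["model"] = model
            diff_rows.append(d.reset_index())
        differences = pd.concat(diff_rows, ignore_index=True)
        rows = []
        for model, grp in differences.groupby("model"):
            for metric in metrics:
                vals = grp[metric].dropna().to_numpy(float)
                if vals.size == 0:
                    continue
                med, lo, hi = np.percentile(vals, [50, 2.5, 97.5])
                rows.append({"model": model, "metric": metric, "median": med,
                             "p2.5": lo, "p97.5": hi})
        diff_summary = (pd.DataFrame(rows)
                        .set_index(["model", "metric"]).sort_index())
    return ScoreReport(per_split.sort_values(["split", "model"])
                       .reset_index(drop=True),
                       summary, differences, diff_summary)


# ---------------------------------------------------------------------------
# complete-case logistic baseline


@dataclass(frozen=True)
class BaselineConfig:
    """The refit complete-case logistic comparator.

    Stands in for the incumbent point-estimate calculator: cases with any
    missing covariate are discarded, continuous covariates enter with
    polynomial terms up to ``polynomial_degree``, and the model is refit
    on every development set.
    """

    variables: tuple[str, ...] | None = None   # None -> routine covariates
    polynomial_degree: int = 2

    def resolve_variables(self, specs: Mapping[str, VariableSpec],
                          columns) -> list[str]:
        if self.variables is not None:
            return [v for v in self.variables if v in columns]
        out = []
        for name, s in specs.items():
            if name == "died" or name in LAB_VARIABLES:
                continue
            if name.endswith("_missing"):
                continue
            if name in columns:
                out.append(name)
        return out


@dataclass
class FittedBaseline:
    config: BaselineConfig
    variables: list[str]
    model: object
    scaler: object
    specs: Mapping[str, VariableSpec]

    def _design(self, df: pd.DataFrame) -> np.ndarray:
        cols = []
        for name in self.variables:
            s = self.specs[name]
            if s.kind == "continuous":
                x = df[name].to_numpy(float)
                for d in range(1, self.config.polynomial_degree + 1):
                    cols.append(x ** d)
            else:
                cats = s.allowed_categories or ()
                base = s.base_category
                for c in cats:
                    cv = float(c) if s.kind in ("binary", "ordinal") else c
                    if cv == (float(base) if s.kind in ("binary", "ordinal")
                              else base):
                        continue
                    cols.append((df[name].to_numpy(object) == cv).astype(float))
        return np.column_stack(cols)

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        X = self.scaler.transform(self._design(df))
        return self.model.predict_proba(X)[:, 1]


def fit_baseline(train_df: pd.DataFrame, specs: Mapping[str, VariableSpec],
                 config: BaselineConfig = BaselineConfig()) -> FittedBaseline:
    """Fit the complete-case logistic baseline on development cases."""
    from sklearn.linear_model import LogisticRegression
    from sklearn.preprocessing import StandardScaler

    variables = config.resolve_variables(specs, train_df.columns)
    cc = train_df.dropna(subset=variables + ["died"])
    fb = FittedBaseline(config, variables, None, None, specs)
    X = fb._design(cc)
    scaler = StandardScaler().fit(X)
    clf = LogisticRegression(C=100.0, max_iter=2000)
    clf.fit(scaler.transform(X), cc["died"].to_numpy(float))
    fb.model, fb.scaler = clf, scaler
    return fb


# ---------------------------------------------------------------------------
# the full harness


def _lab_missingness_group(row) -> str:
    lac, alb = bool(row["lactate_missing"]), bool(row["albumin_missing"])
    if lac and alb:
        return "both"
    if lac:
        return "lactate_only"
    if alb:
        return "albumin_only"
    return "none"


def run_validation(cohort: Cohort, dist_config: ImputationConfig,
                   baseline_config: BaselineConfig, plan: SplitPlan,
                   gam_spec: gam.GamSpec | None = None,
                   compute_mace: bool = True,
                   return_artifacts: bool = False) -> ScoreReport:
    """Grouped repeated cross-validation of the distributional model
    against the complete-case baseline.

    Every split refits Winsor thresholds, imputation sub-models and the
    risk model on development cases only. Validation cases with a missing
    value among the baseline covariates are excluded from scoring for
    both models, so the two are compared on identical cases; lactate and
    albumin may still be missing there and are imputed prospectively.
    Also emits risk-distribution-range summaries stratified by which labs
    required imputation.
    """
    specs = cohort.specs
    plan_hosps = set().union(*[t | s for t, s in plan.splits])
    if not plan_hosps <= set(cohort.df["hospital_id"].astype(str)):
        raise SplitError("plan references hospitals absent from the cohort")
    score_rows, rdr_rows, artifacts = [], [], []
    for split_idx, (train_h, test_h) in enumerate(plan.splits):
        hosp = cohort.df["hospital_id"].astype(str)
        train_df = cohort.df[hosp.isin(train_h)].reset_index(drop=True)
        test_df = cohort.df[hosp.isin(test_h)].reset_index(drop=True)
        train = Cohort(train_df, specs, provenance="cv train")
        test = Cohort(test_df, specs, provenance="cv test")

        thresholds = fit_winsor_thresholds(train, specs)
        train = apply_winsor(add_missingness_indicators(train), thresholds)
        test = apply_winsor(add_missingness_indicators(test), thresholds)

        from dataclasses import replace as _replace
        split_cfg = _replace(dist_config,
                             seed=dist_config.seed + 1000 * (split_idx + 1))
        completed, lab_imputers = impute_cohort(train, split_cfg, thresholds)

        spec = gam_spec
        if spec is None:
            spec = gam.default_risk_terms(specs, [v for v in specs
                                                  if v != "died"])
        info = gam.fit_design_info(completed[0].df, spec, specs)
        fits = [gam.fit_binomial_gam(c.df, spec, info=info) for c in completed]
        pooled = gam.pool_fits(fits)

        if return_artifacts:
            artifacts.append({"split": split_idx,
                              "coef": pooled.coef.copy(),
                              "thresholds": thresholds.to_json()})
        baseline = fit_baseline(train.df, specs, baseline_config)
        # score both models on identical cases: complete for the baseline
        # covariates and for every routine input the distributional model
        # or its lab imputers need (only labs are imputed prospectively)
        required = set(baseline.variables) | {"died"}
        required |= {v for v in spec.variables if v not in LAB_VARIABLES}
        for imp in lab_imputers.values():
            required |= {v for v in imp.model.info.spec.variables
                         if v not in LAB_VARIABLES and v != "died"}
        eligible = test.df.dropna(
            subset=[c for c in required if c in test.df.columns]).copy()
        if len(eligible) == 0 or eligible["died"].nunique() < 2:
            warnings.warn(f"split {split_idx}: no usable validation cases; skipped")
            continue

        risks, _ = predict_matrix(eligible, pooled, lab_imputers, split_cfg,
                                  seed=np.random.default_rng(
                                      np.random.SeedSequence(
                                          [split_cfg.seed, 55, split_idx])))
        y = eligible["died"].to_numpy(float)
        dist_scores = score_distribution_model(risks, y, include_mace=compute_mace)
        base_p = baseline.predict(eligible)
        base_scores = score_predictions(base_p, y)
        if compute_mace:
            base_scores["mace"] = calibration_curve(base_p, y)["mace"]
        score_rows.append({"split": split_idx, "model": "distributional",
                           **dist_scores})
        score_rows.append({"split": split_idx, "model": "baseline",
                           **base_scores})

        p2_5, p97_5 = np.percentile(risks, [2.5, 97.5], axis=1)
        rdr = p97_5 - p2_5
        groups = eligible.apply(_lab_missingness_group, axis=1)
        for g in ("none", "albumin_only", "lactate_only", "both"):
            mask = (groups == g).to_numpy()
            if mask.any():
                med, lo, hi = np.percentile(rdr[mask], [50, 2.5, 97.5])
                rdr_rows.append({"split": split_idx, "group": g,
                                 "n": int(mask.sum()), "median_rdr": med,
                                 "p2.5": lo, "p97.5": hi})
    per_split = pd.DataFrame(score_rows)
    report = aggregate_cv(per_split, baseline_model="baseline")
    report.rdr_strata = pd.DataFrame(rdr_rows)
    if return_artifacts:
        report.artifacts = artifacts
    return report
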