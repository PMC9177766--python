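"""Variable transformations applied before imputation and model fitting.

Thresholds for Winsorization are fitted on development (training) cases
only and re-fitted in every cross-validation round; validation and
prospective inputs are clamped to the stored training thresholds, never
refit. Percentiles use linear interpolation between order statistics
throughout the package.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import FitError
from .schema import Cohort, VariableSpec

__all__ = [
    "WinsorThresholds",
    "fit_winsor_thresholds",
    "apply_winsor",
    "binarize_ecg",
    "consolidate_indication",
    "add_missingness_indicators",
    "redact_implausible",
    "DEFAULT_ECG_MAP",
]

WINSOR_LOWER_PCT = 0.1
WINSOR_UPPER_PCT = 99.9


@dataclass
class WinsorThresholds:
    """Per-variable clamp values; a side may be inactive (None).

    Age clamps the upper tail only.
    """

    lower: dict[str, float | None] = field(default_factory=dict)
    upper: dict[str, float | None] = field(default_factory=dict)

    def clamp(self, name: str, values: np.ndarray) -> np.ndarray:
        lo = self.lower.get(name)
        hi = self.upper.get(name)
        out = np.asarray(values, float).copy()
        obs = ~np.isnan(out)
        if lo is not None:
            out[obs] = np.maximum(out[obs], lo)
        if hi is not None:
            out[obs] = np.minimum(out[obs], hi)
        return out

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps({"lower": self.lower, "upper": self.upper}, indent=1)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "WinsorThresholds":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        data = json.loads(text)
        return cls(lower=dict(data["lower"]), upper=dict(data["upper"]))


def fit_winsor_thresholds(train: Cohort,
                          specs: Mapping[str, VariableSpec] | None = None,
                          ) -> WinsorThresholds:
    """Fit 0.1/99.9 percentile clamps on training values of each continuous
    variable; variables with the lower side disabled get an upper clamp only.
    """
    specs = specs or train.specs
    thr = WinsorThresholds()
    for name, spec in specs.items():
        if spec.kind != "continuous" or name not in train.df.columns:
            continue
        values = train.df[name].dropna().to_numpy(float)
        if values.size == 0:
            raise FitError(f"cannot fit Winsor thresholds: {name!r} has no "
                           "non-missing training values")
        if values.size < 1000:
            warnings.warn(f"fewer than 1000 non-missing training values for "
                          f"{name!r}; Winsor thresholds may be unstable")
        lo, hi = np.percentile(values, [WINSOR_LOWER_PCT, WINSOR_UPPER_PCT],
                               method="linear")
        thr.lower[name] = float(lo) if spec.winsor_lower_enabled else None
        thr.upper[name] = float(hi)
    return thr


def apply_winsor(cohort: Cohort, thresholds: WinsorThresholds) -> Cohort:
    """Clamp every non-missing continuous value into its training thresholds.

    Missing markers pass through untouched; idempotent.
    """
    out = cohort.copy()
    for name in thresholds.upper:
        if name in out.df.columns:
            out.df[name] = thresholds.clamp(name, out.df[name].to_numpy(float))
    return out


#: Raw ECG category -> presence of any arrhythmia.
DEFAULT_ECG_MAP: dict[str, int] = {
    "sinus_rhythm": 0,
    "no_abnormality": 0,
    "af_rate_60_90": 1,
    "af_rate_over_90": 1,
    "other_arrhythmia": 1,
}


def binarize_ecg(raw_ecg, ecg_map: Mapping[str, int] = DEFAULT_ECG_MAP):
    """Rationalise the raw ECG category to a binary any-arrhythmia flag.

    Missing propagates; an unknown category raises ``ValueError``.
    Accepts a scalar or a pandas Series.
    """
    if isinstance(raw_ecg, pd.Series):
        return raw_ecg.map(lambda v: binarize_ecg(v, ecg_map))
    if pd.isna(raw_ecg):
        return np.nan
    try:
        return float(ecg_map[raw_ecg])
    except KeyError:
        raise ValueError(f"unknown ECG category {raw_ecg!r}") from None


def consolidate_indication(raw_indications: Iterable[str] | None,
                           top13: tuple[str, ...]):
    """Collapse a raw indication set to one of the 13 commonest indications,
    "other", or missing.

    A single raw indication maps to itself if among the top 13 and to
    "other" otherwise. An empty set — and, by this package's convention,
    multiple simultaneous indications — maps to missing (to be imputed).
    """
    if len(top13) != 13:
        raise ValueError(f"top13 must have exactly 13 entries, got {len(top13)}")
    if raw_indications is None:
        return np.nan
    items = [x for x in raw_indications if not pd.isna(x)]
    if len(items) != 1:
        return np.nan
    return items[0] if items[0] in top13 else "other"


def add_missingness_indicators(cohort: Cohort,
                               variables: tuple[str, ...] = ("lactate", "albumin"),
                               ) -> Cohort:
    """Set ``<var>_missing`` to 1 iff the value is absent, before imputation.

    The indicators themselves are never missing and become model covariates,
    testing the hypothesis that being measured at all carries information.
    """
    out = cohort.copy()
    for name in variables:
        out.df[f"{name}_missing"] = cohort.df[name].isna().astype(float)
    return out


def redact_implausible(cohort: Cohort) -> tuple[Cohort, dict[str, int]]:
    """Set values outside each variable's plausible physiologic range to
    missing; returns the redaction counts per variable."""
    out = cohort.copy()
    counts: dict[str, int] = {}
    for name, spec in cohort.specs.items():
        if spec.plausible_range is None or name not in out.df.columns:
            continue
        lo, hi = spec.plausible_range
        col = out.df[name].to_numpy(float)
        bad = (~np.isnan(col)) & ((col < lo) | (col > hi))
        if bad.any():
            counts[name] = int(bad.sum())
            col[bad] = np.nan
            out.df[name] = col
    return out, counts
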