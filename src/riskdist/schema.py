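"""Case-level data model: variable specifications, cohorts, eligibility rules.

A cohort is one row per surgical case (demographics, physiology, labs,
operative findings, a binary in-hospital mortality outcome and a hospital
identifier), held in a :class:`pandas.DataFrame` with per-variable typing
driven by :class:`VariableSpec`. Missing values use a single sentinel
(``NaN``), serialized as an empty CSV cell so that read/write round-trips
exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import IntegrityError, SchemaError

__all__ = [
    "VariableSpec",
    "Cohort",
    "ParseReport",
    "ExclusionReport",
    "RESERVED_COLUMNS",
    "AGE_MIN",
    "AGE_MAX",
    "default_variable_specs",
    "read_cohort",
    "write_cohort",
    "apply_exclusions",
    "resolve_outcome",
    "specs_to_json",
    "specs_from_json",
]

#: Columns every cohort frame carries in addition to modelled variables.
RESERVED_COLUMNS = ("case_id", "hospital_id")

#: Inclusive eligibility bounds on age in years.
AGE_MIN = 18
AGE_MAX = 109

VALID_KINDS = ("continuous", "binary", "ordinal", "nominal")


@dataclass(frozen=True)
class VariableSpec:
    """Typing and validation rules for one covariate.

    Parameters
    ----------
    name
        Column name in the cohort frame.
    kind
        One of ``continuous``, ``binary``, ``ordinal``, ``nominal``.
    unit
        Free-text unit, e.g. ``"mmol L-1"``; empty for unitless variables.
    allowed_categories
        Ordered category list for nominal/ordinal variables. ``None`` means
        the variable accepts any level (used for raw, pre-consolidation data).
    base_category
        Level excluded from dummy encoding (the dummy-variable-trap rule).
    winsor_lower_enabled
        Whether the lower tail is clamped during Winsorization. Age clamps
        the upper tail only.
    plausible_range
        ``(min, max)`` physiologic limits; values outside are redacted to
        missing during preprocessing. ``None`` disables the check.
    """

    name: str
    kind: str
    unit: str = ""
    allowed_categories: tuple | None = None
    base_category: object | None = None
    winsor_lower_enabled: bool = True
    plausible_range: tuple[float, float] | None = None

    def __post_init__(self):
        if self.kind not in VALID_KINDS:
            raise SchemaError(f"unknown variable kind {self.kind!r} for {self.name!r}")
        if self.allowed_categories is not None:
            object.__setattr__(self, "allowed_categories", tuple(self.allowed_categories))
            if self.base_category is not None and self.base_category not in self.allowed_categories:
                raise SchemaError(
                    f"{self.name!r}: base category {self.base_category!r} "
                    "not among allowed categories"
                )
        if self.plausible_range is not None:
            lo, hi = self.plausible_range
            if not lo < hi:
                raise SchemaError(f"{self.name!r}: plausible_range min must be < max")

    @property
    def is_numeric(self) -> bool:
        return self.kind in ("continuous", "binary", "ordinal")


#: Surgical indications retained after consolidation (13 + "other").
INDICATION_CATEGORIES = (
    "small_bowel_obstruction",
    "large_bowel_obstruction",
    "perforation",
    "peritonitis",
    "ischaemia",
    "sepsis_other",
    "haemorrhage",
    "anastomotic_leak",
    "abdominal_abscess",
    "colitis",
    "incarcerated_hernia",
    "volvulus",
    "intestinal_fistula",
    "other",
)

SOILING_CATEGORIES = ("none", "serous_fluid", "localised_pus", "free_pus_blood_faeces")
MALIGNANCY_CATEGORIES = ("none", "primary_only", "nodal_metastases", "distant_metastases")


def default_variable_specs() -> dict[str, VariableSpec]:
    """Specs for the study's covariate set, in Table-1 units.

    Creatinine and blood urea nitrogen are stored in mg/dL; no unit
    auto-conversion is performed.
    """
    ordinal = lambda name, lo, hi, base, **kw: VariableSpec(  # noqa: E731
        name, "ordinal",
        allowed_categories=tuple(range(lo, hi + 1)), base_category=base, **kw)
    specs = [
        VariableSpec("age", "continuous", "years", winsor_lower_enabled=False,
                     plausible_range=(0, 130)),
        ordinal("asa", 1, 5, 1),
        ordinal("cardio_status", 0, 3, 0),
        ordinal("resp_status", 0, 3, 0),
        VariableSpec("heart_rate", "continuous", "beats min-1", plausible_range=(10, 300)),
        VariableSpec("arrhythmia", "binary", allowed_categories=(0, 1), base_category=0),
        VariableSpec("systolic_bp", "continuous", "mmHg", plausible_range=(30, 300)),
        VariableSpec("sodium", "continuous", "mmol L-1", plausible_range=(90, 190)),
        VariableSpec("potassium", "continuous", "mmol L-1", plausible_range=(1.0, 10.0)),
        VariableSpec("wcc", "continuous", "1e9 L-1", plausible_range=(0.0, 100.0)),
        VariableSpec("creatinine", "continuous", "mg/dL", plausible_range=(0.05, 25.0)),
        VariableSpec("bun", "continuous", "mg/dL", plausible_range=(0.5, 250.0)),
        VariableSpec("lactate", "continuous", "mmol L-1", plausible_range=(0.1, 30.0)),
        VariableSpec("albumin", "continuous", "g L-1", plausible_range=(5.0, 70.0)),
        VariableSpec("gcs", "continuous", plausible_range=(3, 15)),
        VariableSpec("ct_performed", "binary", allowed_categories=(0, 1), base_category=0),
        VariableSpec("soiling", "nominal", allowed_categories=SOILING_CATEGORIES,
                     base_category="none"),
        VariableSpec("malignancy", "nominal", allowed_categories=MALIGNANCY_CATEGORIES,
                     base_category="none"),
        VariableSpec("indication", "nominal", allowed_categories=INDICATION_CATEGORIES,
                     base_category="small_bowel_obstruction"),
        VariableSpec("lactate_missing", "binary", allowed_categories=(0, 1), base_category=0),
        VariableSpec("albumin_missing", "binary", allowed_categories=(0, 1), base_category=0),
        VariableSpec("died", "binary", allowed_categories=(0, 1), base_category=0),
    ]
    return {s.name: s for s in specs}


@dataclass
class ParseReport:
    """Counts of cells coerced to missing while reading a cohort file."""

    n_rows: int = 0
    coerced_cells: dict[str, int] = field(default_factory=dict)

    @property
    def n_coerced(self) -> int:
        return sum(self.coerced_cells.values())


@dataclass
class Cohort:
    """An ordered collection of cases plus their variable specs.

    ``df`` holds one row per case; numeric variables are float64 with NaN
    as the missing marker, nominal variables are object-dtype strings.
    """

    df: pd.DataFrame
    specs: Mapping[str, VariableSpec]
    provenance: str = ""
    parse_report: ParseReport | None = None

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for col in RESERVED_COLUMNS:
            if col not in self.df.columns:
                raise SchemaError(f"cohort frame lacks required column {col!r}")
        if self.df["case_id"].duplicated().any():
            dup = self.df["case_id"][self.df["case_id"].duplicated()].iloc[0]
            raise IntegrityError(f"duplicate case_id {dup!r}")
        if self.df["hospital_id"].isna().any():
            raise IntegrityError("hospital_id is missing for at least one case")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def variables(self) -> list[str]:
        return [name for name in self.specs if name in self.df.columns]

    def copy(self) -> "Cohort":
        return Cohort(self.df.copy(), dict(self.specs), self.provenance, self.parse_report)

    def missing_fraction(self, name: str) -> float:
        return float(self.df[name].isna().mean())


def _coerce_column(raw: pd.Series, spec: VariableSpec) -> tuple[pd.Series, int]:
    """Type one raw string column; return (typed series, n coerced cells)."""
    stripped = raw.astype("string").str.strip()
    blank = stripped.isna() | (stripped == "")
    if spec.is_numeric:
        typed = pd.to_numeric(stripped.mask(blank), errors="coerce").astype(float)
        coerced = int((typed.isna() & ~blank).sum())
        return typed, coerced
    typed = stripped.mask(blank).astype(object)
    if spec.allowed_categories is not None:
        allowed = set(map(str, spec.allowed_categories))
        bad = typed.notna() & ~typed.isin(allowed)
        return typed.mask(bad), int(bad.sum())
    return typed, 0


def read_cohort(path: str | Path, specs: Mapping[str, VariableSpec]) -> Cohort:
    """Read a cohort CSV (RFC-4180, header row, empty cell = missing).

    Unparseable cells become missing and are counted per column in the
    returned cohort's ``parse_report``. A modelled column absent from the
    file raises :class:`SchemaError` naming it.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    for col in RESERVED_COLUMNS:
        if col not in raw.columns:
            raise SchemaError(f"{path.name}: missing required column {col!r}")
    report = ParseReport(n_rows=len(raw))
    out = pd.DataFrame(index=raw.index)
    out["case_id"] = raw["case_id"].astype(str)
    out["hospital_id"] = raw["hospital_id"].astype(str)
    for name, spec in specs.items():
        if name not in raw.columns:
            raise SchemaError(f"{path.name}: missing required column {name!r}")
        typed, n_coerced = _coerce_column(raw[name], spec)
        out[name] = typed
        if n_coerced:
            report.coerced_cells[name] = n_coerced
    return Cohort(out, dict(specs), provenance=f"read from {path.name}", parse_report=report)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort as CSV; missing values become empty cells."""
    df = cohort.df.copy()
    for name, spec in cohort.specs.items():
        if name not in df.columns or not spec.is_numeric:
            continue
        # Integral values print without a trailing ".0" so ordinals/binaries
        # round-trip to the same literal.
        col = df[name]
        as_int = col.dropna().pipe(lambda s: (s == s.round()).all())
        if as_int and len(col.dropna()):
            df[name] = col.map(lambda v: "" if pd.isna(v) else
                               (str(int(v)) if v == round(v) else repr(v)))
    df.to_csv(path, index=False, na_rep="")


@dataclass
class ExclusionReport:
    """Counts per eligibility-exclusion reason; retained + excluded = input."""

    n_input: int
    n_retained: int
    reasons: dict[str, int] = field(default_factory=dict)

    @property
    def n_excluded(self) -> int:
        return sum(self.reasons.values())


def apply_exclusions(cohort: Cohort) -> tuple[Cohort, ExclusionReport]:
    """Apply the study eligibility rule: retain cases with 18 <= age <= 109.

    Bounds are inclusive ("below 18 or above 109" are excluded). Age must be
    non-missing for every case. Idempotent.
    """
    age = cohort.df["age"]
    if age.isna().any():
        raise SchemaError("age must be non-missing before applying exclusions")
    under = age < AGE_MIN
    over = age > AGE_MAX
    keep = ~(under | over)
    report = ExclusionReport(
        n_input=len(cohort),
        n_retained=int(keep.sum()),
        reasons={"age_under_18": int(under.sum()), "age_over_109": int(over.sum())},
    )
    retained = Cohort(cohort.df.loc[keep].reset_index(drop=True),
                      dict(cohort.specs), cohort.provenance, cohort.parse_report)
    return retained, report


#: Raw end-of-follow-up status tokens.
OUTCOME_STATUSES = ("died", "discharged_alive", "in_hospital_day60")


def resolve_outcome(raw_status: str) -> int:
    """Map an end-of-follow-up status to the binary in-hospital death outcome.

    Death in hospital before day 60 is the event; patients still in hospital
    on day 60 are treated as discharged alive.
    """
    mapping = {"died": 1, "discharged_alive": 0, "in_hospital_day60": 0}
    try:
        return mapping[raw_status]
    except KeyError:
        raise ValueError(f"unknown outcome status {raw_status!r}; "
                         f"expected one of {OUTCOME_STATUSES}") from None


def specs_to_json(specs: Mapping[str, VariableSpec], path: str | Path | None = None) -> str:
    payload = json.dumps({name: asdict(s) for name, s in specs.items()}, indent=1)
    if path is not None:
        Path(path).write_text(payload)
    return payload


def specs_from_json(source: str | Path) -> dict[str, VariableSpec]:
    text = Path(source).read_text() if Path(str(source)).exists() else str(source)
    data = json.loads(text)
    out = {}
    for name, kw in data.items():
        if kw.get("allowed_categories") is not None:
            kw["allowed_categories"] = tuple(kw["allowed_categories"])
        if kw.get("plausible_range") is not None:
            kw["plausible_range"] = tuple(kw["plausible_range"])
        out[name] = VariableSpec(**kw)
    return out
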