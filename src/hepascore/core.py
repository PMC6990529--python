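"""Preoperative mortality risk scores for liver resection, with validation statistics.

This module implements, in the order a study runs them:

1.  **Score calculators** — the Heidelberg Mortality Risk Score (an additive
    8-component point score, 0-16 points, stratified into risk groups
    1/2A/2B/3A/3B/4), the labMELD score (logarithmic formula over creatinine,
    bilirubin and INR with floor/cap rules, integer 6-40) and the P-POSSUM
    system (12 physiological + 6 operative items graded 1/2/4/8, combined by a
    published logistic equation into a predicted in-patient mortality).
2.  **Cohort statistics** — stratified 90-day mortality tables with odds
    ratios (cross-product estimator, Woolf confidence intervals, Wald
    p-values), Fisher's exact test, the Mann-Whitney U test, maximum-likelihood
    logistic regression, ROC curves, the C-index, and paired ROC/AUC
    comparison (DeLong).
3.  **Synthetic cohort generation** — a seeded generator emulating the case
    mix of a 529-patient hepatectomy cohort (covariate prevalences, risk-group
    death rates), plus deterministic reconstruction of the published stratum
    count tables.
4.  **Pipeline I/O** — CSV schema, batch scoring with an explicit rejects
    channel, and report rendering (stratum tables, AUC comparison table,
    per-group descriptive table, ROC operating points).

The outcome throughout is binary 90-day all-cause mortality.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

__all__ = [
    # errors
    "HepascoreError", "DomainError", "MissingDataError", "SchemaError",
    "CohortSpecError", "StatisticsError",
    # scores
    "ClinicalRecord", "RiskScoreResult", "PossumInput", "PossumResult",
    "mortality_risk_points", "risk_group", "labmeld", "labmeld_value",
    "grade_physiology", "grade_operative",
    "possum_physiological_score", "possum_operative_score", "ppossum_mortality",
    "possum_result", "MannWhitneyResult",
    "POSSUM_BAND_TABLE_VERSION", "PHYSIOLOGY_ITEMS", "OPERATIVE_ITEMS",
    # cohort statistics
    "Contingency2x2", "OddsRatioResult", "StratumRow", "RocResult",
    "LogisticFit", "ScoreComparison", "StratifierScheme", "Stratum",
    "odds_ratio", "fisher_exact", "mann_whitney_u", "fit_logistic",
    "c_index", "roc_curve", "compare_scores", "stratified_mortality_table",
    "RISK_SCORE_SCHEME", "LABMELD_SCHEME",
    # synthetic cohorts
    "CohortSpec", "generate_cohort", "reconstruct_printed_cohort",
    "cohort_records", "load_cohort_spec",
    # pipeline
    "SCHEMA_COLUMNS", "read_cohort_csv", "write_cohort_csv", "score_cohort",
    "run_simulate", "run_score", "run_validate", "run_compare_roc",
]

__version__ = "0.1.0"

log = logging.getLogger("hepascore")

# --------------------------------------------------------------------------
# Configuration constants
# --------------------------------------------------------------------------

#: labMELD coefficients: 10*(c1*ln(creatinine) + c2*ln(bilirubin) + c3*ln(INR) + c0)
LABMELD_COEF = {"creatinine": 0.957, "bilirubin": 0.378, "inr": 1.120, "const": 0.643}
LABMELD_CREATININE_CAP = 4.0
LABMELD_COMPONENT_FLOOR = 1.0
LABMELD_MIN, LABMELD_MAX = 6, 40

#: P-POSSUM in-patient mortality equation (Portsmouth modification):
#: ln(R/(1-R)) = -9.065 + 0.1692*PS + 0.1550*OS
PPOSSUM_INTERCEPT = -9.065
PPOSSUM_PS_COEF = 0.1692
PPOSSUM_OS_COEF = 0.1550

Z_95 = 1.959963984540054  # two-sided 95% normal quantile

#: CLI / pipeline exit codes (0 = success).
EXIT_SCHEMA_ERROR = 2
EXIT_VALIDATION_ERROR = 3
EXIT_STATISTICS_ERROR = 4


def _configure_logging(verbosity: int = 0, logfile: Path | None = None) -> None:
    """Structured logging to stderr and optionally a run-log file."""
    level = logging.WARNING - 10 * min(verbosity, 2)
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    fmt = logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    log.setLevel(level)
    for h in handlers:
        h.setFormatter(fmt)
        log.addHandler(h)


# --------------------------------------------------------------------------
# Errors
# --------------------------------------------------------------------------

class HepascoreError(Exception):
    """Base class for all package errors."""


class DomainError(HepascoreError, ValueError):
    """A value is outside the domain a calculator is defined on."""


class MissingDataError(DomainError):
    """A scored field is absent.  Scores are never silently imputed."""

    def __init__(self, fieldname: str):
        self.fieldname = fieldname
        super().__init__(f"{fieldname} missing")


class SchemaError(HepascoreError, ValueError):
    """An input table does not conform to the cohort CSV schema."""


class CohortSpecError(HepascoreError, ValueError):
    """A synthetic cohort specification is internally inconsistent."""


class StatisticsError(HepascoreError, ValueError):
    """A statistical routine received a degenerate input."""


# ==========================================================================
# SECTION 1 — score calculators
# ==========================================================================

DIAGNOSES = ("intrahepatic_cc", "perihilar_cc", "other")
SEXES = ("male", "female")

_DIAGNOSIS_POINTS = {"intrahepatic_cc": 1, "perihilar_cc": 2, "other": 0}
_ASA_POINTS = {1: 0, 2: 0, 3: 1, 4: 5}

_GROUP_DESCRIPTION = {
    "1": "very low-risk", "2A": "low-risk", "2B": "low-risk",
    "3A": "medium-risk", "3B": "medium-risk", "4": "high-risk",
}
GROUP_ORDER = ("1", "2A", "2B", "3A", "3B", "4")


@dataclass(frozen=True)
class ClinicalRecord:
    """One patient's preoperative covariates and 90-day outcome.

    ``death_90d`` may be ``None`` when the record is scored prospectively.
    POSSUM item grades, when available, travel separately in a
    :class:`PossumInput`.
    """

    age_years: float
    sex: str
    asa_class: int
    diagnosis: str
    right_trisectionectomy: bool
    inr: float
    ggt_u_per_l: float
    platelets_per_nl: float
    creatinine_mg_dl: float
    bilirubin_mg_dl: float
    on_dialysis: bool = False
    death_90d: bool | None = None
    possum: "PossumInput | None" = None

    def __post_init__(self):
        if self.sex is not None and self.sex not in SEXES:
            raise DomainError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.diagnosis is not None and self.diagnosis not in DIAGNOSES:
            raise DomainError(
                f"diagnosis must be one of {DIAGNOSES}, got {self.diagnosis!r}")


@dataclass(frozen=True)
class RiskScoreResult:
    """Mortality Risk Score points with their component breakdown and group."""

    points: int
    components: Mapping[str, int]
    group: str
    group_description: str


def risk_group(points: int) -> str:
    """Map Mortality Risk Score points to the risk group label.

    0-1 point → group 1 (very low-risk); 2 → 2A and 3 → 2B (low-risk);
    4 → 3A and 5 → 3B (medium-risk); ≥6 → 4 (high-risk).
    """
    if isinstance(points, bool) or not isinstance(points, (int, np.integer)):
        raise DomainError(f"points must be an integer, got {points!r}")
    if points < 0 or points > 16:
        raise DomainError(f"points must be in [0, 16], got {points}")
    if points <= 1:
        return "1"
    return {2: "2A", 3: "2B", 4: "3A", 5: "3B"}.get(int(points), "4")


_SCORED_FIELDS = (
    "age_years", "asa_class", "diagnosis", "right_trisectionectomy",
    "inr", "ggt_u_per_l", "platelets_per_nl", "creatinine_mg_dl",
)


def mortality_risk_points(record: ClinicalRecord) -> RiskScoreResult:
    """Compute the 8-component Mortality Risk Score for one patient.

    Point awards (thresholds inclusive exactly as published): age ≥ 60 y → 1;
    right trisectionectomy → 1; INR ≥ 1.1 → 1; GGT ≥ 60 U/l → 1;
    platelets < 120/nl → 2; creatinine ≥ 2 mg/dl → 3; diagnosis
    intrahepatic cholangiocarcinoma → 1, perihilar cholangiocarcinoma → 2,
    other → 0; ASA III → 1, ASA IV → 5, ASA I/II → 0.

    Raises
    ------
    MissingDataError
        if any scored field is ``None`` (no imputation, ever).
    DomainError
        if ``asa_class`` is outside 1-4 (ASA V is not covered by the score).
    """
    for name in _SCORED_FIELDS:
        if getattr(record, name) is None:
            raise MissingDataError(name)
    asa = record.asa_class
    if isinstance(asa, bool) or int(asa) != asa or int(asa) not in _ASA_POINTS:
        raise DomainError(f"asa_class must be an integer in 1-4, got {asa!r}")
    components = {
        "age": 1 if record.age_years >= 60 else 0,
        "right_trisectionectomy": 1 if record.right_trisectionectomy else 0,
        "inr": 1 if record.inr >= 1.1 else 0,
        "ggt": 1 if record.ggt_u_per_l >= 60 else 0,
        "platelets": 2 if record.platelets_per_nl < 120 else 0,
        "creatinine": 3 if record.creatinine_mg_dl >= 2 else 0,
        "diagnosis": _DIAGNOSIS_POINTS[record.diagnosis],
        "asa": _ASA_POINTS[int(asa)],
    }
    points = sum(components.values())
    group = risk_group(points)
    return RiskScoreResult(points, components, group, _GROUP_DESCRIPTION[group])


def labmeld_value(creatinine_mg_dl: float, bilirubin_mg_dl: float, inr: float,
                  on_dialysis: bool = False) -> float:
    """The unrounded labMELD value after the cap/floor rules.

    10·(0.957·ln creatinine + 0.378·ln bilirubin + 1.120·ln INR + 0.643),
    with serum creatinine capped at 4 mg/dl (and set to 4 mg/dl for patients
    dialysed at least twice in the previous week) and every component floored
    at 1 before the logarithm.
    """
    for name, v in (("creatinine_mg_dl", creatinine_mg_dl),
                    ("bilirubin_mg_dl", bilirubin_mg_dl), ("inr", inr)):
        if v is None:
            raise MissingDataError(name)
        if not math.isfinite(v) or v <= 0:
            raise DomainError(f"{name} must be a positive finite number, got {v!r}")
    cre = LABMELD_CREATININE_CAP if on_dialysis else min(creatinine_mg_dl,
                                                         LABMELD_CREATININE_CAP)
    cre = max(cre, LABMELD_COMPONENT_FLOOR)
    bil = max(bilirubin_mg_dl, LABMELD_COMPONENT_FLOOR)
    i = max(inr, LABMELD_COMPONENT_FLOOR)
    return 10.0 * (LABMELD_COEF["creatinine"] * math.log(cre)
                   + LABMELD_COEF["bilirubin"] * math.log(bil)
                   + LABMELD_COEF["inr"] * math.log(i)
                   + LABMELD_COEF["const"])


def labmeld(creatinine_mg_dl: float, bilirubin_mg_dl: float, inr: float,
            on_dialysis: bool = False) -> int:
    """Compute the labMELD score (integer, 6-40).

    The unrounded value (see :func:`labmeld_value`) is rounded to the nearest
    integer — half away from zero, i.e. half-up for these positive values,
    the UNOS convention — then clamped to [6, 40].
    """
    value = labmeld_value(creatinine_mg_dl, bilirubin_mg_dl, inr, on_dialysis)
    rounded = math.floor(value + 0.5)  # round half-up
    return int(min(max(rounded, LABMELD_MIN), LABMELD_MAX))


# ---- POSSUM item grading (Copeland banding tables) -----------------------

POSSUM_BAND_TABLE_VERSION = "copeland-1991"

PHYSIOLOGY_ITEMS = (
    "age", "cardiac", "respiratory", "systolic_bp", "pulse", "gcs",
    "hemoglobin", "wbc", "urea", "sodium", "potassium", "ecg",
)
OPERATIVE_ITEMS = (
    "severity", "multiple_procedures", "blood_loss", "soiling",
    "malignancy", "mode",
)
VALID_GRADES = (1, 2, 4, 8)


@dataclass(frozen=True)
class _NumericBands:
    """Banding of a continuous measurement into POSSUM grades.

    Raw values are rounded to ``resolution`` (the precision the original
    banding table is printed at) so that the printed bands tile the
    plausibility interval exactly.  Band bounds are inclusive, in units of
    ``resolution``.
    """

    unit: str
    resolution: float
    bands: tuple[tuple[int, int, int], ...]  # (lo, hi, grade) scaled by 1/resolution

    def grade(self, item: str, value: float) -> int:
        if not isinstance(value, (int, float, np.integer, np.floating)) \
                or not math.isfinite(value):
            raise DomainError(f"{item}: expected a finite number, got {value!r}")
        v = round(value / self.resolution)
        for lo, hi, g in self.bands:
            if lo <= v <= hi:
                return g
        lo_all = min(b[0] for b in self.bands) * self.resolution
        hi_all = max(b[1] for b in self.bands) * self.resolution
        raise DomainError(
            f"{item}: value {value} {self.unit} outside plausible range "
            f"[{lo_all}, {hi_all}] of the {POSSUM_BAND_TABLE_VERSION} band table")


@dataclass(frozen=True)
class _CategoricalBands:
    categories: Mapping[str, int]

    def grade(self, item: str, value) -> int:
        if isinstance(value, (int, np.integer)) and not isinstance(value, bool) \
                and int(value) in VALID_GRADES:
            return int(value)  # pre-graded
        if value not in self.categories:
            raise DomainError(
                f"{item}: {value!r} is not a recognised category "
                f"(one of {sorted(self.categories)}) or grade in {VALID_GRADES}")
        return self.categories[value]


# Transcription of the original POSSUM banding tables (Copeland 1991).
PHYSIOLOGY_BANDS: Mapping[str, _NumericBands | _CategoricalBands] = {
    "age": _NumericBands("years", 1.0, ((18, 60, 1), (61, 70, 2), (71, 110, 4))),
    "cardiac": _CategoricalBands({
        "no_failure": 1,
        "cardiac_medication": 2,          # diuretic/digoxin/antianginal/antihypertensive
        "oedema_or_warfarin": 4,          # peripheral oedema, warfarin, borderline cardiomegaly
        "jvp_or_cardiomegaly": 8,         # raised JVP, frank cardiomegaly
    }),
    "respiratory": _CategoricalBands({
        "no_dyspnoea": 1,
        "exertional_dyspnoea": 2,         # or mild COAD
        "limiting_dyspnoea": 4,           # one flight of stairs; moderate COAD
        "dyspnoea_at_rest": 8,            # rate ≥ 30/min; fibrosis or consolidation
    }),
    "systolic_bp": _NumericBands("mmHg", 1.0, (
        (110, 130, 1), (131, 170, 2), (100, 109, 2),
        (171, 300, 4), (90, 99, 4), (40, 89, 8))),
    "pulse": _NumericBands("bpm", 1.0, (
        (50, 80, 1), (81, 100, 2), (40, 49, 2),
        (101, 120, 4), (121, 250, 8), (20, 39, 8))),
    "gcs": _NumericBands("points", 1.0, (
        (15, 15, 1), (12, 14, 2), (9, 11, 4), (3, 8, 8))),
    "hemoglobin": _NumericBands("g/dl", 0.1, (
        (130, 160, 1), (115, 129, 2), (161, 170, 2),
        (100, 114, 4), (171, 180, 4), (30, 99, 8), (181, 250, 8))),
    "wbc": _NumericBands("10^9/l", 0.1, (
        (40, 100, 1), (101, 200, 2), (31, 39, 2),
        (201, 1000, 4), (5, 30, 4))),
    "urea": _NumericBands("mmol/l", 0.1, (
        (5, 75, 1), (76, 100, 2), (101, 150, 4), (151, 800, 8))),
    "sodium": _NumericBands("mmol/l", 1.0, (
        (136, 180, 1), (131, 135, 2), (126, 130, 4), (100, 125, 8))),
    "potassium": _NumericBands("mmol/l", 0.1, (
        (35, 50, 1), (32, 34, 2), (51, 53, 2),
        (29, 31, 4), (54, 59, 4), (10, 28, 8), (60, 100, 8))),
    "ecg": _CategoricalBands({
        "normal": 1,
        "af_rate_60_90": 4,               # atrial fibrillation, rate 60-90
        "other_abnormal": 8,              # any other rhythm, ≥5 ectopics/min, Q or ST/T changes
    }),
}

OPERATIVE_BANDS: Mapping[str, _NumericBands | _CategoricalBands] = {
    "severity": _CategoricalBands({
        "minor": 1, "moderate": 2, "major": 4, "major_plus": 8}),
    "multiple_procedures": _CategoricalBands({"one": 1, "two": 4, "more_than_two": 8}),
    "blood_loss": _NumericBands("ml", 1.0, (
        (0, 100, 1), (101, 500, 2), (501, 999, 4), (1000, 20000, 8))),
    "soiling": _CategoricalBands({
        "none": 1, "serous": 2, "local_pus": 4, "free_pus_blood_or_bowel": 8}),
    "malignancy": _CategoricalBands({
        "none": 1, "primary_only": 2, "nodal_metastases": 4,
        "distant_metastases": 8}),
    "mode": _CategoricalBands({
        "elective": 1, "emergency_resuscitation": 4, "emergency_immediate": 8}),
}


def grade_physiology(raw: Mapping[str, object]) -> dict[str, int]:
    """Grade the 12 raw physiological measurements into POSSUM items (1/2/4/8).

    ``raw`` maps each of :data:`PHYSIOLOGY_ITEMS` to a measurement — numeric
    for the continuous items, a category name (or a pre-assigned grade) for
    cardiac/respiratory history and ECG.  Missing items are an error: the
    caller must either supply every raw item or pass pre-graded items to the
    score functions directly.
    """
    grades: dict[str, int] = {}
    for item in PHYSIOLOGY_ITEMS:
        if item not in raw or raw[item] is None:
            raise MissingDataError(item)
        grades[item] = PHYSIOLOGY_BANDS[item].grade(item, raw[item])
    return grades


def grade_operative(raw: Mapping[str, object]) -> dict[str, int]:
    """Grade the 6 raw operative descriptors into POSSUM items (1/2/4/8)."""
    grades: dict[str, int] = {}
    for item in OPERATIVE_ITEMS:
        if item not in raw or raw[item] is None:
            raise MissingDataError(item)
        grades[item] = OPERATIVE_BANDS[item].grade(item, raw[item])
    return grades


def _check_grades(items, names: tuple[str, ...], what: str) -> dict[str, int]:
    if isinstance(items, Mapping):
        keys = set(items)
        if keys != set(names):
            raise DomainError(
                f"{what} items must be exactly {sorted(names)}; "
                f"missing {sorted(set(names) - keys)}, extra {sorted(keys - set(names))}")
        out = {k: items[k] for k in names}
    else:
        vals = list(items)
        if len(vals) != len(names):
            raise DomainError(f"{what} expects {len(names)} item grades, got {len(vals)}")
        out = dict(zip(names, vals))
    for k, g in out.items():
        if isinstance(g, bool) or g not in VALID_GRADES:
            raise DomainError(f"{what} item {k!r}: grade must be one of "
                              f"{VALID_GRADES}, got {g!r}")
        out[k] = int(g)
    return out


@dataclass(frozen=True)
class PossumInput:
    """Validated POSSUM item grades: 12 physiological + 6 operative."""

    physiological: Mapping[str, int]
    operative: Mapping[str, int]

    def __post_init__(self):
        object.__setattr__(self, "physiological",
                           _check_grades(self.physiological, PHYSIOLOGY_ITEMS,
                                         "physiological"))
        object.__setattr__(self, "operative",
                           _check_grades(self.operative, OPERATIVE_ITEMS,
                                         "operative"))


@dataclass(frozen=True)
class PossumResult:
    ps: int
    os: int
    predicted_mortality: float


def possum_physiological_score(items) -> int:
    """Sum the 12 physiological item grades into PS (12-96)."""
    return sum(_check_grades(items, PHYSIOLOGY_ITEMS, "physiological").values())


def possum_operative_score(items, force_major: bool = True) -> int:
    """Sum the 6 operative item grades into OS (6-48).

    With ``force_major`` (the study convention) the operative-severity item is
    floored at the 'major' grade (4): a minor/moderate grade is raised to 4,
    a 'major+' grade (8) is left as is.
    """
    grades = _check_grades(items, OPERATIVE_ITEMS, "operative")
    if force_major:
        grades["severity"] = max(grades["severity"], 4)
    return sum(grades.values())


def ppossum_mortality(ps: int, os: int) -> float:
    """Predicted in-patient mortality R from the P-POSSUM logistic equation.

    ln(R/(1-R)) = -9.065 + 0.1692·PS + 0.1550·OS; strictly increasing in both
    scores.
    """
    if not (12 <= ps <= 96):
        raise DomainError(f"physiological score must be in [12, 96], got {ps}")
    if not (6 <= os <= 48):
        raise DomainError(f"operative score must be in [6, 48], got {os}")
    return float(expit(PPOSSUM_INTERCEPT + PPOSSUM_PS_COEF * ps + PPOSSUM_OS_COEF * os))


def possum_result(possum: PossumInput, force_major: bool = True) -> PossumResult:
    """Convenience wrapper: PS, OS and predicted mortality in one object."""
    ps = possum_physiological_score(possum.physiological)
    os_ = possum_operative_score(possum.operative, force_major=force_major)
    return PossumResult(ps, os_, ppossum_mortality(ps, os_))


# ==========================================================================
# SECTION 2 — cohort statistics
# ==========================================================================

@dataclass(frozen=True)
class Contingency2x2:
    """2×2 table: a = events in the index stratum, b = non-events there,
    c = events in the reference stratum, d = non-events there."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if isinstance(v, bool) or int(v) != v or v < 0:
                raise DomainError(f"cell {name} must be a non-negative integer, got {v!r}")
        if self.a + self.b + self.c + self.d == 0:
            raise DomainError("contingency table is empty")

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (int(self.a), int(self.b), int(self.c), int(self.d))


@dataclass(frozen=True)
class OddsRatioResult:
    value: float
    ci_low: float
    ci_high: float
    corrected: bool = False   # Haldane-Anscombe +0.5 applied
    undefined: bool = False


def odds_ratio(t: Contingency2x2) -> OddsRatioResult:
    """Cross-product odds ratio with a Woolf (log-normal) 95% CI.

    If any cell is zero the Haldane-Anscombe correction (+0.5 to every cell)
    is applied and the result flagged.  A zero margin on either the event or
    the exposure axis leaves the OR undefined even after correction.
    """
    a, b, c, d = t.cells
    if (a == 0 and c == 0) or (b == 0 and d == 0) \
            or (a == 0 and b == 0) or (c == 0 and d == 0):
        return OddsRatioResult(math.nan, math.nan, math.nan, False, True)
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = math.exp(math.log(or_) - Z_95 * se)
    hi = math.exp(math.log(or_) + Z_95 * se)
    return OddsRatioResult(or_, lo, hi, corrected, False)


def _woolf_wald_p(t: Contingency2x2) -> float:
    """Two-sided Wald p for ln(OR) = 0.

    For a saturated single-indicator logistic model on a 2×2 table the Wald z
    equals ln(OR) divided by the Woolf standard error, so the stratum-versus-
    reference logistic Wald test reduces to this closed form.
    """
    res = odds_ratio(t)
    if res.undefined or res.value <= 0:
        return math.nan
    a, b, c, d = t.cells
    if res.corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = math.log(res.value) / se
    return float(2 * stats.norm.sf(abs(z)))


def fisher_exact(t: Contingency2x2) -> float:
    """Two-sided Fisher exact p by point-probability hypergeometric summation.

    Sums the probabilities of all tables (with the observed margins) whose
    hypergeometric probability does not exceed the observed table's, the
    definition used by common statistical packages.
    """
    a, b, c, d = t.cells
    n = a + b + c + d
    r1 = a + b        # index-stratum margin
    c1 = a + c        # event margin
    if r1 == 0 or c1 == 0 or r1 == n or c1 == n:
        return 1.0    # a zero margin: only one table is possible
    hg = stats.hypergeom(n, r1, c1)
    support = np.arange(max(0, c1 - (n - r1)), min(r1, c1) + 1)
    pmf = hg.pmf(support)
    p_obs = hg.pmf(a)
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    return min(p, 1.0)


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    p_value: float
    method: str  # "exact" or "normal"


def _exact_u_distribution(ranks2: np.ndarray, n: int) -> np.ndarray:
    """Exact permutation distribution of 2·R_x over subsets of size n.

    ``ranks2`` holds the doubled midranks (integers) of the pooled sample.
    Returns counts indexed by the doubled rank sum; dynamic programming over
    items, equivalent to full enumeration of all C(n+m, n) assignments.
    """
    smax = int(ranks2.sum())
    counts = np.zeros((n + 1, smax + 1))
    counts[0, 0] = 1.0
    for r in ranks2:
        r = int(r)
        for k in range(min(n, 1_000_000), 0, -1):
            counts[k, r:] += counts[k - 1, : smax + 1 - r]
    return counts[n]


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> MannWhitneyResult:
    """Mann-Whitney U (midrank ties) with a two-sided p-value.

    Exact permutation p when n·m ≤ 400 (tie-safe dynamic programming over the
    doubled midranks), otherwise a normal approximation with tie-corrected
    variance and continuity correction.  Identical samples give p = 1 with a
    warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise StatisticsError("both samples must be non-empty")
    n, m = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u = float(ranks[:n].sum() - n * (n + 1) / 2)  # U statistic for x
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical across both samples; p set to 1",
                      stacklevel=2)
        return MannWhitneyResult(u, 1.0, "degenerate-ties")
    nm = n * m
    if nm <= 400:
        # run the DP on the smaller sample (min(n,m) <= 20 when n*m <= 400)
        # and mirror via U_x + U_y = nm; the distribution is symmetric anyway
        k = min(n, m)
        ranks2 = np.rint(ranks * 2).astype(int)
        dist = _exact_u_distribution(ranks2, k)
        total = dist.sum()
        # doubled U values for the size-k side: 2*R - k(k+1)
        u2 = np.arange(dist.size) - k * (k + 1)
        u2_obs = int(round(2 * u)) if k == n else 2 * nm - int(round(2 * u))
        u2_lo = min(u2_obs, 2 * nm - u2_obs)
        u2_hi = 2 * nm - u2_lo
        p = float((dist[u2 <= u2_lo].sum() + dist[u2 >= u2_hi].sum()) / total)
        return MannWhitneyResult(u, min(p, 1.0), "exact")
    nn = n + m
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum()) / (nn * (nn - 1))
    sigma2 = nm / 12.0 * ((nn + 1) - tie_term)
    centred = u - nm / 2.0
    cc = 0.5 * np.sign(centred)
    z = (centred - cc) / math.sqrt(sigma2)
    p = float(min(2 * stats.norm.sf(abs(z)), 1.0))
    return MannWhitneyResult(u, p, "normal")


@dataclass(frozen=True)
class LogisticFit:
    """Maximum-likelihood logistic regression fit."""

    coef: np.ndarray          # including intercept first when add_constant
    cov: np.ndarray           # inverse observed information
    converged: bool
    separated: bool
    n_iter: int
    loglike: float

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


def fit_logistic(outcome: Sequence[int], predictors, *, add_constant: bool = True,
                 max_iter: int = 100, tol: float = 1e-8) -> LogisticFit:
    """Fit a logistic regression by Newton-Raphson.

    ``predictors`` is a 1-D predictor or a 2-D design matrix (columns =
    covariates).  Convergence when the largest coefficient update falls below
    ``tol``.  Complete separation is detected (coefficients diverging while
    fitted probabilities saturate) and flagged rather than raised; a
    rank-deficient design raises :class:`StatisticsError`.
    """
    y = np.asarray(outcome, dtype=float)
    X = np.asarray(predictors, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if add_constant:
        X = np.column_stack([np.ones(len(y)), X])
    if y.size != X.shape[0]:
        raise StatisticsError("outcome and predictors have different lengths")
    if not ((y == 0) | (y == 1)).all():
        raise StatisticsError("outcome must be binary 0/1")
    if y.sum() == 0 or y.sum() == y.size:
        raise StatisticsError("need at least one event and one non-event")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise StatisticsError("design matrix is rank deficient (collinear columns)")

    beta = np.zeros(X.shape[1])
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        p = expit(eta)
        w = p * (1 - p)
        grad = X.T @ (y - p)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break  # information singular: separation territory
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    separated = bool(np.max(np.abs(beta)) > 30) and not converged
    p = expit(X @ beta)
    w = np.clip(p * (1 - p), 1e-12, None)
    H = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.full((X.shape[1], X.shape[1]), np.nan)
        separated = True
    eps = 1e-300
    ll = float(np.sum(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
    return LogisticFit(beta, cov, converged and not separated, separated, it, ll)


def _check_classes(scores, outcomes):
    s = np.asarray(scores, dtype=float)
    try:
        y = np.asarray(outcomes).astype(int)
    except (TypeError, ValueError) as exc:
        raise StatisticsError(f"outcomes must be binary 0/1 ({exc})") from exc
    if s.size != y.size:
        raise StatisticsError("scores and outcomes have different lengths")
    if not np.isin(y, (0, 1)).all():
        raise StatisticsError("outcomes must be binary 0/1")
    return s, y


def c_index(scores: Sequence[float], outcomes: Sequence[int]) -> float:
    """Concordance statistic (AUC): P(score_event > score_non-event), ties ½.

    Computed by the rank formula, AUC = (R₁ − n₁(n₁+1)/2)/(n₁·n₀) with R₁ the
    midrank sum of the events.  Returns NaN if a class is absent.
    """
    s, y = _check_classes(scores, outcomes)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        return math.nan
    ranks = stats.rankdata(s)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


@dataclass(frozen=True)
class RocResult:
    """ROC operating points and trapezoidal area.

    ``points`` rows are (threshold, sensitivity, 1−specificity), one per
    distinct score value (score ≥ threshold ⇒ predicted positive), preceded by
    the degenerate (+inf, 0, 0) point.
    """

    points: pd.DataFrame
    auc: float
    auc_se: float


def _delong_placements(s: np.ndarray, y: np.ndarray):
    """DeLong structural components V10 (per event) and V01 (per non-event)."""
    pos = s[y == 1]
    neg = s[y == 0]
    n1, n0 = pos.size, neg.size
    ranks_all = stats.rankdata(np.concatenate([pos, neg]))
    ranks_pos = stats.rankdata(pos)
    ranks_neg = stats.rankdata(neg)
    v10 = (ranks_all[:n1] - ranks_pos) / n0
    v01 = 1.0 - (ranks_all[n1:] - ranks_neg) / n1
    return v10, v01


def roc_curve(scores: Sequence[float], outcomes: Sequence[int]) -> RocResult:
    """ROC curve with one operating point per distinct threshold.

    The trapezoidal area over the staircase equals the rank-formula C-index
    (ties contribute diagonal segments).  ``auc_se`` is the DeLong standard
    error.
    """
    s, y = _check_classes(scores, outcomes)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise StatisticsError("ROC curve undefined: one outcome class is absent")
    order = np.argsort(-s, kind="mergesort")
    s_sorted = s[order]
    y_sorted = y[order]
    distinct = np.r_[np.diff(s_sorted) != 0, True]
    tps = np.cumsum(y_sorted)[distinct]
    fps = np.cumsum(1 - y_sorted)[distinct]
    thresholds = s_sorted[distinct]
    pts = pd.DataFrame({
        "threshold": np.r_[np.inf, thresholds],
        "sensitivity": np.r_[0.0, tps / n1],
        "one_minus_specificity": np.r_[0.0, fps / n0],
    })
    auc = float(np.trapezoid(pts["sensitivity"], pts["one_minus_specificity"]))
    v10, v01 = _delong_placements(s, y)
    var = v10.var(ddof=1) / n1 + v01.var(ddof=1) / n0
    return RocResult(pts, auc, float(math.sqrt(max(var, 0.0))))


@dataclass(frozen=True)
class ScoreComparison:
    auc_a: float
    auc_b: float
    difference: float
    se: float
    z: float
    p_value: float
    method: str


def compare_scores(score_a, score_b, outcomes, *,
                   method: str = "delong") -> ScoreComparison:
    """Paired comparison of two scores' discrimination on the same patients.

    ``method="delong"`` (default): DeLong paired AUC difference with a
    Wald-type z statistic from the estimated covariance of the two AUCs.
    ``method="logistic_wald"``: a Wald test of equal standardized slopes in a
    joint logistic model containing both scores — a likelihood-based
    alternative mirroring contrast tests from underlying logistic fits.
    """
    sa, y = _check_classes(score_a, outcomes)
    sb, _ = _check_classes(score_b, outcomes)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise StatisticsError("comparison undefined: one outcome class is absent")
    auc_a = c_index(sa, y)
    auc_b = c_index(sb, y)
    diff = auc_a - auc_b
    if method == "delong":
        v10a, v01a = _delong_placements(sa, y)
        v10b, v01b = _delong_placements(sb, y)
        s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
        s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
        cov = s10 / n1 + s01 / n0
        var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
        if var <= 0:
            return ScoreComparison(auc_a, auc_b, diff, 0.0, 0.0, 1.0, method)
        se = math.sqrt(var)
        z = diff / se
        p = float(min(2 * stats.norm.sf(abs(z)), 1.0))
        return ScoreComparison(auc_a, auc_b, diff, se, z, p, method)
    if method == "logistic_wald":
        za = (sa - sa.mean()) / (sa.std(ddof=0) or 1.0)
        zb = (sb - sb.mean()) / (sb.std(ddof=0) or 1.0)
        if np.allclose(za, zb):
            return ScoreComparison(auc_a, auc_b, diff, 0.0, 0.0, 1.0, method)
        fit = fit_logistic(y, np.column_stack([za, zb]))
        contrast = np.array([0.0, 1.0, -1.0])
        est = float(contrast @ fit.coef)
        var = float(contrast @ fit.cov @ contrast)
        se = math.sqrt(max(var, 0.0))
        z = est / se if se > 0 else 0.0
        p = float(min(2 * stats.norm.sf(abs(z)), 1.0)) if se > 0 else 1.0
        return ScoreComparison(auc_a, auc_b, diff, se, z, p, method)
    raise ValueError(f"unknown method {method!r}")


# ---- stratified mortality tables ------------------------------------------

@dataclass(frozen=True)
class Stratum:
    label: str
    lo: float
    hi: float  # inclusive


@dataclass(frozen=True)
class StratifierScheme:
    """A named stratification of a score column; the first stratum is the
    odds-ratio reference."""

    name: str
    column: str
    strata: tuple[Stratum, ...]


RISK_SCORE_SCHEME = StratifierScheme("risk_score", "risk_points", (
    Stratum("0-1", 0, 1), Stratum("2", 2, 2), Stratum("3", 3, 3),
    Stratum("4", 4, 4), Stratum("5", 5, 5), Stratum(">=6", 6, 16),
))

LABMELD_SCHEME = StratifierScheme("labmeld", "labmeld", (
    Stratum("6", 6, 6), Stratum("7", 7, 7), Stratum("8", 8, 8),
    Stratum("9-10", 9, 10), Stratum("11-14", 11, 14), Stratum(">=15", 15, 40),
))


@dataclass(frozen=True)
class StratumRow:
    stratum: str
    n_total: int
    n_events: int
    pct_events: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    reference: bool = False
    or_corrected: bool = False
    or_undefined: bool = False


def stratified_mortality_table(cohort: pd.DataFrame,
                               scheme: StratifierScheme,
                               outcome: str = "death_90d") -> list[StratumRow]:
    """Build a stratum-by-stratum 90-day mortality table.

    One row per stratum in score order: n, events, percent, odds ratio versus
    the scheme's reference stratum (cross-product estimator, Woolf 95% CI,
    Haldane-Anscombe correction on zero cells), and the two-sided Wald p for
    the stratum-versus-reference contrast.  Empty strata are emitted with
    n = 0 and an undefined-OR flag, never dropped.
    """
    if scheme.column not in cohort.columns:
        raise SchemaError(f"cohort lacks the stratifier column {scheme.column!r}")
    if outcome not in cohort.columns:
        raise SchemaError(f"cohort lacks the outcome column {outcome!r}")
    vals = cohort[scheme.column].to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise SchemaError(f"{scheme.column} contains missing values")
    y = cohort[outcome].to_numpy(dtype=float)
    if np.isnan(y).any() or not np.isin(y, (0.0, 1.0)).all():
        raise SchemaError(f"{outcome} must be a complete binary column")
    ref = scheme.strata[0]
    in_ref = (vals >= ref.lo) & (vals <= ref.hi)
    n_ref = int(in_ref.sum())
    e_ref = int(y[in_ref].sum())
    rows: list[StratumRow] = []
    for i, st in enumerate(scheme.strata):
        mask = (vals >= st.lo) & (vals <= st.hi)
        n = int(mask.sum())
        e = int(y[mask].sum())
        pct = 100.0 * e / n if n else math.nan
        if i == 0:
            rows.append(StratumRow(st.label, n, e, pct, 1.0,
                                   math.nan, math.nan, math.nan, reference=True))
            continue
        if n == 0:
            rows.append(StratumRow(st.label, 0, 0, math.nan, math.nan,
                                   math.nan, math.nan, math.nan,
                                   or_undefined=True))
            continue
        t = Contingency2x2(e, n - e, e_ref, n_ref - e_ref)
        res = odds_ratio(t)
        p = _woolf_wald_p(t)
        rows.append(StratumRow(st.label, n, e, pct, res.value,
                               res.ci_low, res.ci_high, p,
                               or_corrected=res.corrected,
                               or_undefined=res.undefined))
    return rows


def stratum_table_frame(rows: Iterable[StratumRow]) -> pd.DataFrame:
    """Render StratumRows as the report DataFrame (full precision)."""
    return pd.DataFrame([dataclasses.asdict(r) for r in rows])


# ==========================================================================
# SECTION 3 — synthetic cohorts
# ==========================================================================

#: Published cohort marginals the generator targets by default: per-factor
#: prevalences of the scored covariates in the 529-patient study population.
DEFAULT_PREVALENCES = {
    "right_trisectionectomy": 39 / 529,   # 0.074
    "intrahepatic_cc": 59 / 529,          # 0.112
    "perihilar_cc": 35 / 529,             # 0.066
    "inr_ge_1_1": 61 / 529,               # 0.115
    "ggt_ge_60": 285 / 529,               # 0.539
    "platelets_lt_120": 32 / 529,         # 0.060
    "creatinine_ge_2": 7 / 529,           # 0.013
    "bilirubin_ge_2": 33 / 529,           # 0.062
    "male": 323 / 529,                    # 0.611
}

#: Published risk-group 90-day death rates (group → probability).
DEFAULT_GROUP_DEATH_RATES = {
    "1": 1 / 193, "2A": 1 / 130, "2B": 6 / 99,
    "3A": 5 / 55, "3B": 3 / 32, "4": 8 / 20,
}

#: ASA class distribution: the study reports only ASA III/IV = 45.9%; the
#: split of the remainder (and III vs IV) is the generator's documented
#: convention for an elective hepatectomy population.
DEFAULT_ASA_PROBS = {1: 0.100, 2: 0.441, 3: 0.440, 4: 0.019}

DEFAULT_DIALYSIS_P = 0.004

#: Lab law medians (log-normal); sigmas are solved from the threshold
#: prevalences above so thresholds and prevalences stay mutually consistent.
DEFAULT_LAB_MEDIANS = {
    "inr": 1.0, "ggt_u_per_l": 65.0, "platelets_per_nl": 220.0,
    "creatinine_mg_dl": 0.9, "bilirubin_mg_dl": 0.7,
}
_LAB_THRESHOLDS = {
    # lab -> (threshold, prevalence key, tail: "ge" or "lt")
    "inr": (1.1, "inr_ge_1_1", "ge"),
    "ggt_u_per_l": (60.0, "ggt_ge_60", "ge"),
    "platelets_per_nl": (120.0, "platelets_lt_120", "lt"),
    "creatinine_mg_dl": (2.0, "creatinine_ge_2", "ge"),
    "bilirubin_mg_dl": (2.0, "bilirubin_ge_2", "ge"),
}

#: Age law targets: published median and IQR of the cohort, truncated at 18.
DEFAULT_AGE_QUARTILES = (52.8, 61.8, 69.0)
AGE_MIN = 18.0

#: POSSUM item grade laws over {1,2,4,8}: chosen so E[PS] ≈ 17 and, with the
#: operative-severity item fixed at 'major' (4), E[OS] ≈ 16.
DEFAULT_PHYS_ITEM_PROBS = (0.78, 0.15, 0.055, 0.015)
DEFAULT_OP_ITEM_PROBS = (0.38, 0.34, 0.21, 0.07)

_STREAMS = ("age", "sex", "asa", "diagnosis", "trisectionectomy", "inr", "ggt",
            "platelets", "creatinine", "bilirubin", "dialysis", "possum_phys",
            "possum_op", "death")


@lru_cache(maxsize=16)
def _fit_age_skewnorm(q25: float, q50: float, q75: float):
    """Solve skew-normal (a, loc, scale) matching the three target quartiles."""

    def resid(theta):
        a, loc, log_scale = theta
        return stats.skewnorm.ppf([0.25, 0.5, 0.75], a, loc,
                                  math.exp(log_scale)) - [q25, q50, q75]

    iqr = q75 - q25
    sol = optimize.least_squares(resid, x0=[-1.0, q50 + iqr / 4, math.log(iqr)],
                                 xtol=1e-12, ftol=1e-12)
    a, loc, log_scale = sol.x
    if not sol.success or np.max(np.abs(sol.fun)) > 1e-6:
        raise CohortSpecError(
            f"cannot fit a skew-normal age law to quartiles {(q25, q50, q75)}")
    return float(a), float(loc), float(math.exp(log_scale))


def _lognormal_sigma(median: float, threshold: float, tail_p: float,
                     tail: str, name: str) -> float:
    """Sigma of a log-normal with the given median and tail probability."""
    if not 0 < tail_p < 1:
        raise CohortSpecError(f"{name}: prevalence must be in (0,1), got {tail_p}")
    p_ge = tail_p if tail == "ge" else 1.0 - tail_p
    z = stats.norm.ppf(1.0 - p_ge)
    sigma = (math.log(threshold) - math.log(median)) / z
    if not math.isfinite(sigma) or sigma <= 0:
        raise CohortSpecError(
            f"{name}: median {median} is inconsistent with P(X >= {threshold})"
            f" = {p_ge:.3f} (implied sigma {sigma:.3g} not positive)")
    return sigma


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic hepatectomy cohort generator.

    Defaults reproduce the published cohort's marginals: scored-covariate
    prevalences, the age median/IQR, the ASA mix, and the per-risk-group
    90-day death rates.  Binary factors are derived by thresholding the
    continuous lab draws, so thresholds and prevalences remain mutually
    consistent by construction.  Factors are independent apart from the
    deterministic ties (diagnosis exclusivity, threshold/lab consistency).
    """

    n: int = 529
    covariate_prevalences: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCES))
    group_death_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_DEATH_RATES))
    asa_probs: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_ASA_PROBS))
    lab_medians: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LAB_MEDIANS))
    age_quartiles: tuple[float, float, float] = DEFAULT_AGE_QUARTILES
    dialysis_p: float = DEFAULT_DIALYSIS_P
    phys_item_probs: tuple[float, ...] = DEFAULT_PHYS_ITEM_PROBS
    op_item_probs: tuple[float, ...] = DEFAULT_OP_ITEM_PROBS

    def validate(self) -> None:
        if not isinstance(self.n, (int, np.integer)) or self.n <= 0:
            raise CohortSpecError(f"cohort size must be a positive integer, got {self.n}")
        for k, p in self.covariate_prevalences.items():
            if not 0 <= p <= 1:
                raise CohortSpecError(f"prevalence {k} = {p} outside [0, 1]")
        missing = set(GROUP_ORDER) - set(self.group_death_rates)
        if missing:
            raise CohortSpecError(f"group_death_rates missing groups {sorted(missing)}")
        for g, d in self.group_death_rates.items():
            if not 0 <= d <= 1:
                raise CohortSpecError(f"death rate for group {g} = {d} outside [0, 1]")
        if abs(sum(self.asa_probs.values()) - 1) > 1e-9 or \
                set(self.asa_probs) != {1, 2, 3, 4}:
            raise CohortSpecError("asa_probs must cover classes 1-4 and sum to 1")
        dx = self.covariate_prevalences["intrahepatic_cc"] \
            + self.covariate_prevalences["perihilar_cc"]
        if dx > 1:
            raise CohortSpecError("diagnosis category probabilities exceed 1")
        for probs, name in ((self.phys_item_probs, "phys_item_probs"),
                            (self.op_item_probs, "op_item_probs")):
            if len(probs) != 4 or abs(sum(probs) - 1) > 1e-9 or min(probs) < 0:
                raise CohortSpecError(f"{name} must be 4 probabilities summing to 1")
        if not 0 <= self.dialysis_p <= 1:
            raise CohortSpecError("dialysis_p outside [0, 1]")
        # lab-law feasibility: a positive sigma must exist for every lab
        self.lab_sigmas()
        self.age_law()

    def lab_sigmas(self) -> dict[str, float]:
        sig = {}
        for lab, (thr, pkey, tail) in _LAB_THRESHOLDS.items():
            sig[lab] = _lognormal_sigma(self.lab_medians[lab], thr,
                                        self.covariate_prevalences[pkey], tail, lab)
        return sig

    def age_law(self):
        return _fit_age_skewnorm(*self.age_quartiles)

    def p_age_ge_60(self) -> float:
        """P(age ≥ 60) under the truncated-at-18 fitted age law."""
        a, loc, scale = self.age_law()
        sf18 = stats.skewnorm.sf(AGE_MIN, a, loc, scale)
        return float(stats.skewnorm.sf(60.0, a, loc, scale) / sf18)

    # ---- closed-form group mixture (the generating law, exactly) ----------

    def point_pmf(self) -> np.ndarray:
        """Exact pmf of the Mortality Risk Score points under this spec.

        Convolves the independent per-factor point distributions; the
        threshold factors have exactly the specified prevalences because the
        binary indicators are deterministic functions of the continuous draws.
        """
        pv = self.covariate_prevalences
        factor_pmfs = []

        def bern(p, pts):
            pmf = np.zeros(pts + 1)
            pmf[0] = 1 - p
            pmf[pts] = p
            return pmf

        factor_pmfs.append(bern(self.p_age_ge_60(), 1))
        factor_pmfs.append(bern(pv["right_trisectionectomy"], 1))
        factor_pmfs.append(bern(pv["inr_ge_1_1"], 1))
        factor_pmfs.append(bern(pv["ggt_ge_60"], 1))
        factor_pmfs.append(bern(pv["platelets_lt_120"], 2))
        factor_pmfs.append(bern(pv["creatinine_ge_2"], 3))
        dx = np.zeros(3)
        dx[0] = 1 - pv["intrahepatic_cc"] - pv["perihilar_cc"]
        dx[1] = pv["intrahepatic_cc"]
        dx[2] = pv["perihilar_cc"]
        factor_pmfs.append(dx)
        asa = np.zeros(6)
        asa[0] = self.asa_probs[1] + self.asa_probs[2]
        asa[1] = self.asa_probs[3]
        asa[5] = self.asa_probs[4]
        factor_pmfs.append(asa)
        pmf = np.array([1.0])
        for f in factor_pmfs:
            pmf = np.convolve(pmf, f)
        return pmf  # index = points, length 17

    def expected_group_probabilities(self) -> dict[str, float]:
        pmf = self.point_pmf()
        groups = {g: 0.0 for g in GROUP_ORDER}
        for pts, p in enumerate(pmf):
            groups[risk_group(pts)] += float(p)
        return groups

    def expected_death_rate(self) -> float:
        """Closed-form mixture mean: Σ_g P(group g)·death_rate(g)."""
        gp = self.expected_group_probabilities()
        return float(sum(gp[g] * self.group_death_rates[g] for g in GROUP_ORDER))


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Per-variable substream: adding a variable never perturbs earlier ones."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS.index(stream),)))


GRADE_VALUES = np.array([1, 2, 4, 8])


def _risk_points_frame(df: pd.DataFrame) -> np.ndarray:
    """Vectorized Mortality Risk Score points (cross-checked against
    :func:`mortality_risk_points` in the test suite)."""
    diag_pts = df["diagnosis"].map(_DIAGNOSIS_POINTS).to_numpy()
    asa_pts = df["asa_class"].map(_ASA_POINTS).to_numpy()
    pts = ((df["age_years"].to_numpy() >= 60).astype(int)
           + df["right_trisectionectomy"].to_numpy().astype(int)
           + (df["inr"].to_numpy() >= 1.1).astype(int)
           + (df["ggt_u_per_l"].to_numpy() >= 60).astype(int)
           + 2 * (df["platelets_per_nl"].to_numpy() < 120).astype(int)
           + 3 * (df["creatinine_mg_dl"].to_numpy() >= 2).astype(int)
           + diag_pts + asa_pts)
    return pts.astype(int)


def _group_labels(points: np.ndarray) -> np.ndarray:
    conds = [points <= 1, points == 2, points == 3, points == 4, points == 5]
    return np.select(conds, ["1", "2A", "2B", "3A", "3B"], default="4")


def generate_cohort(spec: CohortSpec, seed: int) -> pd.DataFrame:
    """Draw a synthetic cohort as a DataFrame in the standard CSV schema.

    Continuous labs come from log-normal laws whose sigmas are solved from
    the specified threshold prevalences; age from a skew-normal fitted to the
    target quartiles, truncated at 18.  Each record is scored with the
    Mortality Risk Score and its 90-day death drawn Bernoulli with the
    record's risk-group death rate.  Deterministic under (seed, spec).
    """
    spec.validate()
    n = int(spec.n)
    pv = spec.covariate_prevalences

    a, loc, scale = spec.age_law()
    age_rng = _rng(seed, "age")
    age = stats.skewnorm.rvs(a, loc, scale, size=n, random_state=age_rng)
    bad = age < AGE_MIN
    while bad.any():  # rejection sampling below the adult truncation point
        age[bad] = stats.skewnorm.rvs(a, loc, scale, size=int(bad.sum()),
                                      random_state=age_rng)
        bad = age < AGE_MIN

    sex = np.where(_rng(seed, "sex").random(n) < pv["male"], "male", "female")
    asa = _rng(seed, "asa").choice([1, 2, 3, 4], size=n,
                                   p=[spec.asa_probs[k] for k in (1, 2, 3, 4)])
    p_ih, p_ph = pv["intrahepatic_cc"], pv["perihilar_cc"]
    diagnosis = _rng(seed, "diagnosis").choice(
        np.array(DIAGNOSES), size=n, p=[p_ih, p_ph, 1 - p_ih - p_ph])
    trisect = _rng(seed, "trisectionectomy").random(n) < pv["right_trisectionectomy"]

    sig = spec.lab_sigmas()

    def lab(name, stream):
        mu = math.log(spec.lab_medians[name])
        return np.exp(_rng(seed, stream).normal(mu, sig[name], size=n))

    inr = lab("inr", "inr")
    ggt = lab("ggt_u_per_l", "ggt")
    plt = lab("platelets_per_nl", "platelets")
    cre = lab("creatinine_mg_dl", "creatinine")
    bil = lab("bilirubin_mg_dl", "bilirubin")
    dialysis = _rng(seed, "dialysis").random(n) < spec.dialysis_p

    phys = _rng(seed, "possum_phys").choice(
        GRADE_VALUES, size=(n, 12), p=spec.phys_item_probs)
    op = _rng(seed, "possum_op").choice(
        GRADE_VALUES, size=(n, 6), p=spec.op_item_probs)
    op[:, 0] = 4  # operative severity: 'major' for every hepatectomy, by design

    # labs kept at full precision: rounding near a scoring threshold would
    # bias the binary-factor prevalences away from the generating law
    df = pd.DataFrame({
        "age_years": age,
        "sex": sex,
        "asa_class": asa.astype(int),
        "diagnosis": diagnosis,
        "right_trisectionectomy": trisect.astype(int),
        "inr": inr,
        "ggt_u_per_l": ggt,
        "platelets_per_nl": plt,
        "creatinine_mg_dl": cre,
        "bilirubin_mg_dl": bil,
        "on_dialysis": dialysis.astype(int),
    })
    for j, item in enumerate(PHYSIOLOGY_ITEMS):
        df[f"phys_{item}"] = phys[:, j]
    for j, item in enumerate(OPERATIVE_ITEMS):
        df[f"op_{item}"] = op[:, j]

    points = _risk_points_frame(df)
    groups = _group_labels(points)
    rates = np.array([spec.group_death_rates[g] for g in groups])
    df["death_90d"] = (_rng(seed, "death").random(n) < rates).astype(int)
    return df


# ---- published stratum-count reconstruction -------------------------------

#: Published per-stratum totals and 90-day deaths of the 529-patient cohort.
PRINTED_RISK_SCORE_STRATA = (
    # (label, representative points, n_total, deaths)
    ("0-1", 1, 193, 1), ("2", 2, 130, 1), ("3", 3, 99, 6),
    ("4", 4, 55, 5), ("5", 5, 32, 3), (">=6", 6, 20, 8),
)
PRINTED_LABMELD_STRATA = (
    ("6", 6, 236, 4), ("7", 7, 148, 5), ("8", 8, 57, 4),
    ("9-10", 9, 41, 2), ("11-14", 11, 28, 4), (">=15", 15, 19, 5),
)


def reconstruct_printed_cohort(table: str) -> pd.DataFrame:
    """Deterministic cohort with exactly the published per-stratum counts.

    ``table`` ∈ {"risk_score", "labmeld"}.  Score values are representative
    level codes (any strictly increasing coding gives identical percentages,
    odds ratios and C-index, which depend only on the stratum counts).
    Returns a DataFrame with the score column and ``death_90d``.
    """
    if table == "risk_score":
        strata, column = PRINTED_RISK_SCORE_STRATA, "risk_points"
    elif table == "labmeld":
        strata, column = PRINTED_LABMELD_STRATA, "labmeld"
    else:
        raise ValueError(f"table must be 'risk_score' or 'labmeld', got {table!r}")
    scores: list[int] = []
    deaths: list[int] = []
    for _, level, n, e in strata:
        scores.extend([level] * n)
        deaths.extend([1] * e + [0] * (n - e))
    df = pd.DataFrame({column: scores, "death_90d": deaths})
    if table == "risk_score":
        df["risk_group"] = _group_labels(df["risk_points"].to_numpy())
    return df


def cohort_records(df: pd.DataFrame) -> list[ClinicalRecord]:
    """Convert a schema DataFrame into validated :class:`ClinicalRecord`s."""
    records = []
    has_possum = all(f"phys_{i}" in df.columns for i in PHYSIOLOGY_ITEMS) and \
        all(f"op_{i}" in df.columns for i in OPERATIVE_ITEMS)
    for row in df.itertuples(index=False):
        possum = None
        if has_possum:
            possum = PossumInput(
                {i: int(getattr(row, f"phys_{i}")) for i in PHYSIOLOGY_ITEMS},
                {i: int(getattr(row, f"op_{i}")) for i in OPERATIVE_ITEMS})
        records.append(ClinicalRecord(
            age_years=float(row.age_years),
            sex=str(row.sex),
            asa_class=int(row.asa_class),
            diagnosis=str(row.diagnosis),
            right_trisectionectomy=bool(row.right_trisectionectomy),
            inr=float(row.inr),
            ggt_u_per_l=float(row.ggt_u_per_l),
            platelets_per_nl=float(row.platelets_per_nl),
            creatinine_mg_dl=float(row.creatinine_mg_dl),
            bilirubin_mg_dl=float(row.bilirubin_mg_dl),
            on_dialysis=bool(row.on_dialysis),
            death_90d=None if "death_90d" not in df.columns
            else bool(row.death_90d),
            possum=possum,
        ))
    return records


def load_cohort_spec(path: str | Path) -> CohortSpec:
    """Load a CohortSpec from a YAML/JSON config file; omitted keys keep
    their defaults."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise CohortSpecError(f"config {path} must be a mapping")
    kwargs = {}
    simple = {"n", "dialysis_p"}
    merged = {"covariate_prevalences", "group_death_rates", "lab_medians"}
    for key, val in raw.items():
        if key in simple:
            kwargs[key] = val
        elif key in merged:
            base = dict(getattr(CohortSpec(), key))
            if key == "group_death_rates":
                val = {str(k): v for k, v in val.items()}
            base.update(val)
            kwargs[key] = base
        elif key == "asa_probs":
            kwargs[key] = {int(k): v for k, v in val.items()}
        elif key == "age_quartiles":
            kwargs[key] = tuple(val)
        elif key in {"phys_item_probs", "op_item_probs"}:
            kwargs[key] = tuple(val)
        else:
            raise CohortSpecError(f"unknown CohortSpec key {key!r}")
    spec = CohortSpec(**kwargs)
    spec.validate()
    return spec


# ==========================================================================
# SECTION 4 — pipeline I/O
# ==========================================================================

#: Core cohort CSV schema (one row per patient, UTF-8, comma separated,
#: '.' decimal; booleans as 0/1).  POSSUM item columns are optional but must
#: be complete when present.
SCHEMA_COLUMNS = (
    "age_years", "sex", "asa_class", "diagnosis", "right_trisectionectomy",
    "inr", "ggt_u_per_l", "platelets_per_nl", "creatinine_mg_dl",
    "bilirubin_mg_dl", "on_dialysis",
)
POSSUM_COLUMNS = tuple(f"phys_{i}" for i in PHYSIOLOGY_ITEMS) \
    + tuple(f"op_{i}" for i in OPERATIVE_ITEMS)
SCORE_COLUMNS = ("risk_points", "risk_group", "labmeld", "ps", "os", "ppossum_pct")


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read a cohort CSV, checking the schema header."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise SchemaError(f"{path}: not a readable cohort CSV ({exc})") from exc
    missing = [c for c in SCHEMA_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    known = set(SCHEMA_COLUMNS) | set(POSSUM_COLUMNS) | set(SCORE_COLUMNS) \
        | {"death_90d"}
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        raise SchemaError(f"{path}: unknown columns {unknown}")
    return df


def write_cohort_csv(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def score_cohort(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Append score columns to a cohort table; route bad rows to rejects.

    Returns ``(scored, rejects)``.  Rows with any missing scored field, an
    out-of-domain ASA class, a non-positive lab value or an invalid POSSUM
    grade are moved to the rejects frame with a ``reject_reason`` column —
    never silently dropped or imputed.  P-POSSUM columns are added only when
    the POSSUM item columns are present (operative severity floored at
    'major').
    """
    reasons = pd.Series("", index=df.index, dtype=object)

    def flag(mask, reason):
        nonlocal reasons
        mask = mask.fillna(False) if hasattr(mask, "fillna") else mask
        newly = mask & (reasons == "")
        reasons[newly] = reason

    for col in _SCORED_FIELDS_CSV:
        flag(df[col].isna(), f"{col} missing")
    flag(~df["diagnosis"].isin(DIAGNOSES) & (reasons == ""), "diagnosis invalid")
    asa_num = pd.to_numeric(df["asa_class"], errors="coerce")
    flag(asa_num.notna() & ~asa_num.isin([1, 2, 3, 4]), "asa_class outside 1-4")
    for col in ("inr", "creatinine_mg_dl", "bilirubin_mg_dl"):
        v = pd.to_numeric(df[col], errors="coerce")
        flag(v.notna() & (v <= 0), f"{col} not positive")
    has_possum = all(c in df.columns for c in POSSUM_COLUMNS)
    if has_possum:
        for col in POSSUM_COLUMNS:
            flag(df[col].isna(), f"{col} missing")
            v = pd.to_numeric(df[col], errors="coerce")
            flag(v.notna() & ~v.isin(list(VALID_GRADES)), f"{col} invalid grade")

    ok = reasons == ""
    rejects = df.loc[~ok].copy()
    rejects["reject_reason"] = reasons[~ok]
    scored = df.loc[ok].copy()
    if len(scored):
        pts = _risk_points_frame(scored)
        scored["risk_points"] = pts
        scored["risk_group"] = _group_labels(pts)
        cre = scored["creatinine_mg_dl"].to_numpy(dtype=float)
        cre = np.where(scored["on_dialysis"].to_numpy(dtype=bool),
                       LABMELD_CREATININE_CAP,
                       np.minimum(cre, LABMELD_CREATININE_CAP))
        cre = np.maximum(cre, LABMELD_COMPONENT_FLOOR)
        bil = np.maximum(scored["bilirubin_mg_dl"].to_numpy(dtype=float),
                         LABMELD_COMPONENT_FLOOR)
        inr = np.maximum(scored["inr"].to_numpy(dtype=float),
                         LABMELD_COMPONENT_FLOOR)
        meld = 10.0 * (LABMELD_COEF["creatinine"] * np.log(cre)
                       + LABMELD_COEF["bilirubin"] * np.log(bil)
                       + LABMELD_COEF["inr"] * np.log(inr)
                       + LABMELD_COEF["const"])
        scored["labmeld"] = np.clip(np.floor(meld + 0.5),
                                    LABMELD_MIN, LABMELD_MAX).astype(int)
        if has_possum:
            ps = scored[[f"phys_{i}" for i in PHYSIOLOGY_ITEMS]] \
                .to_numpy(dtype=int).sum(axis=1)
            op = scored[[f"op_{i}" for i in OPERATIVE_ITEMS]].to_numpy(dtype=int)
            op_sev = np.maximum(op[:, 0], 4)
            os_ = op_sev + op[:, 1:].sum(axis=1)
            scored["ps"] = ps
            scored["os"] = os_
            scored["ppossum_pct"] = 100.0 * expit(
                PPOSSUM_INTERCEPT + PPOSSUM_PS_COEF * ps + PPOSSUM_OS_COEF * os_)
    else:
        for col in SCORE_COLUMNS:
            scored[col] = pd.Series(dtype=float)
    return scored, rejects


_SCORED_FIELDS_CSV = (
    "age_years", "asa_class", "diagnosis", "right_trisectionectomy",
    "inr", "ggt_u_per_l", "platelets_per_nl", "creatinine_mg_dl",
    "bilirubin_mg_dl", "on_dialysis",
)


def _write_manifest(outdir: Path, name: str, payload: dict) -> None:
    payload = dict(payload, package_version=__version__)
    with open(outdir / name, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
    log.info("wrote %s", outdir / name)


def _spec_hash(spec: CohortSpec) -> str:
    blob = json.dumps(dataclasses.asdict(spec), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()


def run_simulate(outdir: str | Path, seed: int, spec: CohortSpec | None = None,
                 table: str | None = None) -> Path:
    """Generate (or reconstruct) a cohort CSV plus a reproducibility manifest.

    With ``table`` set, emits the deterministic published-count
    reconstruction instead of a random cohort.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if table is not None:
        df = reconstruct_printed_cohort(table)
        name = f"cohort_{table}_printed.csv"
        manifest = {"mode": "reconstruct", "table": table, "rows": len(df)}
    else:
        spec = spec or CohortSpec()
        df = generate_cohort(spec, seed)
        name = "cohort.csv"
        manifest = {"mode": "simulate", "seed": seed, "rows": len(df),
                    "spec": dataclasses.asdict(spec), "spec_sha256": _spec_hash(spec)}
    path = outdir / name
    write_cohort_csv(df, path)
    manifest["csv_sha256"] = hashlib.sha256(path.read_bytes()).hexdigest()
    _write_manifest(outdir, "manifest_simulate.json", manifest)
    return path


def run_score(input_path: str | Path, outdir: str | Path) -> tuple[Path, Path]:
    """Score a cohort CSV; write ``scored.csv`` and ``rejects.csv``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df = read_cohort_csv(input_path)
    scored, rejects = score_cohort(df)
    scored_path = outdir / "scored.csv"
    rejects_path = outdir / "rejects.csv"
    scored.to_csv(scored_path, index=False)
    rejects.to_csv(rejects_path, index=False)
    log.info("scored %d rows, rejected %d", len(scored), len(rejects))
    _write_manifest(outdir, "manifest_score.json", {
        "input": str(input_path), "n_scored": len(scored),
        "n_rejected": len(rejects)})
    return scored_path, rejects_path


def _render_stratum_csv(rows: list[StratumRow], path: Path) -> pd.DataFrame:
    frame = stratum_table_frame(rows)
    out = frame.copy()
    out["pct_events"] = out["pct_events"].round(1)  # mirror the published tables
    out["odds_ratio"] = out["odds_ratio"].round(2)
    out["ci_low"] = out["ci_low"].round(2)
    out["ci_high"] = out["ci_high"].round(2)
    out["p_value"] = out["p_value"].round(4)
    out.to_csv(path, index=False)
    return frame


def run_validate(input_path: str | Path, outdir: str | Path,
                 roc_test: str = "delong") -> dict[str, Path]:
    """Run the validation report on a scored cohort with outcomes.

    Emits whichever of the following the input supports: ``table2.csv``
    (risk-score strata), ``table3.csv`` (labMELD strata), ``table4.csv``
    (AUC per score, 95% CI and pairwise comparison against the risk score),
    ``table5.csv`` (per-risk-group descriptives of the comparator scores)
    and ``roc_<score>.csv`` operating-point tables, plus a manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df = pd.read_csv(input_path)
    if "death_90d" not in df.columns:
        raise SchemaError(f"{input_path}: no outcome column 'death_90d'")
    y = df["death_90d"].to_numpy()
    outputs: dict[str, Path] = {}
    method = {"delong": "delong", "wald": "logistic_wald",
              "logistic_wald": "logistic_wald"}.get(roc_test)
    if method is None:
        raise HepascoreError(f"unknown ROC comparison method {roc_test!r}")

    if "risk_points" in df.columns:
        rows = stratified_mortality_table(df, RISK_SCORE_SCHEME)
        outputs["table2"] = outdir / "table2.csv"
        _render_stratum_csv(rows, outputs["table2"])
    if "labmeld" in df.columns:
        rows = stratified_mortality_table(df, LABMELD_SCHEME)
        outputs["table3"] = outdir / "table3.csv"
        _render_stratum_csv(rows, outputs["table3"])

    score_cols = [c for c in ("risk_points", "labmeld", "ps", "os", "ppossum_pct")
                  if c in df.columns]
    both_classes = 0 < y.sum() < len(y)
    t4 = []
    for col in score_cols:
        if not both_classes:
            t4.append({"score": col, "auc": math.nan, "ci_low": math.nan,
                       "ci_high": math.nan, "p_vs_risk_score": math.nan,
                       "note": "undefined: single outcome class"})
            continue
        roc = roc_curve(df[col], y)
        p_cmp = math.nan
        if col != "risk_points" and "risk_points" in df.columns:
            p_cmp = compare_scores(df["risk_points"], df[col], y,
                                   method=method).p_value
        t4.append({"score": col, "auc": roc.auc,
                   "ci_low": roc.auc - Z_95 * roc.auc_se,
                   "ci_high": roc.auc + Z_95 * roc.auc_se,
                   "p_vs_risk_score": p_cmp, "note": ""})
        roc_path = outdir / f"roc_{col}.csv"
        roc.points.to_csv(roc_path, index=False)
        outputs[f"roc_{col}"] = roc_path
    if t4:
        outputs["table4"] = outdir / "table4.csv"
        pd.DataFrame(t4).round(4).to_csv(outputs["table4"], index=False)

    comparators = [c for c in ("labmeld", "ppossum_pct", "ps", "os")
                   if c in df.columns]
    if "risk_group" in df.columns and comparators:
        recs = []
        for g in GROUP_ORDER:
            sub = df[df["risk_group"].astype(str) == g]
            rec = {"risk_group": g, "n": len(sub)}
            for col in comparators:
                v = sub[col].astype(float)
                rec[f"{col}_median"] = v.median()
                rec[f"{col}_q1"] = v.quantile(0.25)
                rec[f"{col}_q3"] = v.quantile(0.75)
                rec[f"{col}_mean"] = v.mean()
                rec[f"{col}_sd"] = v.std(ddof=1)
            recs.append(rec)
        outputs["table5"] = outdir / "table5.csv"
        pd.DataFrame(recs).round(2).to_csv(outputs["table5"], index=False)

    _write_manifest(outdir, "manifest_validate.json", {
        "input": str(input_path), "n": len(df), "roc_test": method,
        "outputs": {k: str(v) for k, v in outputs.items()}})
    return outputs


def run_compare_roc(input_path: str | Path, score_a: str, score_b: str,
                    method: str = "delong") -> ScoreComparison:
    """Paired ROC/AUC comparison of two score columns of a scored cohort."""
    df = pd.read_csv(input_path)
    for col in (score_a, score_b, "death_90d"):
        if col not in df.columns:
            raise SchemaError(f"{input_path}: missing column {col!r}")
    method = {"wald": "logistic_wald"}.get(method, method)
    return compare_scores(df[score_a], df[score_b], df["death_90d"],
                          method=method)
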