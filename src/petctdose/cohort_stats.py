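"""Weight stratification, summary statistics and two-cohort comparison.

Patients are stratified into the seven clinical weight bands ("<50" through
">100" kg).  Per quantity and per stratum the pipeline reports median,
interquartile range, percentage difference of the comparison cohort against
the reference cohort, and a two-sided Mann–Whitney U p-value.  Medians are
used throughout to blunt the influence of outliers; no multiple-testing
correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .dosimetry import DoseCoefficientScheme, PatientRecord, default_scheme, dose_result_for_patient
from .errors import EmptyInputError, InvalidInputError, ValidationError

__all__ = [
    "WeightBin",
    "WeightCategoryScheme",
    "ComparisonRow",
    "default_weight_categories",
    "assign_weight_category",
    "median_iqr",
    "percent_difference",
    "mann_whitney_u",
    "ct_dose_proportion",
    "dose_table",
    "compare_cohorts",
    "ct_proportion_by_stratum",
    "DOSE_QUANTITIES",
]

ALL_LABEL = "ALL"

#: Pooled-size threshold below which the exact Mann–Whitney null is used
#: (tie-free samples only); chosen small so exact tests stay fast.
EXACT_THRESHOLD = 12


@dataclass(frozen=True)
class WeightBin:
    label: str
    lower: float  # kg, inclusive
    upper: float  # kg, exclusive

    def contains(self, weight: float) -> bool:
        return self.lower <= weight < self.upper


@dataclass(frozen=True)
class WeightCategoryScheme:
    bins: tuple[WeightBin, ...]

    def __post_init__(self):
        if not self.bins:
            raise InvalidInputError("weight-category scheme needs at least one bin")
        if self.bins[0].lower != 0.0 or not math.isinf(self.bins[-1].upper):
            raise InvalidInputError("bins must cover all positive weights")
        for a, b in zip(self.bins, self.bins[1:]):
            if b.lower != a.upper:
                raise InvalidInputError(f"bins {a.label!r} and {b.label!r} are not contiguous")

    @property
    def labels(self) -> list[str]:
        return [b.label for b in self.bins]


def default_weight_categories() -> WeightCategoryScheme:
    """The seven clinical weight bands.

    Half-open bins [lower, lower+10); exactly 100 kg goes to ">100" so the
    bins stay contiguous.
    """
    return WeightCategoryScheme(
        bins=(
            WeightBin("<50", 0.0, 50.0),
            WeightBin("50–59", 50.0, 60.0),
            WeightBin("60–69", 60.0, 70.0),
            WeightBin("70–79", 70.0, 80.0),
            WeightBin("80–89", 80.0, 90.0),
            WeightBin("90–99", 90.0, 100.0),
            WeightBin(">100", 100.0, math.inf),
        )
    )


def assign_weight_category(weight: float, scheme: WeightCategoryScheme | None = None) -> str:
    """Map a positive weight to exactly one stratum label."""
    if not math.isfinite(weight) or weight <= 0:
        raise InvalidInputError(f"weight must be finite and > 0, got {weight!r}")
    scheme = scheme or default_weight_categories()
    for b in scheme.bins:
        if b.contains(weight):
            return b.label
    raise InvalidInputError(f"no bin contains weight {weight}")  # pragma: no cover


def median_iqr(values: Sequence[float]) -> tuple[float, float, float]:
    """Median and quartiles (Q1, Q3) by linear interpolation between order statistics."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise EmptyInputError("median_iqr needs at least one value")
    q1, med, q3 = np.percentile(arr, [25.0, 50.0, 75.0], method="linear")
    return float(med), float(q1), float(q3)


def percent_difference(reference: float, comparison: float) -> float:
    """Percent change of ``comparison`` relative to ``reference`` (the mCT-era cohort)."""
    if reference == 0:
        raise InvalidInputError("percent_difference reference must be nonzero")
    return 100.0 * (comparison - reference) / reference


def mann_whitney_u(sample_a: Sequence[float], sample_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test; returns (U of sample_a, p-value).

    Exact null enumeration when the pooled size is at most 12 and the
    samples are tie-free; otherwise the normal approximation with midranks,
    tie-corrected variance and continuity correction.  The U statistic
    counts (a > b) pairs with half credit for ties, so U_a + U_b = n_a·n_b.
    """
    a = np.asarray(list(sample_a), dtype=float)
    b = np.asarray(list(sample_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise EmptyInputError("mann_whitney_u needs non-empty samples")
    pooled = np.concatenate([a, b])
    tie_free = np.unique(pooled).size == pooled.size
    if tie_free and pooled.size <= EXACT_THRESHOLD:
        res = mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic", use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def ct_dose_proportion(ed_ct: float, ed_total: float) -> float:
    """Percent of a patient's total effective dose contributed by the CT component."""
    if ed_total <= 0:
        raise InvalidInputError("ed_total must be > 0")
    if ed_ct < 0 or ed_ct > ed_total * (1 + 1e-12):
        raise InvalidInputError("ed_ct must lie in [0, ed_total]")
    return 100.0 * ed_ct / ed_total


@dataclass(frozen=True)
class ComparisonRow:
    """One quantity in one stratum, across the two cohorts."""

    quantity: str
    stratum: str
    n_a: int
    n_b: int
    median_a: Optional[float]
    q1_a: Optional[float]
    q3_a: Optional[float]
    median_b: Optional[float]
    q1_b: Optional[float]
    q3_b: Optional[float]
    percent_difference: Optional[float]
    p_value: Optional[float]
    significant: Optional[bool]


#: Quantities compared between cohorts, in report order.
DOSE_QUANTITIES = (
    ("weight_kg", "Weight (kg)"),
    ("injected_activity_mbq", "Injected activity (MBq)"),
    ("ed_ct", "ED_CT (mSv)"),
    ("ed_pet", "ED_PET (mSv)"),
    ("ed_pet_ws", "ED_PET-WS (mSv)"),
    ("ed_pet_bv", "ED_PET-BV (mSv)"),
    ("ed_total_icrp", "ED_TOTAL-ICRP (mSv)"),
    ("ed_total_ws", "ED_TOTAL-WS (mSv)"),
    ("ed_total_bv", "ED_TOTAL-BV (mSv)"),
)

_REQUIRED_COLUMNS = (
    "patient_id",
    "cohort",
    "weight_kg",
    "height_cm",
    "gender",
    "injected_activity_mbq",
    "dlp_mgycm",
)


def _record_from_row(row: pd.Series) -> PatientRecord:
    h = row["height_cm"]
    height = None if h is None or (isinstance(h, float) and math.isnan(h)) else float(h)
    gender = row.get("gender", "unknown")
    if gender is None or (isinstance(gender, float) and math.isnan(gender)) or gender == "":
        gender = "unknown"
    return PatientRecord(
        patient_id=str(row["patient_id"]),
        cohort=str(row["cohort"]),
        weight_kg=float(row["weight_kg"]),
        injected_activity_mbq=float(row["injected_activity_mbq"]),
        dlp_mgycm=float(row["dlp_mgycm"]),
        height_cm=height,
        gender=str(gender),
    )


def dose_table(
    records: pd.DataFrame,
    scheme: DoseCoefficientScheme | None = None,
    categories: WeightCategoryScheme | None = None,
) -> pd.DataFrame:
    """Per-patient dose table: input columns plus dose results and stratum label.

    Validates every row; schema violations are collected and raised together
    so a bad file reports all offending rows at once.
    """
    scheme = scheme or default_scheme()
    categories = categories or default_weight_categories()
    missing = [c for c in _REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValidationError(f"patient table missing columns: {missing}")
    if len(records) == 0:
        raise EmptyInputError("patient table is empty")

    bad: list[tuple[int, str]] = []
    results = []
    for idx, row in records.iterrows():
        try:
            rec = _record_from_row(row)
            results.append(dose_result_for_patient(rec, scheme))
        except (InvalidInputError, ValueError, TypeError) as exc:
            bad.append((idx, str(exc)))
    if bad:
        raise ValidationError(
            "invalid patient rows: " + "; ".join(f"row {i}: {m}" for i, m in bad),
            rows=[i for i, _ in bad],
        )

    out = records.reset_index(drop=True).copy()
    for col in ("ed_pet", "ed_pet_ws", "ed_pet_bv", "ed_ct", "ed_total_icrp", "ed_total_ws", "ed_total_bv"):
        out[col] = [getattr(r, col) for r in results]
    out["model_name"] = [r.model_name for r in results]
    out["weight_category"] = [assign_weight_category(w, categories) for w in out["weight_kg"]]
    out["ct_proportion_ws"] = [
        ct_dose_proportion(r.ed_ct, r.ed_total_ws) for r in results
    ]
    return out


def _strata_frames(df: pd.DataFrame, categories: WeightCategoryScheme):
    yield ALL_LABEL, df
    for label in categories.labels:
        yield label, df[df["weight_category"] == label]


def _compare_one(quantity: str, stratum: str, a: pd.Series, b: pd.Series) -> ComparisonRow:
    a = a.dropna()
    b = b.dropna()
    n_a, n_b = int(a.size), int(b.size)
    if n_a == 0 or n_b == 0:
        med_a = q1_a = q3_a = None
        med_b = q1_b = q3_b = None
        if n_a:
            med_a, q1_a, q3_a = median_iqr(a)
        if n_b:
            med_b, q1_b, q3_b = median_iqr(b)
        return ComparisonRow(quantity, stratum, n_a, n_b, med_a, q1_a, q3_a, med_b, q1_b, q3_b, None, None, None)
    med_a, q1_a, q3_a = median_iqr(a)
    med_b, q1_b, q3_b = median_iqr(b)
    pdiff = percent_difference(med_a, med_b) if med_a != 0 else None
    _, p = mann_whitney_u(a, b)
    return ComparisonRow(
        quantity, stratum, n_a, n_b, med_a, q1_a, q3_a, med_b, q1_b, q3_b, pdiff, p, p < 0.05
    )


def compare_cohorts(
    records_a: pd.DataFrame,
    records_b: pd.DataFrame,
    scheme: DoseCoefficientScheme | None = None,
    categories: WeightCategoryScheme | None = None,
) -> list[ComparisonRow]:
    """Full stratified comparison of two cohorts.

    Cohort A is the reference (conventional-scanner era) for every
    percentage difference.  For blood-volume quantities the per-stratum n
    counts only patients with a recorded height.
    """
    categories = categories or default_weight_categories()
    dt_a = dose_table(records_a, scheme, categories)
    dt_b = dose_table(records_b, scheme, categories)
    rows: list[ComparisonRow] = []
    for quantity, _ in DOSE_QUANTITIES:
        for stratum, (sub_a, sub_b) in (
            (label, (fa, fb))
            for (label, fa), (_, fb) in zip(
                _strata_frames(dt_a, categories), _strata_frames(dt_b, categories)
            )
        ):
            rows.append(_compare_one(quantity, stratum, sub_a[quantity], sub_b[quantity]))
    return rows


def ct_proportion_by_stratum(
    dose_df: pd.DataFrame, categories: WeightCategoryScheme | None = None
) -> pd.DataFrame:
    """Median CT share (%) of the weight-scaled total dose, per stratum and overall."""
    categories = categories or default_weight_categories()
    rows = []
    for label, sub in _strata_frames(dose_df, categories):
        if len(sub) == 0:
            rows.append({"stratum": label, "n": 0, "median_ct_proportion": math.nan})
        else:
            med, _, _ = median_iqr(sub["ct_proportion_ws"])
            rows.append({"stratum": label, "n": len(sub), "median_ct_proportion": med})
    return pd.DataFrame(rows)
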