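"""Per-patient effective dose for whole-body [18F]FDG PET/CT.

The PET component of the effective dose is the injected activity times a
dose coefficient (mSv/MBq) for the ICRP reference phantom that best matches
the patient's weight: the 70 kg adult (0.019 mSv/MBq) above 65 kg, the
57 kg adult (0.024 mSv/MBq) between 45 and 65 kg inclusive, and the 33 kg
child (0.036 mSv/MBq) below 45 kg.  Two rescalings of that value are
carried alongside it:

* weight scaling — ``ED_PET * model_weight / patient_weight``, a first-order
  correction for the mismatch between the phantom and the patient;
* blood-volume scaling — ``ED_PET * IBV / 70`` where the indexed blood
  volume ``IBV = 70 / sqrt(BMI / 22)`` ml/kg estimates blood volume per kg
  from body-mass index.  At the reference BMI of 22 kg/m² this is the
  identity; heavier habitus (larger BMI) lowers the per-kg blood volume and
  with it the scaled dose.  It needs a recorded height, so it is absent
  (never imputed) for patients without one.

The CT component is the scanner-reported dose-length product times a
whole-body conversion factor, 0.018 mSv per mGy·cm by default.  Totals are
CT + PET, one per PET method.

All computation is done at full precision; rounding happens only when
tables are rendered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from .errors import ConfigurationError, InvalidInputError

__all__ = [
    "ReferenceModelEntry",
    "DoseCoefficientScheme",
    "PatientRecord",
    "DoseResult",
    "default_scheme",
    "scheme_from_yaml",
    "assign_reference_model",
    "ed_pet",
    "ed_pet_weight_scaled",
    "body_mass_index",
    "indexed_blood_volume",
    "ed_pet_blood_volume_scaled",
    "ed_ct_from_dlp",
    "ed_total",
    "dose_result_for_patient",
]

GENDERS = ("male", "female", "unknown")

#: Reference indexed blood volume, ml per kg body weight.
REFERENCE_BLOOD_VOLUME_ML_PER_KG = 70.0

#: Reference body-mass index, kg/m².
REFERENCE_BMI = 22.0


def _require_finite_positive(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value) or value <= 0:
        raise InvalidInputError(f"{name} must be a finite positive number, got {value!r}")
    return value


def _require_finite_nonnegative(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value) or value < 0:
        raise InvalidInputError(f"{name} must be finite and >= 0, got {value!r}")
    return value


@dataclass(frozen=True)
class ReferenceModelEntry:
    """One ICRP reference phantom with its dose coefficient and weight band.

    The band is ``weight > lower_bound`` (or ``>=`` when ``lower_inclusive``);
    entries are tried from the heaviest band down, so an ordered scheme
    partitions all positive weights.
    """

    name: str
    model_weight: float  # kg
    coefficient: float  # mSv/MBq
    lower_bound: float  # kg
    lower_inclusive: bool = False

    def matches(self, weight: float) -> bool:
        if self.lower_inclusive:
            return weight >= self.lower_bound
        return weight > self.lower_bound


@dataclass(frozen=True)
class DoseCoefficientScheme:
    """Dose-coefficient assignment rule plus the DLP conversion factor."""

    entries: tuple[ReferenceModelEntry, ...]
    dlp_conversion: float = 0.018  # mSv per mGy·cm

    def __post_init__(self):
        if not self.entries:
            raise ConfigurationError("scheme needs at least one reference model")
        bounds = [e.lower_bound for e in self.entries]
        if any(b2 >= b1 for b1, b2 in zip(bounds, bounds[1:])):
            raise ConfigurationError(
                "reference-model entries must be ordered by strictly decreasing lower bound"
            )
        last = self.entries[-1]
        if last.lower_bound != 0.0:
            raise ConfigurationError("last entry must cover down to weight 0 (lower_bound 0)")
        for e in self.entries:
            if e.model_weight <= 0 or e.coefficient <= 0:
                raise ConfigurationError(f"model {e.name!r}: weight and coefficient must be > 0")
        if self.dlp_conversion <= 0:
            raise ConfigurationError("dlp_conversion must be > 0")


def default_scheme() -> DoseCoefficientScheme:
    """ICRP 128 FDG coefficients with the weight-band assignment used here."""
    return DoseCoefficientScheme(
        entries=(
            ReferenceModelEntry("70 kg adult", 70.0, 0.019, 65.0, lower_inclusive=False),
            ReferenceModelEntry("57 kg adult", 57.0, 0.024, 45.0, lower_inclusive=True),
            ReferenceModelEntry("33 kg child", 33.0, 0.036, 0.0, lower_inclusive=False),
        ),
        dlp_conversion=0.018,
    )


def scheme_from_yaml(path: str | Path) -> DoseCoefficientScheme:
    """Load a coefficient scheme from a YAML file (see ``configs/dose_coefficients.yaml``)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        entries = tuple(
            ReferenceModelEntry(
                name=str(m["name"]),
                model_weight=float(m["model_weight"]),
                coefficient=float(m["coefficient"]),
                lower_bound=float(m["lower_bound"]),
                lower_inclusive=bool(m.get("lower_inclusive", False)),
            )
            for m in raw["models"]
        )
        return DoseCoefficientScheme(
            entries=entries, dlp_conversion=float(raw.get("dlp_conversion", 0.018))
        )
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(f"malformed coefficient scheme in {path}: {exc}") from exc


def scheme_to_dict(scheme: DoseCoefficientScheme) -> dict:
    return {
        "dlp_conversion": scheme.dlp_conversion,
        "models": [
            {
                "name": e.name,
                "model_weight": e.model_weight,
                "coefficient": e.coefficient,
                "lower_bound": e.lower_bound,
                "lower_inclusive": e.lower_inclusive,
            }
            for e in scheme.entries
        ],
    }


@dataclass(frozen=True)
class PatientRecord:
    """One scanned patient.

    ``height_cm`` may be ``None`` (not every study records it); everything
    else is required.  Gender is carried through for reporting only — none
    of the in-scope dose equations depend on it.
    """

    patient_id: str
    cohort: str
    weight_kg: float
    injected_activity_mbq: float
    dlp_mgycm: float
    height_cm: Optional[float] = None
    gender: str = "unknown"

    def __post_init__(self):
        _require_finite_positive("weight_kg", self.weight_kg)
        _require_finite_nonnegative("injected_activity_mbq", self.injected_activity_mbq)
        _require_finite_nonnegative("dlp_mgycm", self.dlp_mgycm)
        if self.height_cm is not None and not (
            isinstance(self.height_cm, float) and math.isnan(self.height_cm)
        ):
            _require_finite_positive("height_cm", self.height_cm)
        if self.gender not in GENDERS:
            raise InvalidInputError(f"gender must be one of {GENDERS}, got {self.gender!r}")

    @property
    def height_missing(self) -> bool:
        return self.height_cm is None or (
            isinstance(self.height_cm, float) and math.isnan(self.height_cm)
        )


@dataclass(frozen=True)
class DoseResult:
    """Per-patient effective doses (mSv) under the three PET methods.

    Blood-volume fields are ``None`` when the patient's height is missing.
    """

    patient_id: str
    model_name: str
    ed_pet: float
    ed_pet_ws: float
    ed_pet_bv: Optional[float]
    ed_ct: float
    ed_total_icrp: float
    ed_total_ws: float
    ed_total_bv: Optional[float]


def assign_reference_model(
    weight: float, scheme: DoseCoefficientScheme | None = None
) -> ReferenceModelEntry:
    """Pick the ICRP reference phantom for a patient weight.

    Bands with the default scheme: > 65 kg → 70 kg adult; [45, 65] kg →
    57 kg adult; < 45 kg → 33 kg child.  Both band edges (45 and 65 kg)
    belong to the 57 kg adult.
    """
    weight = _require_finite_positive("weight", weight)
    scheme = scheme or default_scheme()
    for entry in scheme.entries:
        if entry.matches(weight):
            return entry
    raise ConfigurationError(f"scheme does not cover weight {weight}")  # pragma: no cover


def ed_pet(injected_activity: float, coefficient: float) -> float:
    """PET effective dose in mSv: activity (MBq) times dose coefficient (mSv/MBq)."""
    injected_activity = _require_finite_nonnegative("injected_activity", injected_activity)
    coefficient = _require_finite_positive("coefficient", coefficient)
    return injected_activity * coefficient


def ed_pet_weight_scaled(ed_pet_msv: float, model_weight: float, patient_weight: float) -> float:
    """Rescale the phantom-based PET dose by model weight over patient weight."""
    _require_finite_nonnegative("ed_pet", ed_pet_msv)
    model_weight = _require_finite_positive("model_weight", model_weight)
    patient_weight = _require_finite_positive("patient_weight", patient_weight)
    return ed_pet_msv * model_weight / patient_weight


def body_mass_index(weight: float, height_cm: Optional[float]) -> Optional[float]:
    """BMI in kg/m² from weight in kg and height in cm; ``None`` when height is missing.

    A missing (or non-positive / NaN) height is a missing-data condition,
    not an error: the blood-volume pathway simply drops out for that patient.
    """
    _require_finite_positive("weight", weight)
    if height_cm is None:
        return None
    height_cm = float(height_cm)
    if not math.isfinite(height_cm) or height_cm <= 0:
        return None
    height_m = height_cm / 100.0
    return weight / (height_m * height_m)


def indexed_blood_volume(bmi: float) -> float:
    """Indexed blood volume in ml/kg: ``70 / sqrt(BMI / 22)``.

    Equals 70 ml/kg at the reference BMI of 22 kg/m² and decreases with BMI.
    """
    bmi = _require_finite_positive("bmi", bmi)
    return REFERENCE_BLOOD_VOLUME_ML_PER_KG / math.sqrt(bmi / REFERENCE_BMI)


def ed_pet_blood_volume_scaled(ed_pet_msv: float, indexed_bv: float) -> float:
    """Rescale the phantom-based PET dose by indexed blood volume over 70 ml/kg."""
    _require_finite_nonnegative("ed_pet", ed_pet_msv)
    indexed_bv = _require_finite_positive("indexed_bv", indexed_bv)
    return ed_pet_msv * indexed_bv / REFERENCE_BLOOD_VOLUME_ML_PER_KG


def ed_ct_from_dlp(dlp: float, conversion: float = 0.018) -> float:
    """CT effective dose in mSv from the dose-length product (mGy·cm)."""
    dlp = _require_finite_nonnegative("dlp", dlp)
    conversion = _require_finite_positive("conversion", conversion)
    return dlp * conversion


def ed_total(ed_ct: float, ed_pet_variant: float) -> float:
    """Total effective dose: CT plus one PET-method dose."""
    _require_finite_nonnegative("ed_ct", ed_ct)
    _require_finite_nonnegative("ed_pet_variant", ed_pet_variant)
    return ed_ct + ed_pet_variant


def dose_result_for_patient(
    record: PatientRecord, scheme: DoseCoefficientScheme | None = None
) -> DoseResult:
    """Compose the full per-patient dose result from a patient record."""
    scheme = scheme or default_scheme()
    model = assign_reference_model(record.weight_kg, scheme)
    pet = ed_pet(record.injected_activity_mbq, model.coefficient)
    pet_ws = ed_pet_weight_scaled(pet, model.model_weight, record.weight_kg)
    bmi = body_mass_index(record.weight_kg, record.height_cm)
    if bmi is None:
        pet_bv = None
        total_bv = None
    else:
        pet_bv = ed_pet_blood_volume_scaled(pet, indexed_blood_volume(bmi))
    ct = ed_ct_from_dlp(record.dlp_mgycm, scheme.dlp_conversion)
    if bmi is not None:
        total_bv = ed_total(ct, pet_bv)
    return DoseResult(
        patient_id=record.patient_id,
        model_name=model.name,
        ed_pet=pet,
        ed_pet_ws=pet_ws,
        ed_pet_bv=pet_bv,
        ed_ct=ct,
        ed_total_icrp=ed_total(ct, pet),
        ed_total_ws=ed_total(ct, pet_ws),
        ed_total_bv=total_bv,
    )
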