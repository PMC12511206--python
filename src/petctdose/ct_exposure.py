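"""CT acquisition arithmetic for the helical scanners paired with each PET system.

Covers the exposure bookkeeping that surrounds a phantom-based CT dose
calculation: total collimation (slice collimation × simultaneously acquired
channels), table feed (total collimation × pitch), recovery of the tube
current-time product from the scanner-reported CTDIvol, and the male/female
"potential error" on an effective-dose estimate made under an all-male
assumption.

CTDI relations used: CTDIvol = CTDIw / pitch, and CTDIw scales linearly
with mAs through the scanner's normalized CTDIw (mGy per 100 mAs), so

    mAs = 100 · CTDIvol · pitch / nCTDIw.

The normalized CTDIw is a scanner constant supplied by configuration, not a
measured quantity of this package.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ConfigurationError, InvalidInputError

__all__ = [
    "CTScannerConfig",
    "total_collimation",
    "table_feed",
    "mas_from_ctdivol",
    "potential_error_gender",
    "default_scanners",
    "scanners_from_yaml",
]


@dataclass(frozen=True)
class CTScannerConfig:
    """Acquisition settings for one helical CT scanner.

    ``scan_range_cm`` follows the signed convention of the phantom software:
    the vertex sits at +94 cm and caudal positions are negative; it is used
    only to report scan length.  ``normalized_ctdiw`` is mGy per 100 mAs.
    """

    scanner_name: str
    tube_voltage_kvp: float
    slice_collimation_mm: float
    active_channels: int
    pitch: float
    scan_range_cm: tuple[float, float]  # (caudal start, cranial end)
    rotation_time_s: float
    normalized_ctdiw: float

    def __post_init__(self):
        if self.pitch <= 0:
            raise ConfigurationError("pitch must be > 0")
        if self.slice_collimation_mm <= 0:
            raise ConfigurationError("slice collimation must be > 0")
        if self.active_channels < 1:
            raise ConfigurationError("active_channels must be >= 1")
        if self.scan_range_cm[1] <= self.scan_range_cm[0]:
            raise ConfigurationError("scan range end must exceed start")
        if self.normalized_ctdiw <= 0:
            raise ConfigurationError("normalized_ctdiw must be > 0")

    @property
    def total_collimation_mm(self) -> float:
        return total_collimation(self.slice_collimation_mm, self.active_channels)

    @property
    def table_feed_mm(self) -> float:
        return table_feed(self.total_collimation_mm, self.pitch)

    @property
    def scan_length_cm(self) -> float:
        return self.scan_range_cm[1] - self.scan_range_cm[0]


def total_collimation(slice_collimation_mm: float, active_channels: int) -> float:
    """Total beam collimation in mm: channel thickness times simultaneous channels."""
    if slice_collimation_mm <= 0 or active_channels <= 0:
        raise InvalidInputError("slice collimation and channel count must be positive")
    return slice_collimation_mm * active_channels


def table_feed(total_collimation_mm: float, pitch: float) -> float:
    """Table travel per rotation in mm: total collimation times pitch."""
    if total_collimation_mm <= 0 or pitch <= 0:
        raise InvalidInputError("total collimation and pitch must be positive")
    return total_collimation_mm * pitch


def mas_from_ctdivol(ctdivol: float, pitch: float, normalized_ctdiw: float) -> float:
    """Invert CTDIvol to the tube current-time product (mAs).

    Uses CTDIvol = nCTDIw · mAs / (100 · pitch); the scanner does not record
    the delivered mAs directly, so it is recovered from the reported dose
    index.
    """
    if normalized_ctdiw <= 0:
        raise ConfigurationError("normalized_ctdiw must be > 0")
    if pitch <= 0:
        raise InvalidInputError("pitch must be > 0")
    if ctdivol < 0:
        raise InvalidInputError("ctdivol must be >= 0")
    return 100.0 * ctdivol * pitch / normalized_ctdiw


def potential_error_gender(ed_male: float, ed_female: float) -> float:
    """Percent error of an all-male dose estimate relative to the female model.

    Defined as 100 · (ED_female − ED_male) / ED_female; the female model is
    the denominator because the male-model estimate is the one under audit.
    Full precision is returned; round to one decimal for reporting.
    """
    if ed_male <= 0 or ed_female <= 0:
        raise InvalidInputError("effective doses must be positive")
    return 100.0 * (ed_female - ed_male) / ed_female


# Normalized CTDIw values are not published for these systems in the source
# audit; the shipped constants are back-inferred from the all-patient median
# (mAs, CTDIvol) pair of each scanner and should be replaced with measured
# values where available.
def default_scanners() -> dict[str, CTScannerConfig]:
    """The three scanner configurations used in the audit (two mCT scan ranges)."""
    return {
        "quadra_de": CTScannerConfig(
            scanner_name="Siemens Definition Edge (Quadra)",
            tube_voltage_kvp=120.0,
            slice_collimation_mm=0.6,
            active_channels=128,
            pitch=0.8,
            scan_range_cm=(-14.0, 94.0),
            rotation_time_s=0.28,
            normalized_ctdiw=6.39,
        ),
        "mct_as_100": CTScannerConfig(
            scanner_name="Siemens Definition AS (mCT, 100 cm range)",
            tube_voltage_kvp=120.0,
            slice_collimation_mm=1.2,
            active_channels=16,
            pitch=0.8,
            scan_range_cm=(-6.0, 94.0),
            rotation_time_s=0.33,
            normalized_ctdiw=7.78,
        ),
        "mct_as_110": CTScannerConfig(
            scanner_name="Siemens Definition AS (mCT, 110 cm range)",
            tube_voltage_kvp=120.0,
            slice_collimation_mm=1.2,
            active_channels=16,
            pitch=0.8,
            scan_range_cm=(-16.0, 94.0),
            rotation_time_s=0.33,
            normalized_ctdiw=7.78,
        ),
    }


def scanners_from_yaml(path: str | Path) -> dict[str, CTScannerConfig]:
    """Load scanner configurations from YAML (see ``configs/scanners.yaml``)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    out: dict[str, CTScannerConfig] = {}
    try:
        for key, s in raw["scanners"].items():
            out[key] = CTScannerConfig(
                scanner_name=str(s["scanner_name"]),
                tube_voltage_kvp=float(s["tube_voltage_kvp"]),
                slice_collimation_mm=float(s["slice_collimation_mm"]),
                active_channels=int(s["active_channels"]),
                pitch=float(s["pitch"]),
                scan_range_cm=(float(s["scan_range_cm"][0]), float(s["scan_range_cm"][1])),
                rotation_time_s=float(s["rotation_time_s"]),
                normalized_ctdiw=float(s["normalized_ctdiw"]),
            )
    except (KeyError, TypeError, IndexError) as exc:
        raise ConfigurationError(f"malformed scanner config in {path}: {exc}") from exc
    return out
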