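"""Reading and writing patient tables (comma-separated text).

Schema (header required):
patient_id,cohort,weight_kg,height_cm,gender,injected_activity_mbq,dlp_mgycm
with height_cm left empty when unrecorded and gender one of male/female/unknown
(empty treated as unknown).
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd

from .errors import ValidationError

PATIENT_COLUMNS = [
    "patient_id",
    "cohort",
    "weight_kg",
    "height_cm",
    "gender",
    "injected_activity_mbq",
    "dlp_mgycm",
]

_NUMERIC = ["weight_kg", "height_cm", "injected_activity_mbq", "dlp_mgycm"]


def read_patient_table(path: str | Path) -> pd.DataFrame:
    """Read and schema-check a patient table; raises ValidationError with row indices."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"patient table not found: {path}")
    df = pd.read_csv(path, dtype={"patient_id": str, "cohort": str, "gender": str})
    missing = [c for c in PATIENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    for col in _NUMERIC:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["gender"] = df["gender"].fillna("unknown").replace("", "unknown")
    bad = df.index[
        df["weight_kg"].isna()
        | (df["weight_kg"] <= 0)
        | df["injected_activity_mbq"].isna()
        | (df["injected_activity_mbq"] < 0)
        | df["dlp_mgycm"].isna()
        | (df["dlp_mgycm"] < 0)
        | (df["height_cm"].notna() & (df["height_cm"] <= 0))
        | ~df["gender"].isin(["male", "female", "unknown"])
    ].tolist()
    if bad:
        raise ValidationError(f"{path}: {len(bad)} invalid rows (indices {bad[:20]}...)", rows=bad)
    return df[PATIENT_COLUMNS]


def write_patient_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
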