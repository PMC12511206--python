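"""Audit report assembly and table rendering.

`run_audit` drives the end-to-end comparison of two patient tables and
returns an :class:`AuditReport`; `render_table` turns comparison rows into
CSV, Markdown or aligned plain text.  Displayed doses are rounded to one
decimal (mSv) and significance at α = 0.05 is marked with ``*``; the CSV
written by :meth:`AuditReport.write` keeps full precision so a written
report re-reads to exactly the computed values.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .cohort_stats import (
    ComparisonRow,
    WeightCategoryScheme,
    compare_cohorts,
    ct_proportion_by_stratum,
    default_weight_categories,
    dose_table,
)
from .dosimetry import DoseCoefficientScheme, default_scheme, scheme_from_yaml, scheme_to_dict
from .errors import EmptyInputError, InvalidInputError
from .io import file_sha256, read_patient_table

logger = logging.getLogger(__name__)

__all__ = ["AuditReport", "run_audit", "render_table", "comparison_frame"]

_COLUMNS = [
    "quantity",
    "stratum",
    "n_a",
    "n_b",
    "median_a",
    "q1_a",
    "q3_a",
    "median_b",
    "q1_b",
    "q3_b",
    "percent_difference",
    "p_value",
    "significant",
]


@dataclass
class AuditReport:
    """Everything the audit computed, plus provenance metadata."""

    comparison_rows: list[ComparisonRow]
    ct_proportion_a: pd.DataFrame
    ct_proportion_b: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def comparison_frame(self) -> pd.DataFrame:
        return comparison_frame(self.comparison_rows)

    def row(self, quantity: str, stratum: str = "ALL") -> ComparisonRow:
        for r in self.comparison_rows:
            if r.quantity == quantity and r.stratum == stratum:
                return r
        raise KeyError(f"no comparison row for {quantity!r} / {stratum!r}")

    def write(self, outdir: str | Path) -> None:
        """Write comparison.csv (full precision), proportion tables, report.md, metadata.json."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.comparison_frame().to_csv(outdir / "comparison.csv", index=False)
        self.ct_proportion_a.to_csv(outdir / "ct_proportion_cohort_a.csv", index=False)
        self.ct_proportion_b.to_csv(outdir / "ct_proportion_cohort_b.csv", index=False)
        (outdir / "report.md").write_text(
            "# PET/CT effective-dose audit\n\n"
            + render_table(self.comparison_rows, style="markdown")
            + "\n"
        )
        (outdir / "metadata.json").write_text(json.dumps(self.metadata, indent=2, default=str))


def comparison_frame(rows: Sequence[ComparisonRow]) -> pd.DataFrame:
    return pd.DataFrame([{c: getattr(r, c) for c in _COLUMNS} for r in rows], columns=_COLUMNS)


def _fmt(value: Optional[float], decimals: int = 1) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ""
    return f"{value:.{decimals}f}"


def _fmt_p(p: Optional[float]) -> str:
    if p is None or (isinstance(p, float) and math.isnan(p)):
        return ""
    star = "*" if p < 0.05 else ""
    if p < 0.001:
        return f"<0.001{star}"
    return f"{p:.3g}{star}"


def render_table(rows: Sequence[ComparisonRow], style: str = "plain") -> str:
    """Render comparison rows as ``"csv"``, ``"markdown"`` or aligned ``"plain"`` text.

    Medians and IQRs are shown to one decimal, percent differences to one
    decimal, and p-values to three significant figures with ``*`` marking
    p < 0.05.  Absent statistics (e.g. blood-volume rows with no recorded
    heights) render as empty cells.
    """
    if not rows:
        raise EmptyInputError("render_table needs at least one row")
    header = [
        "Quantity",
        "Stratum",
        "n (A)",
        "Median A (IQR)",
        "n (B)",
        "Median B (IQR)",
        "Diff (%)",
        "p-value",
    ]
    body = []
    for r in rows:
        med_a = _fmt(r.median_a) and f"{_fmt(r.median_a)} ({_fmt(r.q1_a)}–{_fmt(r.q3_a)})"
        med_b = _fmt(r.median_b) and f"{_fmt(r.median_b)} ({_fmt(r.q1_b)}–{_fmt(r.q3_b)})"
        body.append(
            [
                r.quantity,
                r.stratum,
                str(r.n_a),
                med_a or "",
                str(r.n_b),
                med_b or "",
                _fmt(r.percent_difference),
                _fmt_p(r.p_value),
            ]
        )
    if style == "csv":
        lines = [",".join(header)] + [",".join(row) for row in body]
        return "\n".join(lines)
    if style == "markdown":
        widths = [max(len(h), *(len(row[i]) for row in body)) for i, h in enumerate(header)]
        def mdrow(cells):
            return "| " + " | ".join(c.ljust(w) for c, w in zip(cells, widths)) + " |"
        lines = [mdrow(header), "|" + "|".join("-" * (w + 2) for w in widths) + "|"]
        lines += [mdrow(row) for row in body]
        return "\n".join(lines)
    if style == "plain":
        widths = [max(len(h), *(len(row[i]) for row in body)) for i, h in enumerate(header)]
        lines = ["  ".join(h.ljust(w) for h, w in zip(header, widths))]
        lines += ["  ".join(c.ljust(w) for c, w in zip(row, widths)) for row in body]
        return "\n".join(lines)
    raise InvalidInputError(f"unknown table style {style!r}")


def run_audit(
    cohort_a_path: str | Path,
    cohort_b_path: str | Path,
    config_path: str | Path | None = None,
    categories: WeightCategoryScheme | None = None,
) -> AuditReport:
    """End-to-end audit of two patient tables.

    Deterministic for fixed inputs: reads both tables, computes per-patient
    doses, the stratified comparison, and the CT-share tables; metadata
    records file hashes, cohort sizes and height-exclusion counts.
    """
    scheme = scheme_from_yaml(config_path) if config_path else default_scheme()
    categories = categories or default_weight_categories()
    df_a = read_patient_table(cohort_a_path)
    df_b = read_patient_table(cohort_b_path)

    dt_a = dose_table(df_a, scheme, categories)
    dt_b = dose_table(df_b, scheme, categories)
    excl_a = int(dt_a["ed_pet_bv"].isna().sum())
    excl_b = int(dt_b["ed_pet_bv"].isna().sum())
    logger.info(
        "audit: cohort A n=%d (%d without height), cohort B n=%d (%d without height)",
        len(dt_a), excl_a, len(dt_b), excl_b,
    )
    for name, dt in (("A", dt_a), ("B", dt_b)):
        counts = dt["weight_category"].value_counts()
        for label in categories.labels:
            if counts.get(label, 0) < 5:
                logger.warning(
                    "cohort %s stratum %s has n=%d (<5): medians unstable",
                    name, label, counts.get(label, 0),
                )

    rows = compare_cohorts(df_a, df_b, scheme, categories)
    report = AuditReport(
        comparison_rows=rows,
        ct_proportion_a=ct_proportion_by_stratum(dt_a, categories),
        ct_proportion_b=ct_proportion_by_stratum(dt_b, categories),
        metadata={
            "package_version": __version__,
            "cohort_a": {
                "path": str(cohort_a_path),
                "sha256": file_sha256(cohort_a_path),
                "n": len(dt_a),
                "n_height_missing": excl_a,
            },
            "cohort_b": {
                "path": str(cohort_b_path),
                "sha256": file_sha256(cohort_b_path),
                "n": len(dt_b),
                "n_height_missing": excl_b,
            },
            "scheme": scheme_to_dict(scheme),
            "weight_categories": [b.label for b in categories.bins],
        },
    )
    return report
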