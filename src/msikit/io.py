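"""Case-record CSV reading/writing and report serialization.

The case-record CSV has one row per case with a fixed, documented header:

- ``case_id`` (string, mandatory)
- one 0/1 column per marker id (``shock``, ``cpr``, ... -- see
  :data:`msikit.markers.MARKER_IDS`)
- optional raw-lab columns (``creatinine_umol_l``, ``creatinine_mg_dl``,
  ``bilirubin_umol_l``, ``bilirubin_mg_dl``, ``ph``, ``lactate_mmol_l``,
  ``platelets_per_ul``, ``resp_rate_per_min``, ``spo2_pct``,
  ``pao2_fio2_mmhg``): positive values materialize the corresponding marker
- boolean flags ``early_identification``, ``severe_preeclampsia``,
  ``cancer``, ``hysterectomy``, ``died`` (accepted spellings:
  0/1/true/false/yes/no, case-insensitive)
- optional ``stratum`` (facility or period label for benchmarking)

Unknown columns are ignored with a logged warning; malformed rows are
aggregated into one structured error report with row numbers.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
import math
from pathlib import Path
from typing import Sequence

import pandas as pd

from .markers import CATALOG, MARKER_IDS, CaseRecord

logger = logging.getLogger(__name__)

__all__ = ["read_cases", "write_cases", "write_report", "RAW_LAB_COLUMNS"]

#: CSV column -> (analyte, unit) accepted by evaluate_lab_marker.
RAW_LAB_COLUMNS: dict[str, tuple[str, str]] = {
    "creatinine_umol_l": ("creatinine", "umol/l"),
    "creatinine_mg_dl": ("creatinine", "mg/dl"),
    "bilirubin_umol_l": ("bilirubin", "umol/l"),
    "bilirubin_mg_dl": ("bilirubin", "mg/dl"),
    "ph": ("ph", ""),
    "lactate_mmol_l": ("lactate", "mmol/l"),
    "platelets_per_ul": ("platelets", "per-ul"),
    "resp_rate_per_min": ("respiratory_rate", "/min"),
    "spo2_pct": ("spo2", "%"),
    "pao2_fio2_mmhg": ("pao2_fio2", "mmhg"),
}

_FLAG_COLUMNS = (
    "early_identification",
    "severe_preeclampsia",
    "cancer",
    "hysterectomy",
    "died",
)

_TRUE = {"1", "true", "yes"}
_FALSE = {"0", "false", "no", ""}

#: Marker column order used on write (catalog order).
_MARKER_ORDER = [m.marker_id for m in CATALOG]


def _parse_bool(raw: object, column: str) -> bool:
    if isinstance(raw, bool):
        return raw
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return False
    text = str(raw).strip().lower()
    if text.endswith(".0"):
        text = text[:-2]
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    raise ValueError(f"unparseable boolean {raw!r} in column {column!r}")


def read_cases(path: str | Path) -> list[CaseRecord]:
    """Read and validate a case-record CSV.

    Raw labs are materialized into markers on construction.  All row-level
    problems are collected and raised together as one ValueError listing the
    offending rows.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "case_id" not in df.columns:
        raise ValueError(f"{path}: missing mandatory column 'case_id'")
    known = (
        {"case_id", "stratum"}
        | MARKER_IDS
        | set(RAW_LAB_COLUMNS)
        | set(_FLAG_COLUMNS)
    )
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        logger.warning("%s: ignoring unknown columns %s", path, unknown)
    if df.empty:
        logger.warning("%s: file contains zero data rows", path)
        return []

    cases: list[CaseRecord] = []
    errors: list[str] = []
    marker_cols = [c for c in df.columns if c in MARKER_IDS]
    lab_cols = [c for c in df.columns if c in RAW_LAB_COLUMNS]
    flag_cols = [c for c in df.columns if c in _FLAG_COLUMNS]
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header=1
        rec = row._asdict()
        try:
            markers = {
                c for c in marker_cols if _parse_bool(rec[c], c)
            }
            labs: dict[str, tuple[float, str]] = {}
            for c in lab_cols:
                raw = str(rec[c]).strip()
                if not raw:
                    continue
                value = float(raw)
                if value < 0:
                    raise ValueError(f"negative lab value {value} in {c!r}")
                analyte, unit = RAW_LAB_COLUMNS[c]
                labs[analyte] = (value, unit)
            flags = {c: _parse_bool(rec.get(c, False), c) for c in flag_cols}
            cases.append(
                CaseRecord(
                    case_id=str(rec["case_id"]),
                    markers_present=markers,
                    raw_labs=labs or None,
                    stratum=(str(rec["stratum"]) or None)
                    if "stratum" in rec
                    else None,
                    **{k: flags.get(k, False) for k in _FLAG_COLUMNS},
                )
            )
        except (ValueError, KeyError) as exc:
            errors.append(f"row {i}: {exc}")
    if errors:
        raise ValueError(
            f"{path}: {len(errors)} invalid row(s):\n" + "\n".join(errors)
        )
    return cases


def write_cases(cohort: Sequence[CaseRecord], path: str | Path) -> None:
    """Write a cohort in the standard case-record CSV layout."""
    columns = ["case_id", *_MARKER_ORDER, *_FLAG_COLUMNS, "stratum"]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, quoting=csv.QUOTE_MINIMAL)
        writer.writerow(columns)
        for c in cohort:
            writer.writerow(
                [c.case_id]
                + [int(m in c.markers_present) for m in _MARKER_ORDER]
                + [
                    int(c.early_identification),
                    int(c.severe_preeclampsia),
                    int(c.cancer),
                    int(c.hysterectomy),
                    int(c.died),
                ]
                + [c.stratum or ""]
            )


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        if hasattr(obj, "to_dict"):
            return _jsonable(obj.to_dict())
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, float) and not math.isfinite(obj):
        return None if math.isnan(obj) else ("inf" if obj > 0 else "-inf")
    if hasattr(obj, "item"):  # numpy scalars
        return obj.item()
    return obj


def write_report(report, path: str | Path, format: str = "json") -> None:
    """Serialize a report dict/dataclass/DataFrame to json, csv or txt.

    JSON keeps full numeric precision with stable key ordering; csv expects
    tabular content; txt applies display rounding (3 significant digits for
    probabilities, 1 decimal for ratios).
    """
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(_jsonable(report), indent=2, sort_keys=True))
    elif format == "csv":
        if isinstance(report, pd.DataFrame):
            report.to_csv(path, index=False)
        else:
            flat = _jsonable(report)
            if not isinstance(flat, dict):
                raise ValueError("csv format needs a DataFrame or flat dict")
            pd.DataFrame([flat]).to_csv(path, index=False)
    elif format == "txt":
        lines = _render_txt(_jsonable(report))
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown report format {format!r}")


def _fmt(v) -> str:
    if isinstance(v, float):
        if v == 0:
            return "0"
        if abs(v) < 0.1:
            return f"{v:.3g}"
        return f"{v:.1f}"
    return str(v)


def _render_txt(obj, indent: int = 0) -> list[str]:
    pad = "  " * indent
    lines: list[str] = []
    if isinstance(obj, dict):
        for k, v in obj.items():
            if isinstance(v, (dict, list)):
                lines.append(f"{pad}{k}:")
                lines.extend(_render_txt(v, indent + 1))
            else:
                lines.append(f"{pad}{k}: {_fmt(v)}")
    elif isinstance(obj, list):
        for v in obj:
            lines.extend(_render_txt(v, indent))
            lines.append("")
    else:
        lines.append(f"{pad}{_fmt(obj)}")
    return lines
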