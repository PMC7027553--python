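"""Study-table CSV input/output and arm-statistic normalization.

The table carries one row per (study x response x stratum) comparison.
Dispersion may arrive as SD or SE (exactly one per arm); normalization
converts SE to SD with ``sd = se * sqrt(n)`` so downstream code only ever
sees SDs. Files are plain comma-separated UTF-8 with '.' decimals and empty
cells for missing values.
"""

from __future__ import annotations

import math
from typing import Iterable, List, Optional

import pandas as pd

from .errors import InvalidInputError, SchemaError
from .types import StudyRecord, _is_missing

#: canonical column order for study tables
COLUMNS = [
    "study_id", "dataset_id", "response",
    "mean_w", "sd_w", "se_w", "n_w",
    "mean_c", "sd_c", "se_c", "n_c",
    "latitude_deg", "mat_c", "map_mm", "depth_cm",
    "delta_t", "duration_yr", "moisture_effect",
    "control_cluster",
]

REQUIRED_COLUMNS = [
    "study_id", "dataset_id", "response",
    "mean_w", "n_w", "mean_c", "n_c",
    "latitude_deg", "mat_c", "map_mm", "control_cluster",
]

_TEXT_COLUMNS = {"study_id", "dataset_id", "response", "control_cluster"}
_INT_COLUMNS = {"n_w", "n_c"}
_OPTIONAL_NUMERIC = {"sd_w", "se_w", "sd_c", "se_c", "depth_cm",
                     "delta_t", "duration_yr", "moisture_effect"}


def se_to_sd(se: float, n: int) -> float:
    """Convert a standard error to a standard deviation: ``se * sqrt(n)``."""
    if se is None or not math.isfinite(float(se)) or float(se) < 0:
        raise InvalidInputError(f"se must be finite and >= 0, got {se}")
    if n is None or int(n) < 1 or int(n) != n:
        raise InvalidInputError(f"n must be an integer >= 1, got {n}")
    return float(se) * math.sqrt(int(n))


def normalize_record(record: StudyRecord) -> StudyRecord:
    """Fill SDs from SEs in place; after this both arms carry an SD."""
    for arm in ("w", "c"):
        sd = getattr(record, f"sd_{arm}")
        se = getattr(record, f"se_{arm}")
        if _is_missing(sd):
            if _is_missing(se):
                raise SchemaError(f"record {record.ref}: neither sd_{arm} nor se_{arm} present")
            setattr(record, f"sd_{arm}", se_to_sd(se, getattr(record, f"n_{arm}")))
            setattr(record, f"se_{arm}", None)
        elif not _is_missing(se):
            raise SchemaError(f"record {record.ref}: both sd_{arm} and se_{arm} present")
    return record


def _parse_cell(raw, column: str, row_number: int):
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    text = str(raw).strip()
    if text == "":
        return None
    if column in _TEXT_COLUMNS:
        return text
    try:
        value = float(text)
    except ValueError:
        raise SchemaError(f"row {row_number}: non-numeric value {text!r} in column {column!r}")
    if column in _INT_COLUMNS:
        if value != int(value) or value < 1:
            raise SchemaError(f"row {row_number}: column {column!r} must be an integer >= 1, got {text!r}")
        return int(value)
    return value


def read_study_table(path, normalize: bool = True) -> List[StudyRecord]:
    """Read a study-level CSV into normalized :class:`StudyRecord` objects.

    Raises :class:`SchemaError` (with 1-based data row numbers) on missing
    required columns, non-numeric arm statistics, duplicate
    (dataset_id, response, depth) keys, or inconsistent control clusters.
    """
    frame = pd.read_csv(path, dtype=object, keep_default_na=False, na_values=[""])
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    records: List[StudyRecord] = []
    seen_keys = {}
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        data = {}
        for column in COLUMNS:
            raw = getattr(row, column, None) if column in frame.columns else None
            data[column] = _parse_cell(raw, column, i)
        for column in REQUIRED_COLUMNS:
            if data[column] is None:
                raise SchemaError(f"row {i}: required column {column!r} is empty")
        record = StudyRecord(**data)
        key = record.key
        if key in seen_keys:
            raise SchemaError(
                f"row {i}: duplicate (dataset_id, response, depth) key {key} "
                f"(first seen at row {seen_keys[key]})"
            )
        seen_keys[key] = i
        if normalize:
            try:
                normalize_record(record)
            except SchemaError as exc:
                raise SchemaError(f"row {i}: {exc}") from None
        records.append(record)
    _check_clusters(records)
    return records


def _check_clusters(records: Iterable[StudyRecord]) -> None:
    control_arms = {}
    for record in records:
        arm = (record.mean_c, record.sd_c, record.n_c)
        prior = control_arms.setdefault(record.control_cluster, arm)
        if prior != arm:
            raise SchemaError(
                f"control cluster {record.control_cluster!r}: inconsistent control arms "
                f"{prior} vs {arm}"
            )


def write_study_table(records: Iterable[StudyRecord], path) -> None:
    """Write records to CSV in canonical column order (empty cell = missing)."""
    rows = []
    for record in records:
        rows.append({c: getattr(record, c) for c in COLUMNS})
    frame = pd.DataFrame(rows, columns=COLUMNS)
    frame.to_csv(path, index=False)
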