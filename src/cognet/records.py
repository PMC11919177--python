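"""Respondent-level records: containers, CSV round-trip, scoring.

A :class:`RawRecord` holds one respondent's item responses for one wave
together with the record-validity fields (lie-item correctness, total
response time, age, grade, demographics) used by the screening filters.
The on-disk format is a wide CSV, one row per respondent-wave:

``code, wave, phq_1..phq_9, gad_1..gad_7, rrs_1..rrs_22, anis_1..anis_10,
atq_1..atq_8, rt_s, lie_ok, age, grade, <demographic columns...>``

Missing entries are empty cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .scales import CONSTRUCTS, DEFAULT_SCALES, ScaleDefinition

WAVES = ("T1", "T2")

#: Demographic columns written/read by default (all free-form strings).
DEFAULT_DEMOGRAPHICS = ("sex", "residence")


@dataclass
class RawRecord:
    """One respondent-wave: item responses plus validity fields."""

    code: str
    wave: str
    responses: dict[str, list[int | None]]
    response_time_s: float | None = None
    lie_ok: bool | None = None
    age: float | None = None
    grade: int | None = None
    demographics: dict[str, object] = field(default_factory=dict)

    def has_missing_items(self) -> bool:
        return any(
            v is None for items in self.responses.values() for v in items
        )


def score_record(
    record: RawRecord,
    scales: tuple[ScaleDefinition, ...] = DEFAULT_SCALES,
) -> dict[str, int]:
    """Score one record into its construct totals.

    Totals are plain item sums; RRS items are split across the three
    rumination subscales.  Raises
    :class:`~cognet.scales.MissingItemError` if an item is absent.
    """
    out: dict[str, int] = {}
    for scale in scales:
        responses = record.responses.get(scale.name)
        if responses is None:
            responses = [None] * scale.n_items
        out.update(scale.score(responses))
    return out


def score_wave(
    records: list[RawRecord],
    scales: tuple[ScaleDefinition, ...] = DEFAULT_SCALES,
) -> pd.DataFrame:
    """Score a list of same-wave records into a construct table.

    Returns a DataFrame indexed by respondent code with one column per
    construct (PHQ, GAD, SR, BD, RP, NA, NAT by default).
    """
    rows = {r.code: score_record(r, scales) for r in records}
    df = pd.DataFrame.from_dict(rows, orient="index")
    if df.empty:
        df = pd.DataFrame(columns=list(CONSTRUCTS))
    df.index.name = "code"
    return df[[c for s in scales for c in s.constructs]]


def _item_columns(
    scales: tuple[ScaleDefinition, ...]
) -> list[tuple[str, int]]:
    return [(s.name, i) for s in scales for i in range(1, s.n_items + 1)]


def records_to_frame(
    records: list[RawRecord],
    scales: tuple[ScaleDefinition, ...] = DEFAULT_SCALES,
) -> pd.DataFrame:
    """Flatten records into the wide CSV layout."""
    demo_keys: list[str] = []
    for r in records:
        for k in r.demographics:
            if k not in demo_keys:
                demo_keys.append(k)
    rows = []
    for r in records:
        row: dict[str, object] = {"code": r.code, "wave": r.wave}
        for scale in scales:
            items = r.responses.get(scale.name, [None] * scale.n_items)
            for i in range(1, scale.n_items + 1):
                row[f"{scale.name}_{i}"] = items[i - 1]
        row["rt_s"] = r.response_time_s
        row["lie_ok"] = (
            None if r.lie_ok is None else int(r.lie_ok)
        )
        row["age"] = r.age
        row["grade"] = r.grade
        for k in demo_keys:
            row[k] = r.demographics.get(k)
        rows.append(row)
    cols = (
        ["code", "wave"]
        + [f"{s}_{i}" for s, i in _item_columns(scales)]
        + ["rt_s", "lie_ok", "age", "grade"]
        + demo_keys
    )
    return pd.DataFrame(rows, columns=cols)


def frame_to_records(
    df: pd.DataFrame,
    scales: tuple[ScaleDefinition, ...] = DEFAULT_SCALES,
) -> list[RawRecord]:
    """Inverse of :func:`records_to_frame`; blanks become missing."""
    fixed = {"code", "wave", "rt_s", "lie_ok", "age", "grade"}
    item_cols = {f"{s}_{i}" for s, i in _item_columns(scales)}
    demo_keys = [
        c for c in df.columns if c not in fixed and c not in item_cols
    ]
    records: list[RawRecord] = []
    for _, row in df.iterrows():
        responses: dict[str, list[int | None]] = {}
        for scale in scales:
            vals: list[int | None] = []
            for i in range(1, scale.n_items + 1):
                v = row.get(f"{scale.name}_{i}")
                vals.append(None if pd.isna(v) else int(v))
            responses[scale.name] = vals
        lie = row.get("lie_ok")
        rt = row.get("rt_s")
        age = row.get("age")
        grade = row.get("grade")
        records.append(
            RawRecord(
                code=str(row["code"]),
                wave=str(row["wave"]),
                responses=responses,
                response_time_s=None if pd.isna(rt) else float(rt),
                lie_ok=None if pd.isna(lie) else bool(int(lie)),
                age=None if pd.isna(age) else float(age),
                grade=None if pd.isna(grade) else int(grade),
                demographics={
                    k: (None if pd.isna(row[k]) else row[k])
                    for k in demo_keys
                },
            )
        )
    return records


def write_records_csv(
    records: list[RawRecord],
    path: str | Path,
    scales: tuple[ScaleDefinition, ...] = DEFAULT_SCALES,
) -> None:
    records_to_frame(records, scales).to_csv(path, index=False)


def read_records_csv(
    path: str | Path,
    scales: tuple[ScaleDefinition, ...] = DEFAULT_SCALES,
) -> list[RawRecord]:
    # keep_default_na=False so a demographic literally spelled "NA" (the
    # negative-attention label never collides, but values might) stays a
    # string; empty cells are the only missing marker.
    df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    return frame_to_records(df, scales)
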