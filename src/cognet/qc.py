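"""Record-validity screening and cross-wave matching.

Questionnaires are excluded, in a fixed order so the per-reason counts
are reproducible, when:

1. the record cannot be scored at all ("unparseable");
2. a lie-detection item was answered incorrectly;
3. one or more item responses are missing;
4. the total response time is under 8 minutes (480 s, strict);
5. the reported age falls outside the eligible range (18-24 by
   default; an age/grade consistency table can be supplied);
6. any construct total is a within-wave outlier (default |z| > 3);
7. any demographic field is missing.

Each excluded record is attributed to the *first* reason that fires,
so ``n_input == n_retained + sum(exclusions.values())`` always holds.

Outlier z-scores are computed over every record in the wave whose
responses are complete — not just over survivors of the earlier
filters — so the outlier flag does not depend on the filter order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import RawRecord, score_record, score_wave
from .scales import DEFAULT_SCALES, MissingItemError, ScaleDefinition

#: Exclusion reasons in the order they are tested.
REASONS = (
    "unparseable",
    "lie",
    "missing",
    "fast",
    "age_grade",
    "outlier",
    "demographic",
)


@dataclass(frozen=True)
class QCConfig:
    """Thresholds for the record-validity filters."""

    min_response_time_s: float = 480.0
    outlier_z: float = 3.0
    age_range: tuple[float, float] = (18.0, 24.0)
    #: Optional map grade -> (min age, max age); when given it replaces
    #: the flat age range for records that carry a grade.
    age_by_grade: dict[int, tuple[float, float]] | None = None
    require_demographics: bool = True


@dataclass
class QCReport:
    """Outcome of screening one wave."""

    n_input: int
    n_retained: int
    exclusions: dict[str, int]
    retained_codes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "exclusions": dict(self.exclusions),
            "retained_codes": list(self.retained_codes),
        }


def _age_ok(record: RawRecord, config: QCConfig) -> bool:
    if record.age is None:
        return False
    if config.age_by_grade is not None and record.grade is not None:
        rng = config.age_by_grade.get(record.grade)
        if rng is not None:
            return rng[0] <= record.age <= rng[1]
    lo, hi = config.age_range
    return lo <= record.age <= hi


def _outlier_flags(
    records: list[RawRecord],
    scales: tuple[ScaleDefinition, ...],
    z_threshold: float,
) -> dict[int, bool]:
    """Flag records whose any construct total has |z| > threshold.

    The reference pool is every scoreable (complete-response) record in
    the wave; z uses the population standard deviation.
    """
    scoreable: dict[int, dict[str, int]] = {}
    for idx, r in enumerate(records):
        try:
            scoreable[idx] = score_record(r, scales)
        except (MissingItemError, ValueError):
            continue
    flags = {idx: False for idx in scoreable}
    if len(scoreable) < 2:
        return flags
    table = pd.DataFrame.from_dict(scoreable, orient="index")
    mean = table.mean(axis=0)
    sd = table.std(axis=0, ddof=0)
    for construct in table.columns:
        if sd[construct] == 0:
            continue
        z = (table[construct] - mean[construct]) / sd[construct]
        for idx in table.index[np.abs(z.to_numpy()) > z_threshold]:
            flags[idx] = True
    return flags


def apply_qc(
    records: list[RawRecord],
    config: QCConfig = QCConfig(),
    scales: tuple[ScaleDefinition, ...] = DEFAULT_SCALES,
) -> tuple[list[RawRecord], QCReport]:
    """Screen one wave's records; returns (retained, report)."""
    exclusions = {reason: 0 for reason in REASONS}
    outlier = _outlier_flags(records, scales, config.outlier_z)
    retained: list[RawRecord] = []
    for idx, r in enumerate(records):
        reason = None
        if not isinstance(r.responses, dict):
            reason = "unparseable"
        elif r.lie_ok is False or r.lie_ok is None:
            reason = "lie"
        elif r.has_missing_items():
            reason = "missing"
        elif (
            r.response_time_s is None
            or r.response_time_s < config.min_response_time_s
        ):
            reason = "fast"
        elif not _age_ok(r, config):
            reason = "age_grade"
        elif outlier.get(idx, False):
            reason = "outlier"
        elif config.require_demographics and (
            not r.demographics
            or any(v is None for v in r.demographics.values())
        ):
            reason = "demographic"
        if reason is None:
            retained.append(r)
        else:
            exclusions[reason] += 1
    report = QCReport(
        n_input=len(records),
        n_retained=len(retained),
        exclusions={k: v for k, v in exclusions.items() if v > 0},
        retained_codes=[r.code for r in retained],
    )
    return retained, report


@dataclass
class PairedScores:
    """Construct scores for respondents present at both waves.

    ``t1`` and ``t2`` share an identical index (the matched codes in
    T1 order).
    """

    t1: pd.DataFrame
    t2: pd.DataFrame
    n_t1_only: int
    n_t2_only: int

    @property
    def n_matched(self) -> int:
        return len(self.t1)


def match_waves(
    t1_records: list[RawRecord],
    t2_records: list[RawRecord],
    scales: tuple[ScaleDefinition, ...] = DEFAULT_SCALES,
) -> PairedScores:
    """Inner-join two waves of retained records on respondent code."""
    for wave, recs in (("T1", t1_records), ("T2", t2_records)):
        codes = [r.code for r in recs]
        if len(codes) != len(set(codes)):
            dupes = sorted(
                {c for c in codes if codes.count(c) > 1}
            )
            raise ValueError(f"duplicate codes within {wave}: {dupes}")
    s1 = score_wave(t1_records, scales)
    s2 = score_wave(t2_records, scales)
    matched = [c for c in s1.index if c in set(s2.index)]
    return PairedScores(
        t1=s1.loc[matched],
        t2=s2.loc[matched],
        n_t1_only=len(s1) - len(matched),
        n_t2_only=len(s2) - len(matched),
    )
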