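"""Questionnaire cohort and 7-day bookkeeping diaries.

Participants report demographics (sex, body weight, height, age, education,
region, habitual dining places); food intake is recorded with the bookkeeping
method over a fixed 7-day window including the weekend. The diary is the
quantitative source of the intake rate IR (kg/day per food category) that
feeds the exposure calculation; the body weight BW enters the same formula.
Dietary-frequency answers are carried as metadata only — no frequency-to-mass
mapping is defined, so diaries alone drive IR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyInputError, IntegrityError, ParameterError, SchemaError

SEXES = ("male", "female")
EDUCATIONS = ("junior_college", "bachelor", "postgraduate")
REGIONS = ("core", "peripheral")

#: Printed labels used in subgroup tables, in fixed presentation order.
PARTITION_LABELS: dict[str, list[tuple[str, str]]] = {
    "region": [("core", "Core district"), ("peripheral", "Peripheral areas")],
    "sex": [("male", "Male"), ("female", "Female")],
    "education": [
        ("junior_college", "Junior college"),
        ("bachelor", "Bachelor"),
        ("postgraduate", "Postgraduate"),
    ],
}

COHORT_COLUMNS = (
    "id",
    "sex",
    "body_weight_kg",
    "height_cm",
    "age_years",
    "education",
    "region",
    "dining_places",
)
DIARY_COLUMNS = ("participant_id", "day_index", "food_category", "mass_consumed_kg")

DEFAULT_WEIGHT_WINDOW = (30.0, 150.0)  # kg; sanity window, configurable


@dataclass(frozen=True)
class Participant:
    id: str
    sex: str
    body_weight: float  # kg
    height: float  # cm
    age: float  # years
    education: str
    region: str
    dining_places: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.education not in EDUCATIONS:
            raise ValueError(f"education must be one of {EDUCATIONS}, got {self.education!r}")
        if self.region not in REGIONS:
            raise ValueError(f"region must be one of {REGIONS}, got {self.region!r}")
        if not self.body_weight > 0:
            raise ValueError(f"body_weight must be positive, got {self.body_weight!r}")


@dataclass(frozen=True)
class DiaryEntry:
    participant_id: str
    day_index: int  # 1..7
    food_category: str
    mass_consumed: float  # kg

    def __post_init__(self) -> None:
        if not 1 <= self.day_index:
            raise ValueError(f"day_index must be >= 1, got {self.day_index}")
        if self.mass_consumed < 0:
            raise ValueError(f"mass_consumed must be >= 0, got {self.mass_consumed}")


@dataclass(frozen=True)
class IntakeProfile:
    """Per-person mean daily intake per food category (kg/day)."""

    participant_id: str
    intake_rate_by_category: Mapping[str, float]

    def rate(self, category: str) -> float:
        return self.intake_rate_by_category.get(category, 0.0)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding, matching printed survey percentages."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _check_columns(df: pd.DataFrame, required: Sequence[str], path: Path) -> pd.DataFrame:
    lookup = {str(c).strip().lower(): c for c in df.columns}
    for col in required:
        if col not in lookup:
            raise SchemaError(f"required column {col!r} missing from {path}")
    return df.rename(columns={lookup[c]: c for c in required})


def read_cohort(
    cohort_path: str | Path,
    diary_path: str | Path,
    weight_window: tuple[float, float] = DEFAULT_WEIGHT_WINDOW,
) -> tuple[list[Participant], list[DiaryEntry]]:
    """Read the participant and diary tables and check referential integrity.

    Every diary row must reference a listed participant; orphan rows raise an
    :class:`IntegrityError` naming the offending ids. Body weights outside
    ``weight_window`` load with a validation warning (they may be legitimate
    but are flagged for review). Participants with no diary rows are retained;
    they resolve to an all-zero intake profile downstream.
    """
    cohort_path, diary_path = Path(cohort_path), Path(diary_path)
    try:
        cdf = pd.read_csv(cohort_path, sep=None, engine="python", dtype=str, comment="#")
        ddf = pd.read_csv(diary_path, sep=None, engine="python", dtype=str, comment="#")
    except pd.errors.EmptyDataError as e:
        raise EmptyInputError(str(e)) from None
    cdf = _check_columns(cdf, COHORT_COLUMNS, cohort_path)
    ddf = _check_columns(ddf, DIARY_COLUMNS, diary_path)

    participants = []
    lo, hi = weight_window
    for _, row in cdf.iterrows():
        bw = float(row["body_weight_kg"])
        if not lo <= bw <= hi:
            warnings.warn(
                f"participant {row['id']}: body weight {bw} kg outside sanity window "
                f"[{lo}, {hi}]",
                stacklevel=2,
            )
        places = row["dining_places"]
        participants.append(
            Participant(
                id=str(row["id"]),
                sex=str(row["sex"]).strip().lower(),
                body_weight=bw,
                height=float(row["height_cm"]),
                age=float(row["age_years"]),
                education=str(row["education"]).strip().lower(),
                region=str(row["region"]).strip().lower(),
                dining_places=tuple(str(places).split(";")) if pd.notna(places) and str(places) else (),
            )
        )

    known = {p.id for p in participants}
    orphans = sorted(set(ddf["participant_id"].astype(str)) - known)
    if orphans:
        raise IntegrityError(f"diary rows reference unknown participant ids: {orphans}")

    diary = [
        DiaryEntry(
            participant_id=str(row["participant_id"]),
            day_index=int(row["day_index"]),
            food_category=str(row["food_category"]).strip(),
            mass_consumed=float(row["mass_consumed_kg"]),
        )
        for _, row in ddf.iterrows()
    ]
    return participants, diary


def write_cohort(participants: Sequence[Participant], path: str | Path) -> None:
    pd.DataFrame(
        {
            "id": [p.id for p in participants],
            "sex": [p.sex for p in participants],
            "body_weight_kg": [p.body_weight for p in participants],
            "height_cm": [p.height for p in participants],
            "age_years": [p.age for p in participants],
            "education": [p.education for p in participants],
            "region": [p.region for p in participants],
            "dining_places": [";".join(p.dining_places) for p in participants],
        }
    ).to_csv(path, index=False)


def write_diary(entries: Sequence[DiaryEntry], path: str | Path) -> None:
    pd.DataFrame(
        {
            "participant_id": [e.participant_id for e in entries],
            "day_index": [e.day_index for e in entries],
            "food_category": [e.food_category for e in entries],
            "mass_consumed_kg": [e.mass_consumed for e in entries],
        }
    ).to_csv(path, index=False)


def diary_to_intake(
    diary: Iterable[DiaryEntry],
    n_days: int = 7,
    participant_ids: Iterable[str] | None = None,
) -> dict[str, IntakeProfile]:
    """Convert diary entries into per-person intake rates.

    IR(category) = total mass consumed in that category / ``n_days``. The
    divisor is always the full observation window — days without entries count
    as zero-consumption days, which is what a fixed 7-day bookkeeping window
    implies. ``participant_ids``, when given, guarantees an (possibly empty)
    profile for every listed person.
    """
    if n_days <= 0:
        raise ParameterError(f"n_days must be >= 1, got {n_days}")
    totals: dict[str, dict[str, float]] = {}
    if participant_ids is not None:
        for pid in participant_ids:
            totals[str(pid)] = {}
    for e in diary:
        cat_totals = totals.setdefault(e.participant_id, {})
        cat_totals[e.food_category] = cat_totals.get(e.food_category, 0.0) + e.mass_consumed
    return {
        pid: IntakeProfile(pid, {cat: m / n_days for cat, m in cats.items()})
        for pid, cats in totals.items()
    }


@dataclass(frozen=True)
class CohortSummary:
    """Demographic margins: counts/percentages plus continuous-attribute ranges."""

    n: int
    categorical: Mapping[str, list[tuple[str, int, float]]]  # field -> [(label, count, pct)]
    continuous: Mapping[str, tuple[float, float, float]]  # field -> (mean, min, max)


def summarize_cohort(participants: Sequence[Participant]) -> CohortSummary:
    """Counts and half-up 2-decimal percentages for region/sex/education,
    mean/min/max for weight, height, age."""
    if not participants:
        raise EmptyInputError("empty cohort")
    n = len(participants)
    categorical: dict[str, list[tuple[str, int, float]]] = {}
    for key, labels in PARTITION_LABELS.items():
        rows = []
        for value, label in labels:
            count = sum(getattr(p, key) == value for p in participants)
            rows.append((label, count, round_half_up(100.0 * count / n, 2)))
        categorical[key] = rows
    continuous = {}
    for key in ("body_weight", "height", "age"):
        x = np.asarray([getattr(p, key) for p in participants], dtype=float)
        continuous[key] = (float(np.mean(x)), float(np.min(x)), float(np.max(x)))
    return CohortSummary(n=n, categorical=categorical, continuous=continuous)


def subgroup_partition(
    participants: Sequence[Participant], keys: Sequence[str]
) -> dict[str, list[Participant]]:
    """Partition the cohort by demographic keys, plus the 'All' pseudo-group.

    ``keys`` are drawn from {region, sex, education}. For each key the labelled
    groups are disjoint and exhaustive; 'All' always comes first.
    """
    for key in keys:
        if key not in PARTITION_LABELS:
            raise ParameterError(
                f"unknown partition key {key!r}; valid keys: {sorted(PARTITION_LABELS)}"
            )
    out: dict[str, list[Participant]] = {"All": list(participants)}
    for key in keys:
        for value, label in PARTITION_LABELS[key]:
            out[label] = [p for p in participants if getattr(p, key) == value]
    return out
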