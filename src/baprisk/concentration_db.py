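"""Food-contaminant concentration table: reading, validation, summaries, group tests.

The table mirrors a literature-compiled database of benzo[a]pyrene (BaP)
measurements in foods. Each row is one measured sample: the food category, the
substance, where and when it was detected, the concentration in ug per kg of
food, the applicable national limit (GB 2762-2017 style, ug/kg), and a free-text
source. Concentrations stay in ug/kg throughout this module; unit conversion to
the ng-scale exposure quantities happens in the exposure layer.
"""

from __future__ import annotations


import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .errors import EmptyInputError, InsufficientDataError, SchemaError

#: Canonical column names of the concentration table (order-insensitive on read).
REQUIRED_COLUMNS = (
    "food_category",
    "substance",
    "site",
    "detection_time",
    "concentration_ug_per_kg",
    "national_limit_ug_per_kg",
    "source",
)


@dataclass(frozen=True)
class ConcentrationRecord:
    """One measured contaminant concentration in one food sample.

    Parameters
    ----------
    food_category:
        Food group label, e.g. ``"olive oil"`` or ``"fried meat products"``.
    concentration:
        Measured mass fraction in ug per kg food; must be non-negative.
    national_limit:
        Regulatory maximum for this food class in ug/kg, or ``None`` when no
        limit applies. Limits travel with the record because they differ by
        food class (grain/meat/aquatic 5.0, oils 10.0 under GB 2762-2017).
    """

    food_category: str
    concentration: float
    substance: str = "BaP"
    site: str = ""
    detection_time: str = ""
    national_limit: float | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.concentration) or self.concentration < 0:
            raise ValueError(
                f"concentration must be a non-negative finite number, got {self.concentration!r}"
            )
        if self.national_limit is not None and not self.national_limit > 0:
            raise ValueError(f"national_limit must be positive, got {self.national_limit!r}")

    @property
    def exceeds_limit(self) -> bool:
        """True when the concentration is strictly above the record's limit."""
        return self.national_limit is not None and self.concentration > self.national_limit


@dataclass(frozen=True)
class FoodCategoryStats:
    """Per-category descriptive statistics of measured concentrations (ug/kg)."""

    food_category: str
    n: int
    mean: float
    median: float
    min: float
    max: float
    sd: float
    n_exceeding_limit: int


@dataclass(frozen=True)
class GroupComparison:
    """Welch two-sample t-test result between two concentration samples."""

    statistic: float
    pvalue: float
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.pvalue < self.alpha


def _normalise_header(columns: Iterable[str]) -> dict[str, str]:
    return {str(c).strip().lower(): c for c in columns}


def read_concentration_db(
    path: str | Path, dialect: str | None = None
) -> tuple[list[ConcentrationRecord], int]:
    """Read a delimited concentration table.

    The file must be UTF-8 text with a header naming the seven schema columns
    (case-insensitive, any order); the delimiter is auto-detected between comma
    and tab unless ``dialect`` passes it explicitly (``","`` or ``"\\t"``).
    Rows whose concentration is non-numeric or negative are rejected, not
    fatal: the function returns the clean records together with the rejection
    count, and emits a warning when any row was dropped.

    Returns
    -------
    (records, n_rejected)

    Raises
    ------
    SchemaError
        When a required column is absent (the message names it).
    EmptyInputError
        When the file has no header or no data rows.
    """
    path = Path(path)
    if not path.read_text(encoding="utf-8").strip():
        raise EmptyInputError(f"{path} contains no data")
    try:
        df = pd.read_csv(
            path,
            sep=dialect if dialect is not None else None,
            engine="python",
            dtype=str,
            comment="#",
            skip_blank_lines=True,
        )
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path} contains no data") from None
    if df.empty:
        raise EmptyInputError(f"{path} has a header but no rows")

    lookup = _normalise_header(df.columns)
    for col in REQUIRED_COLUMNS:
        if col not in lookup:
            raise SchemaError(f"required column {col!r} missing from {path}")
    df = df.rename(columns={lookup[c]: c for c in REQUIRED_COLUMNS})

    conc = pd.to_numeric(df["concentration_ug_per_kg"], errors="coerce")
    limit = pd.to_numeric(df["national_limit_ug_per_kg"], errors="coerce")
    ok = conc.notna() & (conc >= 0)
    n_rejected = int((~ok).sum())
    if n_rejected:
        warnings.warn(
            f"rejected {n_rejected} row(s) with non-numeric or negative concentration",
            stacklevel=2,
        )

    records: list[ConcentrationRecord] = []
    for i in df.index[ok]:
        lim = limit.at[i]
        records.append(
            ConcentrationRecord(
                food_category=str(df.at[i, "food_category"]).strip(),
                substance=str(df.at[i, "substance"]).strip(),
                site="" if pd.isna(df.at[i, "site"]) else str(df.at[i, "site"]).strip(),
                detection_time=""
                if pd.isna(df.at[i, "detection_time"])
                else str(df.at[i, "detection_time"]).strip(),
                concentration=float(conc.at[i]),
                national_limit=None if pd.isna(lim) else float(lim),
                source="" if pd.isna(df.at[i, "source"]) else str(df.at[i, "source"]).strip(),
            )
        )
    return records, n_rejected


def write_concentration_db(records: Sequence[ConcentrationRecord], path: str | Path) -> None:
    """Write records as the canonical comma-delimited table."""
    df = pd.DataFrame(
        {
            "food_category": [r.food_category for r in records],
            "substance": [r.substance for r in records],
            "site": [r.site for r in records],
            "detection_time": [r.detection_time for r in records],
            "concentration_ug_per_kg": [r.concentration for r in records],
            "national_limit_ug_per_kg": [r.national_limit for r in records],
            "source": [r.source for r in records],
        }
    )
    df.to_csv(path, index=False)


def import_spreadsheet(xlsx_path: str | Path, csv_path: str | Path, sheet: int | str = 0) -> Path:
    """Convert a spreadsheet copy of the concentration table to delimited text.

    Helper for supplementary files distributed as .xlsx; the core reader only
    parses delimited text.
    """
    df = pd.read_excel(xlsx_path, sheet_name=sheet)
    out = Path(csv_path)
    df.to_csv(out, index=False)
    return out


def summarize_concentrations(
    records: Iterable[ConcentrationRecord],
) -> list[FoodCategoryStats]:
    """Per-category n/mean/median/min/max/sd and limit-exceedance counts.

    sd is the sample standard deviation (divisor n-1); a single-observation
    category reports sd 0 and emits a warning. Exceedance is strict
    (concentration > the record's own national limit). Categories are returned
    in descending order of mean concentration; categories with zero records
    simply do not appear.
    """
    by_cat: dict[str, list[ConcentrationRecord]] = {}
    for r in records:
        by_cat.setdefault(r.food_category, []).append(r)
    if not by_cat:
        raise EmptyInputError("no concentration records to summarize")

    out: list[FoodCategoryStats] = []
    for cat, recs in by_cat.items():
        x = np.asarray([r.concentration for r in recs], dtype=float)
        if x.size == 1:
            warnings.warn(
                f"category {cat!r} has a single observation; sd reported as 0", stacklevel=2
            )
            sd = 0.0
        else:
            sd = float(np.std(x, ddof=1))
        out.append(
            FoodCategoryStats(
                food_category=cat,
                n=int(x.size),
                mean=float(np.mean(x)),
                median=float(np.median(x)),
                min=float(np.min(x)),
                max=float(np.max(x)),
                sd=sd,
                n_exceeding_limit=sum(r.exceeds_limit for r in recs),
            )
        )
    out.sort(key=lambda s: (-s.mean, s.food_category))
    return out


def write_summary(stats: Sequence[FoodCategoryStats], path: str | Path) -> None:
    """Write category summaries as delimited text, one row per category."""
    pd.DataFrame([vars(s) for s in stats]).to_csv(path, index=False)


def compare_groups(
    a: Sequence[float], b: Sequence[float], alpha: float = 0.05
) -> GroupComparison:
    """Welch (unequal-variance) two-sample t-test, two-sided.

    Used to compare concentration levels between food groups (e.g. staple
    grains vs fried meat vs olive oil). Welch's form is the safe default for
    the unequal group sizes and variances typical of literature-compiled data.

    Raises
    ------
    InsufficientDataError
        When either sample has fewer than 2 observations.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each sample needs at least 2 observations")
    if np.var(a) == 0 and np.var(b) == 0:
        # degenerate but well-defined: identical constants compare as equal
        if np.mean(a) == np.mean(b):
            return GroupComparison(statistic=0.0, pvalue=1.0, alpha=alpha)
        return GroupComparison(statistic=math.inf if np.mean(a) > np.mean(b) else -math.inf,
                               pvalue=0.0, alpha=alpha)
    t, p = _sps.ttest_ind(a, b, equal_var=False)
    return GroupComparison(statistic=float(t), pvalue=float(p), alpha=alpha)
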