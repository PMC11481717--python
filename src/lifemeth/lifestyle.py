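"""Comprehensive lifestyle index (CLI) construction.

Four modifiable risk factors — smoking status, alcohol intake, physical
activity and diet quality — are each scored 0 (highest risk), 1 or 2
(lowest risk) and summed into an unweighted 0–8 index.  A total of 4 or
less marks a participant as high-risk; the binary index (1 = high risk)
is the exposure used by the downstream EWAS stages.

Category definitions follow established guidelines: IPAQ for physical
activity (MET-minutes/week), ESC cut-offs for alcohol (max 2 units/day
for men, 1 for women), and fixed thirds of the 0–100 DQI-I range for
diet quality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ActivityRecord",
    "LifestyleScore",
    "score_smoking",
    "score_alcohol",
    "categorize_activity",
    "score_activity",
    "score_diet",
    "compute_cli",
    "score_participants",
    "correlate_components",
]

SMOKING_POINTS = {"current": 0, "former": 1, "never": 2}
ACTIVITY_POINTS = {"low": 0, "moderate": 1, "high": 2}

#: daily alcohol units at or below which intake counts as "optimal"
ALCOHOL_LIMIT = {"male": 2.0, "female": 1.0}

HIGH_RISK_MAX_TOTAL = 4


class ValidationError(ValueError):
    """Raised when a lifestyle input falls outside its documented domain."""


@dataclass(frozen=True)
class ActivityRecord:
    """One participant's physical-activity report (IPAQ-style).

    Days are per week, minutes are per active day; ``total_met_min_week``
    is the precomputed weekly volume in MET-minutes.
    """

    vigorous_days: float = 0.0
    vigorous_min_per_day: float = 0.0
    moderate_days: float = 0.0
    moderate_min_per_day: float = 0.0
    walking_days: float = 0.0
    walking_min_per_day: float = 0.0
    total_met_min_week: float = 0.0

    def __post_init__(self) -> None:
        for f in ("vigorous_days", "moderate_days", "walking_days"):
            v = getattr(self, f)
            if not 0 <= v <= 7:
                raise ValidationError(f"{f}={v} outside [0, 7]")
        for f in (
            "vigorous_min_per_day",
            "moderate_min_per_day",
            "walking_min_per_day",
            "total_met_min_week",
        ):
            if getattr(self, f) < 0:
                raise ValidationError(f"{f} must be non-negative")

    @property
    def combination_days(self) -> float:
        """Day-slots of any activity; overlapping days may double-count."""
        return self.vigorous_days + self.moderate_days + self.walking_days


@dataclass(frozen=True)
class LifestyleScore:
    smoking_points: int
    alcohol_points: int
    activity_points: int
    diet_points: int
    total: int
    risk_level: str  # "high" | "low"
    index: int  # 1 = high risk


def score_smoking(status: str) -> int:
    """current → 0, former → 1, never → 2."""
    try:
        return SMOKING_POINTS[status]
    except KeyError:
        raise ValidationError(
            f"unknown smoking status {status!r}; expected one of "
            f"{sorted(SMOKING_POINTS)}"
        ) from None


def score_alcohol(units_per_day: float, sex: str, never_drinker: bool = False) -> int:
    """Score daily alcohol intake against the sex-specific ESC cut-off.

    Abstainers (never drinkers, or zero units) score 2; intake within the
    optimal limit (≤1 unit/day for women, ≤2 for men) scores 1; anything
    above scores 0.
    """
    if units_per_day < 0:
        raise ValidationError(f"negative alcohol intake: {units_per_day}")
    if sex not in ALCOHOL_LIMIT:
        raise ValidationError(f"unknown sex {sex!r}; expected 'male' or 'female'")
    if never_drinker and units_per_day != 0:
        raise ValidationError("never_drinker set but units_per_day is non-zero")
    if never_drinker or units_per_day == 0:
        return 2
    return 1 if units_per_day <= ALCOHOL_LIMIT[sex] else 0


def categorize_activity(record: ActivityRecord) -> str:
    """Assign the IPAQ activity category: ``high``, ``moderate`` or ``low``.

    High: vigorous activity on ≥3 days with ≥1500 MET-min/week, or any
    combination on ≥7 day-slots with ≥3000 MET-min/week.  Moderate: ≥3
    vigorous days of ≥20 min, or ≥5 days of moderate activity and/or
    walking of ≥30 min, or ≥5 combination day-slots with ≥600
    MET-min/week.  Everything else is low.  High is checked first.
    """
    r = record
    if (r.vigorous_days >= 3 and r.total_met_min_week >= 1500) or (
        r.combination_days >= 7 and r.total_met_min_week >= 3000
    ):
        return "high"
    if (
        (r.vigorous_days >= 3 and r.vigorous_min_per_day >= 20)
        or (
            r.moderate_days + r.walking_days >= 5
            and (r.moderate_min_per_day >= 30 or r.walking_min_per_day >= 30)
        )
        or (r.combination_days >= 5 and r.total_met_min_week >= 600)
    ):
        return "moderate"
    return "low"


def score_activity(category: str) -> int:
    """low → 0, moderate → 1, high → 2."""
    try:
        return ACTIVITY_POINTS[category]
    except KeyError:
        raise ValidationError(
            f"unknown activity category {category!r}; expected one of "
            f"{sorted(ACTIVITY_POINTS)}"
        ) from None


def score_diet(dqi: float) -> int:
    """Score the DQI-I (0–100) by fixed thirds of its range.

    [0, 33.33] → 0, (33.33, 66.66] → 1, (66.66, 100] → 2.
    """
    if not 0 <= dqi <= 100:
        raise ValidationError(f"DQI-I {dqi} outside [0, 100]")
    if dqi <= 33.33:
        return 0
    if dqi <= 66.66:
        return 1
    return 2


def compute_cli(
    smoking_points: int,
    alcohol_points: int,
    activity_points: int,
    diet_points: int,
) -> LifestyleScore:
    """Sum the four component scores into the comprehensive lifestyle index.

    Total ≤ 4 indicates high risk (binary index 1); totals 5–8 are low
    risk (index 0).
    """
    pts = (smoking_points, alcohol_points, activity_points, diet_points)
    for name, p in zip(("smoking", "alcohol", "activity", "diet"), pts):
        if p not in (0, 1, 2):
            raise ValidationError(f"{name}_points={p} not in {{0, 1, 2}}")
    total = sum(pts)
    high = total <= HIGH_RISK_MAX_TOTAL
    return LifestyleScore(
        smoking_points=smoking_points,
        alcohol_points=alcohol_points,
        activity_points=activity_points,
        diet_points=diet_points,
        total=total,
        risk_level="high" if high else "low",
        index=int(high),
    )


def score_participants(phenotype: pd.DataFrame) -> pd.DataFrame:
    """Score every participant of a phenotype table.

    Expects the raw lifestyle columns (``smoking``, ``alcohol_units``,
    ``never_drinker``, ``sex``, the six activity-record columns plus
    ``total_met_min_week``, and ``dqi``).  Missing values are rejected:
    imputation is an upstream concern.

    Returns a table indexed like the input with the four component
    points, ``cli_total``, ``risk_level`` and the binary ``cli_index``.
    """
    required = [
        "smoking",
        "alcohol_units",
        "never_drinker",
        "sex",
        "vigorous_days",
        "vigorous_min_per_day",
        "moderate_days",
        "moderate_min_per_day",
        "walking_days",
        "walking_min_per_day",
        "total_met_min_week",
        "dqi",
    ]
    missing_cols = [c for c in required if c not in phenotype.columns]
    if missing_cols:
        raise ValidationError(f"phenotype table lacks columns: {missing_cols}")
    if phenotype[required].isna().any().any():
        bad = phenotype[required].isna().any()
        raise ValidationError(
            f"missing lifestyle values in columns: {list(bad[bad].index)}"
        )

    rows = []
    for _, row in phenotype.iterrows():
        rec = ActivityRecord(
            vigorous_days=row["vigorous_days"],
            vigorous_min_per_day=row["vigorous_min_per_day"],
            moderate_days=row["moderate_days"],
            moderate_min_per_day=row["moderate_min_per_day"],
            walking_days=row["walking_days"],
            walking_min_per_day=row["walking_min_per_day"],
            total_met_min_week=row["total_met_min_week"],
        )
        score = compute_cli(
            score_smoking(row["smoking"]),
            score_alcohol(
                row["alcohol_units"], row["sex"], bool(row["never_drinker"])
            ),
            score_activity(categorize_activity(rec)),
            score_diet(row["dqi"]),
        )
        rows.append(
            {
                "smoking_points": score.smoking_points,
                "alcohol_points": score.alcohol_points,
                "activity_points": score.activity_points,
                "diet_points": score.diet_points,
                "cli_total": score.total,
                "risk_level": score.risk_level,
                "cli_index": score.index,
            }
        )
    return pd.DataFrame(rows, index=phenotype.index)


def correlate_components(
    score_table: pd.DataFrame, columns: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations among index, components and BMI.

    Returns ``(r, p)`` DataFrames (symmetric, unit diagonal).  Pairs
    involving a zero-variance column are reported as NaN — undefined
    rather than silently zero.
    """
    if columns is None:
        columns = [
            c
            for c in (
                "cli_total",
                "smoking_points",
                "alcohol_points",
                "activity_points",
                "diet_points",
                "bmi",
            )
            if c in score_table.columns
        ]
    data = score_table[columns]
    if len(data) < 3:
        raise ValidationError("need at least 3 rows for a correlation matrix")
    if data.isna().any().any():
        raise ValidationError("missing values in correlation input")

    k = len(columns)
    r = np.eye(k)
    p = np.zeros((k, k))
    degenerate = data.std(ddof=0) == 0
    for i in range(k):
        for j in range(i + 1, k):
            if degenerate.iloc[i] or degenerate.iloc[j]:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            res = stats.pearsonr(data.iloc[:, i], data.iloc[:, j])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
        if degenerate.iloc[i]:
            r[i, i] = np.nan
    return (
        pd.DataFrame(r, index=columns, columns=columns),
        pd.DataFrame(p, index=columns, columns=columns),
    )
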