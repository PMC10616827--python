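"""Diagnostic scoring: Feighner alcohol-dependence criteria, onset ages,
and DSM-V severity mapping.

Feighner diagnosis requires at least one symptom in three of four problem
categories (medical consequences, attempts to control drinking,
legal/social problems, self-reported excessive drinking).  The age of first
problem is the earliest category onset; the age of alcohol-dependent onset
is the age at which the third category became positive, i.e. the third
order statistic of the endorsed category ages (ties share a value).

DSM-V severity maps a count of endorsed conceptual areas to
no-disorder (<2), mild (2-3), moderate (4-5) or severe (>=6).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

FEIGHNER_CATEGORIES = (
    "medical_consequences",
    "control_attempts",
    "legal_social",
    "excessive_drinking_report",
)

SEVERITY_LEVELS = ("no_disorder", "mild", "moderate", "severe")


@dataclass(frozen=True)
class SymptomRecord:
    """Per-category earliest symptom ages (None = category not endorsed)
    plus the count of DSM-V conceptual areas endorsed."""

    medical_consequences: float | None = None
    control_attempts: float | None = None
    legal_social: float | None = None
    excessive_drinking_report: float | None = None
    dsm5_criteria_count: int = 0

    def __post_init__(self) -> None:
        for cat in FEIGHNER_CATEGORIES:
            age = getattr(self, cat)
            if age is not None and age < 0:
                raise ValueError(f"{cat} age must be >= 0")
        if not 0 <= self.dsm5_criteria_count <= 11:
            raise ValueError("dsm5_criteria_count must lie in 0..11")

    def category_ages(self) -> list[float]:
        return [
            getattr(self, cat)
            for cat in FEIGHNER_CATEGORIES
            if getattr(self, cat) is not None and not (
                isinstance(getattr(self, cat), float) and math.isnan(getattr(self, cat))
            )
        ]


def feighner_diagnosis(record: SymptomRecord) -> tuple[bool, float | None, float | None]:
    """(diagnosed, age at first problem, age of dependent onset).

    Diagnosed iff >= 3 of the 4 categories are endorsed; the onset age is
    the third-smallest endorsed category age.  Ages are None when the
    diagnosis is negative.
    """
    ages = sorted(record.category_ages())
    if len(ages) < 3:
        return False, None, None
    return True, ages[0], ages[2]


def dsm5_severity(criteria_count: int) -> str:
    """Map a DSM-V criteria count to a severity category."""
    if criteria_count < 0:
        raise ValueError("criteria count must be >= 0")
    if criteria_count < 2:
        return "no_disorder"
    if criteria_count <= 3:
        return "mild"
    if criteria_count <= 5:
        return "moderate"
    return "severe"


@dataclass
class SeverityDistribution:
    counts: dict
    percentages: dict
    mean_criteria: float
    sd_criteria: float
    n: int


def severity_distribution(records) -> SeverityDistribution:
    """Severity category counts/percentages and criteria-count moments.

    Percentages are reported to one decimal place; the mean and the
    sample standard deviation (n-1 denominator) of the criteria counts to
    two decimals.
    """
    records = list(records)
    if not records:
        raise ValueError("need at least one record")
    counts = {level: 0 for level in SEVERITY_LEVELS}
    crit = []
    for r in records:
        counts[dsm5_severity(r.dsm5_criteria_count)] += 1
        crit.append(r.dsm5_criteria_count)
    n = len(records)
    percentages = {k: round(100.0 * v / n, 1) for k, v in counts.items()}
    crit_arr = np.asarray(crit, dtype=float)
    sd = float(crit_arr.std(ddof=1)) if n > 1 else 0.0
    return SeverityDistribution(
        counts=counts,
        percentages=percentages,
        mean_criteria=round(float(crit_arr.mean()), 2),
        sd_criteria=round(sd, 2),
        n=n,
    )
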