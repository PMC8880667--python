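"""Thresholded alert generation from the hazard index.

Two configurable limits split the [0, 100] hazard scale into three patient
statuses with attached recommendations:

* ``healthy``  — hazard in [0, limit1): schedule a routine revision;
* ``uncertain`` — hazard in [limit1, limit2], both ends inclusive:
  re-evaluate after a period or consider further tests;
* ``cancer``   — hazard in (limit2, 100]: perform confirmatory tests.

The default limits (60, 65) are configuration, not learned: no automatic
threshold tuning from ROC curves is implemented.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = ["TriageLimits", "TriageResult", "classify_hazard", "triage_table",
           "RECOMMENDATIONS", "STATUSES"]

STATUSES = ("healthy", "uncertain", "cancer")

RECOMMENDATIONS = {
    "healthy": "Schedule a routine revision.",
    "uncertain": ("Consider performing more tests or schedule a new "
                  "consultation after a specific time period."),
    "cancer": "Perform confirmatory diagnosis tests.",
}


@dataclass(frozen=True)
class TriageLimits:
    """The two status thresholds, 0 < limit1 <= limit2 < 100."""

    limit1: float = 60.0
    limit2: float = 65.0

    def __post_init__(self) -> None:
        if not (0.0 < self.limit1 <= self.limit2 < 100.0):
            raise ValueError(
                f"limits must satisfy 0 < limit1 <= limit2 < 100, "
                f"got ({self.limit1}, {self.limit2})"
            )


@dataclass(frozen=True)
class TriageResult:
    hazard: float
    status: str
    recommendation: str


def classify_hazard(hazard: float, limits: TriageLimits = TriageLimits()) -> TriageResult:
    """Map one hazard value to its status and recommendation.

    Both limits belong to the ``uncertain`` band (a hazard exactly at
    limit1 or limit2 is uncertain, not healthy/cancer).
    """
    if not 0.0 <= hazard <= 100.0:
        raise ValueError(f"hazard {hazard} outside [0, 100]")
    if hazard < limits.limit1:
        status = "healthy"
    elif hazard <= limits.limit2:
        status = "uncertain"
    else:
        status = "cancer"
    return TriageResult(hazard=float(hazard), status=status,
                        recommendation=RECOMMENDATIONS[status])


def triage_table(
    hazards: Sequence[float] | Iterable[float], limits: TriageLimits = TriageLimits()
) -> tuple[dict[str, int], list[TriageResult]]:
    """Triage a list of hazards; counts always sum to the list length."""
    results = [classify_hazard(h, limits) for h in hazards]
    counts = {status: 0 for status in STATUSES}
    for r in results:
        counts[r.status] += 1
    return counts, results
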