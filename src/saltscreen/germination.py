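"""Germination-stage indices from daily germination counts.

A petri-dish assay follows ``n_seeds`` (50 by default) for 12 days,
recording the number of newly germinated seeds each day, the number of
moldy seeds, and final mean radicle and embryo lengths.  From one such
course the standard agronomic indices are computed:

* germination rate   ``100 * sum_t G_t / n_seeds``
* germination vigor  ``100 * sum_{t<=d} G_t / n_seeds`` for an early day ``d``
* germination index  ``GI = sum_t G_t / t`` (day-weighted; rewards speed)
* vitality index     ``VI = GI * mean radicle length``
* root-bud ratio     ``radicle length / embryo length``

Days are 1-based (day 1 = first day of imbibition).  Moldy seeds are
recorded but enter no index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .registry import TREATMENTS

#: Canonical names of the traits derivable from a germination course,
#: in emission order.
COURSE_TRAITS = (
    "germination_rate",
    "germination_vigor",
    "germination_index",
    "vitality_index",
    "root_bud_ratio",
    "radicle_length",
    "embryo_length",
)


@dataclass
class GerminationCourse:
    """Daily germination record for one dish (accession x treatment x replicate)."""

    accession_id: str
    treatment: str
    replicate: int
    new_germinations: np.ndarray  # G_t, index 0 is day 1
    n_seeds: int = 50
    moldy: int = 0
    radicle_length_cm: float | None = None
    embryo_length_cm: float | None = None

    def __post_init__(self) -> None:
        self.new_germinations = np.asarray(self.new_germinations, dtype=int)
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")
        if self.n_seeds <= 0:
            raise ValueError("n_seeds must be positive")
        if (self.new_germinations < 0).any():
            raise ValueError("daily germination counts must be non-negative")
        if self.moldy < 0:
            raise ValueError("moldy count must be non-negative")
        if self.new_germinations.sum() + self.moldy > self.n_seeds:
            raise ValueError(
                f"germinated + moldy exceeds n_seeds for "
                f"{self.accession_id}/{self.treatment}/rep{self.replicate}"
            )

    @property
    def n_days(self) -> int:
        return len(self.new_germinations)

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.accession_id, self.treatment, self.replicate)


def germination_rate(course: GerminationCourse) -> float:
    """Final germination percentage: 100 * total germinated / seeds sown."""
    return 100.0 * course.new_germinations.sum() / course.n_seeds


def germination_vigor(course: GerminationCourse, vigor_day: int = 5) -> float:
    """Early-germination percentage counted on day ``vigor_day`` (inclusive)."""
    if not 1 <= vigor_day <= course.n_days:
        raise ValueError(f"vigor_day {vigor_day} outside assay days 1..{course.n_days}")
    return 100.0 * course.new_germinations[:vigor_day].sum() / course.n_seeds


def germination_index(course: GerminationCourse) -> float:
    """GI = sum over days of (new germinations on day t) / t."""
    days = np.arange(1, course.n_days + 1, dtype=float)
    return float((course.new_germinations / days).sum())


def vitality_index(course: GerminationCourse) -> float:
    """VI = GI x mean radicle length (cm)."""
    if course.radicle_length_cm is None:
        raise ValueError("vitality index requires a radicle length")
    return germination_index(course) * course.radicle_length_cm


def root_bud_ratio(course: GerminationCourse) -> float:
    """Radicle length over embryo length."""
    if course.embryo_length_cm is None or course.embryo_length_cm <= 0:
        raise ValueError("root-bud ratio requires a positive embryo length")
    if course.radicle_length_cm is None:
        raise ValueError("root-bud ratio requires a radicle length")
    return course.radicle_length_cm / course.embryo_length_cm


def course_indices(course: GerminationCourse, vigor_day: int = 5) -> dict[str, float]:
    """All seven derivable trait values for one course, by canonical name.

    For assays shorter than ``vigor_day`` the vigor count covers the
    whole (shorter) observation window.
    """
    effective_vigor_day = min(vigor_day, course.n_days)
    return {
        "germination_rate": germination_rate(course),
        "germination_vigor": germination_vigor(course, effective_vigor_day),
        "germination_index": germination_index(course),
        "vitality_index": vitality_index(course),
        "root_bud_ratio": root_bud_ratio(course),
        "radicle_length": float(course.radicle_length_cm),
        "embryo_length": float(course.embryo_length_cm),
    }


def course_to_traits(
    courses: list[GerminationCourse], vigor_day: int = 5
) -> pd.DataFrame:
    """Emit tidy trait observations (7 rows per course) from germination courses.

    Output columns: accession, treatment, trait, replicate, value, in
    deterministic sorted-key order.  Duplicate course keys are rejected.
    """
    keys = [c.key for c in courses]
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise ValueError(f"duplicate germination-course keys: {dupes}")
    rows = []
    for course in sorted(courses, key=lambda c: c.key):
        for trait, value in course_indices(course, vigor_day).items():
            rows.append(
                {
                    "accession": course.accession_id,
                    "treatment": course.treatment,
                    "trait": trait,
                    "replicate": course.replicate,
                    "value": value,
                }
            )
    return pd.DataFrame(rows, columns=["accession", "treatment", "trait", "replicate", "value"])
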