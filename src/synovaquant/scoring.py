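"""Ordinal semiquantitative synovitis scoring.

Implements the whole-knee 11-site synovitis instrument (each site
graded 0-3, sites summed, sum banded into severity categories), the
non-enhanced surrogates Hoffa-synovitis and effusion-synovitis (each
0-3), the two-site peripatellar sub-score used to compare
contrast-enhanced with FLAIR imaging, and a thickness-to-grade rule.

Nine sites are mandatory; Baker's cyst and loose bodies are scored
only when present and contribute 0 otherwise, so the summed score
ranges 0-33.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MANDATORY_SITES = (
    "medial_peripatellar",
    "lateral_peripatellar",
    "suprapatellar",
    "infrapatellar",
    "intercondylar",
    "medial_perimeniscal",
    "lateral_perimeniscal",
    "acl_adjacent",
    "pcl_adjacent",
)

OPTIONAL_SITES = ("bakers_cyst", "loose_bodies")

ALL_SITES = MANDATORY_SITES + OPTIONAL_SITES

SEQUENCES = ("IW-FS", "T1-FS CE", "FLAIR-FS")

#: Whole-knee severity bands on the summed 11-site score (inclusive).
SEVERITY_CUTOFFS = {
    "normal_or_equivocal": (0, 5),
    "mild": (6, 9),
    "moderate": (10, 13),
    "severe": (14, None),
}

MAX_GRADE = 3


def _check_grade(grade: int, what: str) -> int:
    grade = int(grade)
    if not 0 <= grade <= MAX_GRADE:
        raise ValueError(f"{what} grade must be in 0..{MAX_GRADE}, got {grade}")
    return grade


@dataclass(frozen=True)
class SiteGrade:
    site: str
    grade: int

    def __post_init__(self) -> None:
        if self.site not in ALL_SITES:
            raise ValueError(f"unknown site {self.site!r}")
        object.__setattr__(self, "grade", _check_grade(self.grade, self.site))


@dataclass
class ScoreSheet:
    """One patient x one sequence set of ordinal grades."""

    patient_id: str
    sequence: str
    site_grades: dict[str, int] = field(default_factory=dict)
    hoffa_grade: int | None = None
    effusion_grade: int | None = None

    def __post_init__(self) -> None:
        if self.sequence not in SEQUENCES:
            raise ValueError(
                f"unknown sequence {self.sequence!r}; expected one of {SEQUENCES}"
            )
        validated = {}
        for site, grade in self.site_grades.items():
            sg = SiteGrade(site, grade)
            validated[sg.site] = sg.grade
        self.site_grades = validated
        if self.hoffa_grade is not None:
            self.hoffa_grade = _check_grade(self.hoffa_grade, "Hoffa-synovitis")
        if self.effusion_grade is not None:
            self.effusion_grade = _check_grade(self.effusion_grade, "effusion-synovitis")


def sum_whole_knee(sheet: ScoreSheet) -> int:
    """Summed 11-site whole-knee synovitis score (range 0-33).

    All nine mandatory sites must be graded; absent optional sites
    (Baker's cyst, loose bodies) contribute 0.
    """
    missing = [s for s in MANDATORY_SITES if s not in sheet.site_grades]
    if missing:
        raise ValueError(f"mandatory sites not graded: {missing}")
    return sum(sheet.site_grades.values())


def categorize_severity(summed: int) -> str:
    """Band a summed whole-knee score: 0-5 normal or equivocal, 6-9 mild,
    10-13 moderate, >=14 severe."""
    summed = int(summed)
    if summed < 0:
        raise ValueError("summed score must be non-negative")
    for category, (lo, hi) in SEVERITY_CUTOFFS.items():
        if summed >= lo and (hi is None or summed <= hi):
            return category
    raise AssertionError("severity bands must partition the non-negative integers")


def peripatellar_sum(sheet: ScoreSheet) -> int:
    """Medial + lateral peripatellar recess grades (range 0-6)."""
    missing = [
        s
        for s in ("medial_peripatellar", "lateral_peripatellar")
        if s not in sheet.site_grades
    ]
    if missing:
        raise ValueError(f"peripatellar sites not graded: {missing}")
    return (
        sheet.site_grades["medial_peripatellar"]
        + sheet.site_grades["lateral_peripatellar"]
    )


def grade_from_thickness(
    thickness_mm: float, grade1_cutoff_mm: float = 2.0
) -> int:
    """Synovial-thickness grade: > 5 mm is grade 3, > 4 and <= 5 mm grade 2.

    The 0/1 boundary is not part of the instrument's published
    modification; it is configurable (default 2 mm) and callers should
    echo the configured value in any report they emit.
    """
    if thickness_mm < 0:
        raise ValueError("thickness must be non-negative")
    if not 0 < grade1_cutoff_mm <= 4:
        raise ValueError("grade1_cutoff_mm must be in (0, 4] mm")
    if thickness_mm > 5:
        return 3
    if thickness_mm > 4:
        return 2
    if thickness_mm > grade1_cutoff_mm:
        return 1
    return 0


@dataclass
class CohortSummary:
    sequence: str
    whole_knee_sums: dict[str, int]
    peripatellar_sums: dict[str, int]
    peripatellar_mean: float
    peripatellar_sd: float
    severity_categories: dict[str, str]
    severity_counts: dict[str, int]


def cohort_summary(sheets: list[ScoreSheet], sequence: str) -> CohortSummary:
    """Per-patient sums and cohort statistics for one sequence.

    Whole-knee sums and severity bands are computed only for sheets
    with all mandatory sites graded; peripatellar statistics for sheets
    with both peripatellar sites graded. SD uses n-1.
    """
    selected = [s for s in sheets if s.sequence == sequence]
    if not selected:
        raise ValueError(f"no score sheets for sequence {sequence!r}")
    seen: set[str] = set()
    for s in selected:
        if s.patient_id in seen:
            raise ValueError(
                f"duplicate sheet for patient {s.patient_id!r} x {sequence!r}"
            )
        seen.add(s.patient_id)
    whole: dict[str, int] = {}
    peri: dict[str, int] = {}
    categories: dict[str, str] = {}
    for s in selected:
        if all(site in s.site_grades for site in MANDATORY_SITES):
            whole[s.patient_id] = sum_whole_knee(s)
            categories[s.patient_id] = categorize_severity(whole[s.patient_id])
        if {"medial_peripatellar", "lateral_peripatellar"} <= s.site_grades.keys():
            peri[s.patient_id] = peripatellar_sum(s)
    counts = {cat: 0 for cat in SEVERITY_CUTOFFS}
    for cat in categories.values():
        counts[cat] += 1
    vals = np.array(list(peri.values()), dtype=float)
    mean = float(vals.mean()) if vals.size else float("nan")
    sd = float(vals.std(ddof=1)) if vals.size >= 2 else float("nan")
    return CohortSummary(
        sequence=sequence,
        whole_knee_sums=whole,
        peripatellar_sums=peri,
        peripatellar_mean=mean,
        peripatellar_sd=sd,
        severity_categories=categories,
        severity_counts=counts,
    )


def sheets_to_csv(sheets: list[ScoreSheet], path: str | Path) -> None:
    """Write score sheets in long format: patient_id, sequence, site, grade.

    Hoffa- and effusion-synovitis are written as pseudo-sites ``hoffa``
    and ``effusion``.
    """
    rows = []
    for s in sheets:
        for site, grade in s.site_grades.items():
            rows.append(
                {"patient_id": s.patient_id, "sequence": s.sequence,
                 "site": site, "grade": grade}
            )
        if s.hoffa_grade is not None:
            rows.append(
                {"patient_id": s.patient_id, "sequence": s.sequence,
                 "site": "hoffa", "grade": s.hoffa_grade}
            )
        if s.effusion_grade is not None:
            rows.append(
                {"patient_id": s.patient_id, "sequence": s.sequence,
                 "site": "effusion", "grade": s.effusion_grade}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def sheets_from_csv(path: str | Path) -> list[ScoreSheet]:
    """Read long-format score sheets written by :func:`sheets_to_csv`."""
    df = pd.read_csv(path)
    required = {"patient_id", "sequence", "site", "grade"}
    if not required <= set(df.columns):
        raise ValueError(f"score CSV must have columns {sorted(required)}")
    sheets = []
    for (pid, seq), grp in df.groupby(["patient_id", "sequence"], sort=False):
        sheet = ScoreSheet(patient_id=str(pid), sequence=str(seq))
        for _, row in grp.iterrows():
            site, grade = str(row["site"]), int(row["grade"])
            if site == "hoffa":
                sheet.hoffa_grade = _check_grade(grade, "Hoffa-synovitis")
            elif site == "effusion":
                sheet.effusion_grade = _check_grade(grade, "effusion-synovitis")
            else:
                sheet.site_grades[SiteGrade(site, grade).site] = grade
        sheets.append(sheet)
    return sheets
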