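"""Assay decision rules: ELISpot positivity, tumor volume, response classification.

ELISpot calls follow the three published conditions, evaluated in order:
(i) the concanavalin-A positive control produced IFN-gamma spots (assay
validity), (ii) the antigen wells show at least ``fold`` (default 3x) the
mock/DMSO background, and (iii) at least ``min_specific`` (default 30)
background-subtracted spot-forming cells per million splenocytes.  "Specific"
SFC is antigen minus DMSO, floored at zero.

Tumor volume from caliper length/width is 0.5 x L x W^2 with L the longer
dimension (inputs are auto-sorted).  A course ends at endpoint when any volume
exceeds 2000 mm^3; a responder shows complete regression (volume 0) at the
last observation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

MOCK_LABEL = "DMSO"
CONA_LABEL = "ConA"


@dataclass(frozen=True)
class ElispotWellSet:
    """Aggregated SFC per 10^6 splenocytes for one antigen of one animal."""

    antigen: str
    antigen_sfc: float
    dmso_sfc: float
    cona_positive: bool

    def __post_init__(self) -> None:
        if self.antigen_sfc < 0 or self.dmso_sfc < 0:
            raise ValueError("SFC values must be non-negative")


@dataclass(frozen=True)
class ElispotCall:
    antigen: str
    specific_sfc: float
    positive: bool
    reason: Optional[str]  # first failing condition: cona | fold | min_specific


@dataclass(frozen=True)
class TumorCourse:
    """One animal's caliper course; volumes are always derived, never stored."""

    animal: str
    days: tuple
    lengths_mm: tuple
    widths_mm: tuple

    def __post_init__(self) -> None:
        if not len(self.days) == len(self.lengths_mm) == len(self.widths_mm):
            raise ValueError("days, lengths, widths must align")
        if list(self.days) != sorted(self.days):
            raise ValueError(f"timepoints out of order for {self.animal}")

    @property
    def volumes_mm3(self) -> tuple:
        return tuple(
            tumor_volume(l, w) if (l > 0 and w > 0) else 0.0
            for l, w in zip(self.lengths_mm, self.widths_mm)
        )

    @property
    def endpoint_flag(self) -> bool:
        return any(v > ENDPOINT_VOLUME_MM3 for v in self.volumes_mm3)


ENDPOINT_VOLUME_MM3 = 2000.0


def call_elispot(
    wellset: ElispotWellSet, min_specific: float = 30.0, fold: float = 3.0
) -> ElispotCall:
    """Positivity call for one antigen; ``reason`` names the first failing
    condition in the published order (ConA validity, fold over mock, minimum
    specific spots)."""
    specific = max(0.0, wellset.antigen_sfc - wellset.dmso_sfc)
    reason = None
    if not wellset.cona_positive:
        reason = "cona"
    elif wellset.antigen_sfc < fold * wellset.dmso_sfc:
        reason = "fold"
    elif specific < min_specific:
        reason = "min_specific"
    return ElispotCall(
        antigen=wellset.antigen,
        specific_sfc=specific,
        positive=reason is None,
        reason=reason,
    )


def aggregate_plate(
    plate: pd.DataFrame, cona_min_sfc: float = 50.0
) -> dict:
    """Aggregate per-well counts into per-(mouse, antigen) well sets.

    ``plate`` columns: ``mouse antigen density replicate spots cells_per_well``.
    Each well is normalized to SFC per 10^6 splenocytes, replicate wells are
    averaged within each plating density, and the two densities are then
    averaged.  Wells labelled ``DMSO`` give the mock background and ``ConA``
    the validity control (positive when its SFC reaches ``cona_min_sfc``).

    Returns ``{mouse: [ElispotWellSet, ...]}`` with antigens in table order.
    """
    required = {"mouse", "antigen", "density", "replicate", "spots", "cells_per_well"}
    missing = required - set(plate.columns)
    if missing:
        raise ValueError(f"plate table missing columns: {sorted(missing)}")
    df = plate.copy()
    if (df["spots"] < 0).any():
        raise ValueError("negative spot counts in plate table")
    df["sfc"] = df["spots"] / df["cells_per_well"] * 1e6
    per = (
        df.groupby(["mouse", "antigen", "density"], sort=False)["sfc"]
        .mean()
        .groupby(["mouse", "antigen"], sort=False)
        .mean()
    )
    out: dict = {}
    for mouse in df["mouse"].unique():
        sfc = per.loc[mouse]
        dmso = float(sfc.get(MOCK_LABEL, 0.0))
        cona = float(sfc.get(CONA_LABEL, 0.0)) >= cona_min_sfc
        sets = []
        for antigen in sfc.index:
            if antigen in (MOCK_LABEL, CONA_LABEL):
                continue
            sets.append(
                ElispotWellSet(
                    antigen=str(antigen),
                    antigen_sfc=float(sfc[antigen]),
                    dmso_sfc=dmso,
                    cona_positive=cona,
                )
            )
        out[mouse] = sets
    return out


def call_plate(
    plate: pd.DataFrame,
    min_specific: float = 30.0,
    fold: float = 3.0,
    cona_min_sfc: float = 50.0,
) -> pd.DataFrame:
    """Per-well CSV -> per-(mouse, antigen) positivity table."""
    rows = []
    for mouse, wellsets in aggregate_plate(plate, cona_min_sfc=cona_min_sfc).items():
        for ws in wellsets:
            call = call_elispot(ws, min_specific=min_specific, fold=fold)
            rows.append(
                {
                    "mouse": mouse,
                    "antigen": call.antigen,
                    "antigen_sfc": ws.antigen_sfc,
                    "dmso_sfc": ws.dmso_sfc,
                    "specific_sfc": call.specific_sfc,
                    "positive": call.positive,
                    "reason": call.reason,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["mouse", "antigen", "antigen_sfc", "dmso_sfc", "specific_sfc",
                 "positive", "reason"],
    )


def tumor_volume(length_mm: float, width_mm: float) -> float:
    """0.5 x length x width^2 (mm^3), with length the longer dimension."""
    if length_mm <= 0 or width_mm <= 0:
        raise ValueError("caliper dimensions must be positive")
    longer, shorter = max(length_mm, width_mm), min(length_mm, width_mm)
    return 0.5 * longer * shorter**2


def classify_course(course: TumorCourse) -> str:
    """``responder`` (complete regression at last timepoint), ``endpoint``
    (any volume > 2000 mm^3; takes precedence — the animal is killed), or
    ``non_responder``."""
    volumes = course.volumes_mm3
    if len(volumes) < 2:
        raise ValueError(f"course for {course.animal} has < 2 timepoints")
    if course.endpoint_flag:
        return "endpoint"
    if volumes[-1] == 0:
        return "responder"
    return "non_responder"


def courses_from_measurements(df: pd.DataFrame) -> list:
    """Caliper CSV (`mouse day length_mm width_mm`) -> per-animal courses."""
    required = {"mouse", "day", "length_mm", "width_mm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"caliper table missing columns: {sorted(missing)}")
    courses = []
    for mouse, grp in df.groupby("mouse", sort=False):
        grp = grp.sort_values("day")
        courses.append(
            TumorCourse(
                animal=str(mouse),
                days=tuple(grp["day"]),
                lengths_mm=tuple(grp["length_mm"]),
                widths_mm=tuple(grp["width_mm"]),
            )
        )
    return courses


def course_report(courses: Sequence) -> pd.DataFrame:
    rows = []
    for c in courses:
        rows.append(
            {
                "mouse": c.animal,
                "n_timepoints": len(c.days),
                "final_volume_mm3": c.volumes_mm3[-1],
                "max_volume_mm3": max(c.volumes_mm3),
                "classification": classify_course(c),
            }
        )
    return pd.DataFrame(rows)
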