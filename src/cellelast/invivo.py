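"""Tumor caliper-to-volume conversion, growth kinetics and necrosis fraction.

Caliper measurements give two orthogonal diameters per time point; volume
uses the ellipsoid equation with the tumor depth assumed equal to the
smaller diameter, V = (pi/6) L W^2. Growth is summarized per subject as
fold change from the day-0 (first-treatment) baseline and per group as
mean +/- SEM, with a treated/control volume ratio per day ready for
external statistics. Necrosis is consumed as pathologist-delineated
(necrotic, total) area pairs and reported as AON% = 100 * necrotic/total.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError, ValidationError


def ellipsoid_volume(length_mm: float, width_mm: float) -> float:
    """Tumor volume (mm^3): V = (pi/6) * L * W^2, depth = smaller diameter.

    Caliper order-agnostic: if width > length the inputs are swapped with
    a warning. Degree-3 homogeneous in the diameters.
    """
    if length_mm <= 0 or width_mm <= 0:
        raise ParameterError("diameters must be > 0")
    if width_mm > length_mm:
        warnings.warn(
            f"width {width_mm} > length {length_mm}: swapping diameters",
            stacklevel=2,
        )
        length_mm, width_mm = width_mm, length_mm
    return math.pi / 6.0 * length_mm * width_mm**2


def aon_percent(necrotic_area: float, total_area: float) -> float:
    """Necrotic area as a percent of total section area (unit-invariant)."""
    if total_area <= 0:
        raise ValidationError("total area must be > 0")
    if necrotic_area < 0 or necrotic_area > total_area:
        raise ValidationError(
            f"necrotic area {necrotic_area} outside [0, total={total_area}]"
        )
    return 100.0 * necrotic_area / total_area


@dataclass(frozen=True)
class TumorMeasurement:
    subject_id: str
    day: int
    length_mm: float
    width_mm: float
    group: str                    # control | every-other-day | daily | twice-daily
    intensity_w_cm2: float | None = None
    mass_mg: float | None = None  # terminal only

    def __post_init__(self) -> None:
        if self.day < 0:
            raise ValidationError("day must be >= 0")
        if self.width_mm <= 0 or self.length_mm < self.width_mm:
            raise ValidationError(
                f"need L >= W > 0, got L={self.length_mm}, W={self.width_mm}"
            )

    @property
    def volume_mm3(self) -> float:
        return ellipsoid_volume(self.length_mm, self.width_mm)


@dataclass(frozen=True)
class HistologySection:
    subject_id: str
    necrotic_area: float
    total_area: float

    def __post_init__(self) -> None:
        aon_percent(self.necrotic_area, self.total_area)  # validates

    @property
    def aon_pct(self) -> float:
        return aon_percent(self.necrotic_area, self.total_area)


@dataclass
class GrowthSummary:
    """Tidy per-subject and per-group tumor kinetics tables."""

    subjects: pd.DataFrame       # subject_id, group, day, volume_mm3, fold_change
    groups: pd.DataFrame         # group, day, n, mean_volume, sem_volume, mean_fold, sem_fold
    ratio_vs_control: pd.DataFrame | None  # day, group, volume_ratio (mean fold / control)
    mass: pd.DataFrame | None    # group, n, mean_mass_mg, sem_mass_mg
    excluded_subjects: list[str]


def _sem(x: pd.Series) -> float:
    return float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else np.nan


def growth_summary(
    measurements: list[TumorMeasurement], control_group: str = "control"
) -> GrowthSummary:
    """Summarize growth kinetics per subject and group.

    Each subject needs a day-0 baseline; subjects without one are excluded
    with a warning. Fold change is V(t)/V(0). The ratio table divides each
    treated group's mean fold change by the control group's on matching
    days (None when the control group is absent).
    """
    rows = [
        {
            "subject_id": m.subject_id,
            "group": m.group,
            "day": m.day,
            "volume_mm3": m.volume_mm3,
            "mass_mg": m.mass_mg,
        }
        for m in measurements
    ]
    if not rows:
        raise ValidationError("no measurements supplied")
    df = pd.DataFrame(rows).sort_values(["group", "subject_id", "day"])

    excluded: list[str] = []
    kept = []
    for sid, sub in df.groupby("subject_id", sort=False):
        base = sub.loc[sub["day"] == 0, "volume_mm3"]
        if base.empty:
            excluded.append(str(sid))
            warnings.warn(f"subject {sid!r} has no day-0 baseline; excluded",
                          stacklevel=2)
            continue
        sub = sub.copy()
        sub["fold_change"] = sub["volume_mm3"] / float(base.iloc[0])
        kept.append(sub)
    if not kept:
        raise ValidationError("no subject has a day-0 baseline")
    subjects = pd.concat(kept, ignore_index=True)

    groups = (
        subjects.groupby(["group", "day"])
        .agg(
            n=("volume_mm3", "size"),
            mean_volume=("volume_mm3", "mean"),
            sem_volume=("volume_mm3", _sem),
            mean_fold=("fold_change", "mean"),
            sem_fold=("fold_change", _sem),
        )
        .reset_index()
    )

    ratio = None
    if control_group in set(groups["group"]):
        ctrl = groups[groups["group"] == control_group][["day", "mean_fold"]]
        ctrl = ctrl.rename(columns={"mean_fold": "control_fold"})
        treated = groups[groups["group"] != control_group]
        ratio = treated.merge(ctrl, on="day")
        ratio["volume_ratio"] = ratio["mean_fold"] / ratio["control_fold"]
        ratio = ratio[["day", "group", "volume_ratio"]].sort_values(["group", "day"])
        ratio = ratio.reset_index(drop=True)

    mass = None
    with_mass = subjects.dropna(subset=["mass_mg"])
    if not with_mass.empty:
        terminal = with_mass.sort_values("day").groupby("subject_id").tail(1)
        mass = (
            terminal.groupby("group")
            .agg(n=("mass_mg", "size"), mean_mass_mg=("mass_mg", "mean"),
                 sem_mass_mg=("mass_mg", _sem))
            .reset_index()
        )

    return GrowthSummary(
        subjects=subjects,
        groups=groups,
        ratio_vs_control=ratio,
        mass=mass,
        excluded_subjects=excluded,
    )
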