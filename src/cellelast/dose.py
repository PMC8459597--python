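"""Ultrasound exposure arithmetic and resazurin plate-reader viability.

Areal energy density is intensity x exposure time (J/cm^2). The duty
cycle of pulsed operation is carried as metadata and deliberately NOT
multiplied into the energy: that is the only convention under which the
instrument settings used here (0.139 or 0.164 W/cm^2 for 20 or 40 s)
reproduce the nominal 2.8 / 3.3 / 5.6 / 6.6 J/cm^2 dose levels at two
significant figures.

Viability is the blank-subtracted treated fluorescence as a percentage of
the blank-subtracted untreated fluorescence (untreated = 100% viable),
the standard resazurin (PrestoBlue) normalization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import NormalizationError, ParameterError, ValidationError


def round_sig(x: float, digits: int = 2) -> float:
    """Round to ``digits`` significant figures (display convention)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + digits - 1)


def energy_density(intensity_w_cm2: float, exposure_time_s: float) -> float:
    """Areal energy density J/cm^2 = intensity x time. Bilinear, exact value.

    Use :func:`round_sig` for the two-significant-figure display form.
    """
    if intensity_w_cm2 <= 0 or exposure_time_s <= 0:
        raise ParameterError("intensity and exposure time must be > 0")
    return intensity_w_cm2 * exposure_time_s


@dataclass(frozen=True)
class UltrasoundExposure:
    """One ultrasound operating condition; energy density is derived."""

    frequency_khz: float
    intensity_w_cm2: float
    exposure_time_s: float
    duty_cycle: float = 0.5

    def __post_init__(self) -> None:
        if min(self.frequency_khz, self.intensity_w_cm2, self.exposure_time_s) <= 0:
            raise ValidationError("frequency, intensity and time must be > 0")
        if not (0 < self.duty_cycle <= 1):
            raise ValidationError("duty_cycle must be in (0, 1]")

    @property
    def energy_density_j_cm2(self) -> float:
        return energy_density(self.intensity_w_cm2, self.exposure_time_s)

    @property
    def energy_density_display(self) -> float:
        """Energy density at two significant figures, as doses are quoted."""
        return round_sig(self.energy_density_j_cm2, 2)


@dataclass
class PlateReading:
    """Fluorescence wells grouped treated / untreated / blank (a.u.).

    Excitation 560 nm / emission 590 nm metadata is informational only.
    """

    treated: np.ndarray
    untreated: np.ndarray
    blank: np.ndarray
    excitation_nm: float = 560.0
    emission_nm: float = 590.0

    def __post_init__(self) -> None:
        self.treated = np.atleast_1d(np.asarray(self.treated, dtype=float))
        self.untreated = np.atleast_1d(np.asarray(self.untreated, dtype=float))
        self.blank = np.atleast_1d(np.asarray(self.blank, dtype=float))
        for name, arr in (
            ("treated", self.treated),
            ("untreated", self.untreated),
            ("blank", self.blank),
        ):
            if arr.size < 1:
                raise ValidationError(f"{name} group needs >= 1 well")
        if self.blank.mean() >= self.untreated.mean():
            raise ValidationError(
                "blank mean must be below untreated mean "
                f"({self.blank.mean():.3g} >= {self.untreated.mean():.3g})"
            )


@dataclass(frozen=True)
class ViabilityResult:
    percent: float
    sem_percent: float
    floored: bool          # True when a negative raw value was clipped to 0
    raw_percent: float


def _sem(arr: np.ndarray) -> float:
    if arr.size < 2:
        return 0.0
    return float(np.std(arr, ddof=1) / np.sqrt(arr.size))


def viability_percent(reading: PlateReading) -> ViabilityResult:
    """Blank-subtracted viability percentage with propagated replicate SEM.

    V = 100 * (mean(treated) - mean(blank)) / (mean(untreated) - mean(blank)).
    Invariant under a common rescaling of all fluorescence values (detector
    gain). Negative results are floored at 0 and flagged, never silently.
    """
    t, u, b = (
        float(reading.treated.mean()),
        float(reading.untreated.mean()),
        float(reading.blank.mean()),
    )
    if u <= b:
        raise NormalizationError("untreated signal <= blank: cannot normalize")
    denom = u - b
    v = 100.0 * (t - b) / denom
    # first-order propagation of the three group SEMs
    dv_dt = 100.0 / denom
    dv_du = -100.0 * (t - b) / denom**2
    dv_db = 100.0 * ((t - b) / denom**2 - 1.0 / denom)
    sem = math.sqrt(
        (dv_dt * _sem(reading.treated)) ** 2
        + (dv_du * _sem(reading.untreated)) ** 2
        + (dv_db * _sem(reading.blank)) ** 2
    )
    return ViabilityResult(
        percent=max(v, 0.0),
        sem_percent=sem,
        floored=v < 0,
        raw_percent=v,
    )
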