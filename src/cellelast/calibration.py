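"""Cantilever calibration: deflection sensitivity and thermal spring constant.

Two quantities turn a raw photodiode trace into force. The deflection
sensitivity (nm/V) comes from an approach curve on a rigid substrate
(glass): past contact the tip cannot indent, so every µm of piezo travel
becomes a µm of cantilever deflection and the inverse slope of the
deflection-vs-z line converts volts to nanometres. The spring constant
(N/m) comes from the cantilever's thermal motion via equipartition,

    k = beta * k_B * T / <d^2>,

where <d^2> is the variance of the free-air deflection fluctuations in
metres squared and ``beta`` is a dimensionless mode-shape correction
(default 1.0; instrument vendors quote values near 0.8 for the
fundamental mode of a triangular lever).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CalibrationError, ParameterError
from .forcecurves import ForceCurve, segment_approach

BOLTZMANN_J_PER_K = 1.380649e-23


@dataclass(frozen=True)
class CalibrationResult:
    """Spring constant / sensitivity with the inputs that produced them."""

    spring_constant: float               # N/m
    deflection_sensitivity: float | None  # nm/V, None if not calibrated here
    method: str
    temperature: float                   # K
    sample_count: int
    variance_of_deflection: float        # m^2
    correction_factor: float

    def __post_init__(self) -> None:
        if self.spring_constant <= 0:
            raise CalibrationError("spring constant must be > 0")
        if self.variance_of_deflection < 0:
            raise CalibrationError("deflection variance must be >= 0")


def deflection_sensitivity_from_hard_curve(
    curve: ForceCurve, contact_fraction: float = 0.5
) -> float:
    """Estimate the deflection sensitivity (nm/V) from a glass curve.

    Expects a baseline-corrected approach curve recorded in volts on a
    rigid, non-deformable surface. The contact region is taken as the
    samples whose deflection exceeds 2% of the maximum; a straight line is
    fit over the deepest ``contact_fraction`` of it, and the sensitivity
    is 1000 / slope (slope in V/µm).
    """
    if not (0 < contact_fraction <= 1):
        raise ParameterError(
            f"contact_fraction must be in (0, 1], got {contact_fraction}"
        )
    app = segment_approach(curve)
    z, d = app.piezo_position_um, app.deflection
    dmax = float(d.max())
    if dmax <= 0:
        raise CalibrationError("no contact detected: deflection never rises")
    contact = np.flatnonzero(d > 0.02 * dmax)
    if contact.size < 4:
        raise CalibrationError("no contact detected: fewer than 4 contact samples")
    n_fit = max(2, int(round(contact_fraction * contact.size)))
    idx = contact[-n_fit:]
    slope = float(np.polyfit(z[idx], d[idx], 1)[0])
    if slope <= 0:
        raise CalibrationError("no contact detected: non-positive contact slope")
    return 1000.0 / slope  # V/µm -> nm/V


def spring_constant_thermal(
    deflection_series_m: np.ndarray,
    temperature: float = 310.15,
    correction_factor: float = 1.0,
) -> CalibrationResult:
    """Equipartition spring-constant estimate from a thermal deflection series.

    ``deflection_series_m`` is baseline-free thermal deflection in metres,
    length >= 1000. Invariant under sign flip and mean shift (variance is
    taken about the sample mean).
    """
    if temperature <= 0:
        raise ParameterError(f"temperature must be > 0 K, got {temperature}")
    if correction_factor <= 0:
        raise ParameterError("correction_factor must be > 0")
    series = np.asarray(deflection_series_m, dtype=float)
    if series.size < 1000:
        raise ParameterError(
            f"need >= 1000 thermal samples, got {series.size}"
        )
    if np.ptp(series) == 0:
        raise CalibrationError("zero deflection variance: series is constant")
    variance = float(np.var(series, ddof=1))
    k = correction_factor * BOLTZMANN_J_PER_K * temperature / variance
    return CalibrationResult(
        spring_constant=k,
        deflection_sensitivity=None,
        method="thermal-equipartition",
        temperature=temperature,
        sample_count=series.size,
        variance_of_deflection=variance,
        correction_factor=correction_factor,
    )
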