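"""Stiffness -> ultrasound-sensitivity model.

Soft cells die, stiff cells survive: across cell lines the post-exposure
viability rises with the line's mean Young's modulus. The model is an
ordinary least-squares line viability = slope * E + intercept, with R^2
reported as the squared Pearson correlation (identical to the OLS
coefficient of determination for a simple linear regression). A log-E
variant is available for curvature checks. Predictions are clamped to the
physical [0, 100]% range and flagged when clamped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateDesignError, ParameterError


@dataclass(frozen=True)
class SensitivityModel:
    slope: float          # % per kPa (or % per log-kPa under log_e)
    intercept: float      # %
    r_squared: float
    n_points: int
    subset: str = "all"   # "all" | "cancer"
    log_e: bool = False

    def predict(self, e_kpa: float) -> tuple[float, bool]:
        """Predicted viability % at modulus e_kpa, clamped to [0, 100].

        Returns (value, clamped_flag).
        """
        x = np.log(e_kpa) if self.log_e else e_kpa
        raw = self.slope * x + self.intercept
        clamped = not (0.0 <= raw <= 100.0)
        return float(min(max(raw, 0.0), 100.0)), clamped


def fit_sensitivity(
    points: Sequence[tuple[float, float]],
    subset: str = "all",
    log_e: bool = False,
) -> SensitivityModel:
    """OLS fit of viability (%) on Young's modulus (kPa).

    ``points`` are (E_kPa, viability_%) pairs; at least two with distinct
    E are required. R^2 is invariant under affine rescaling of the E axis
    (kPa vs Pa give the same correlation).
    """
    if len(points) < 2:
        raise ParameterError("need >= 2 (E, viability) points")
    e = np.array([p[0] for p in points], dtype=float)
    v = np.array([p[1] for p in points], dtype=float)
    if np.ptp(e) == 0:
        raise DegenerateDesignError("all moduli equal: slope is unidentifiable")
    x = np.log(e) if log_e else e
    res = stats.linregress(x, v)
    return SensitivityModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=e.size,
        subset=subset,
        log_e=log_e,
    )


def predict_viability(model: SensitivityModel, e_kpa: float) -> float:
    """Clamped viability prediction (%); see SensitivityModel.predict."""
    return model.predict(e_kpa)[0]
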