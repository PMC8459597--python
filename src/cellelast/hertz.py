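"""Spherical-indenter Hertz fitting of AFM force curves.

The contact model is the paraboloid-approximated rigid sphere indenting an
elastic half-space,

    F = (4/3) * E / (1 - nu^2) * sqrt(R) * delta^(3/2),

valid for indentation delta well below the probe radius R; fits are capped
at delta <= max_indentation_fraction * R (default 0.3R) to stay inside
that regime. With the package's canonical units (delta, R in µm; E in kPa)
the prefactor is exactly 1 and F comes out in nN, because
kPa * µm^2 = 1e3 Pa * 1e-12 m^2 = 1e-9 N.

For a fixed contact point z0 the model is linear in E, so the
least-squares modulus has the closed form

    E = (3/4) * (1 - nu^2) / sqrt(R) * sum(F * delta^(3/2)) / sum(delta^3),

which is exact, fast, and serves as the oracle for any iterative refit.
The contact point itself is found by a grid search minimizing the fit
residual, which is robust on soft cells where the force onset is gradual.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .errors import (
    ContactDetectionError,
    ParameterError,
    QCError,
    ValidationError,
)
from .forcecurves import ForceCurve, baseline_correct, segment_approach

_MIN_FIT_POINTS = 8
_NO_CONTACT = 1e30  # finite sentinel: candidate z0 admits no Hertz fit


@dataclass(frozen=True)
class FitConfig:
    """Tunables of the Hertz fit.

    poisson_ratio: cell Poisson ratio nu; 0.5 = incompressible (default).
    max_indentation_fraction: fit range cap as a fraction of probe radius.
    contact_search_grid_um: z0 grid step for contact-point search.
    max_force_cap_nN: optional upper force bound on fitted samples.
    max_modulus_kpa: fits above this are flagged non-converged (a rigid
        substrate, not a cell).
    max_relative_residual: fits whose residual RMS exceeds this fraction
        of the max fitted force are flagged non-converged (the sphere
        model does not describe the data, e.g. a rigid surface).
    """

    poisson_ratio: float = 0.5
    max_indentation_fraction: float = 0.3
    contact_search_grid_um: float = 0.005
    max_force_cap_nN: float | None = None
    max_modulus_kpa: float = 1000.0
    max_relative_residual: float = 0.2

    def __post_init__(self) -> None:
        if not (0 <= self.poisson_ratio <= 0.5):
            raise ParameterError(
                f"poisson_ratio must be in [0, 0.5], got {self.poisson_ratio}"
            )
        if not (0 < self.max_indentation_fraction <= 1):
            raise ParameterError("max_indentation_fraction must be in (0, 1]")
        if self.contact_search_grid_um <= 0:
            raise ParameterError("contact_search_grid_um must be > 0")


@dataclass
class IndentationFit:
    """Result of fitting one curve: contact point, modulus, diagnostics."""

    contact_point_um: float
    youngs_modulus_kpa: float
    residual_rms_nN: float
    n_points_fit: int
    max_force_nN: float
    max_indentation_um: float
    converged: bool
    reason: str | None = None
    curve_id: str | None = None
    cell_id: str | None = None
    location_id: str | None = None


@dataclass
class PointStiffnessQC:
    """Per-measurement stability check on an acquisition-ordered fit series."""

    modulus_sequence_kpa: np.ndarray
    drift_slope_kpa_per_curve: float
    normality_p: float
    passed: bool
    reason: str | None = None


@dataclass
class CellLineStiffness:
    """Hierarchical curve -> location -> cell -> line stiffness aggregate."""

    per_cell_means_kpa: dict[str, float]
    line_mean_kpa: float
    line_sem_kpa: float | None
    n_cells: int
    n_curves: int
    n_excluded_cells: int = 0


def hertz_force(
    delta_um: np.ndarray | float,
    e_kpa: float,
    nu: float = 0.5,
    radius_um: float = 1.0,
) -> np.ndarray | float:
    """Hertz sphere force (nN) at indentation delta (µm). F(0) = 0."""
    delta = np.asarray(delta_um, dtype=float)
    if np.any(delta < 0):
        raise ParameterError("indentation delta must be >= 0")
    if radius_um <= 0:
        raise ParameterError("probe radius must be > 0")
    out = (4.0 / 3.0) * e_kpa / (1.0 - nu**2) * np.sqrt(radius_um) * delta**1.5
    return out if out.ndim else float(out)


def force_indentation(
    curve: ForceCurve, z0_um: float
) -> tuple[np.ndarray, np.ndarray]:
    """Convert an approach curve to (indentation µm, force nN) past z0.

    Requires a baseline-corrected approach curve with spring constant set
    (and deflection sensitivity, if the signal is in volts). Samples with
    z < z0 are excluded; delta = (z - z0) - d and F = k * d. Negative
    deltas from noise are clipped to zero so the Hertz domain holds.
    """
    if curve.spring_constant is None:
        raise ValidationError(
            f"curve {curve.curve_id!r}: spring_constant unset; run thermal "
            "calibration (cellelast.calibration) first"
        )
    app = segment_approach(curve)
    d_nm = app.deflection_nm()
    z = app.piezo_position_um
    mask = z >= z0_um
    d_nm = d_nm[mask]
    delta = (z[mask] - z0_um) - d_nm * 1e-3  # nm -> µm
    force = curve.spring_constant * d_nm     # (N/m)*(nm) = nN
    return np.clip(delta, 0.0, None), force


def fit_hertz(
    delta_um: np.ndarray,
    force_nN: np.ndarray,
    config: FitConfig,
    radius_um: float,
) -> IndentationFit:
    """Closed-form least-squares Hertz modulus at a fixed contact point.

    Fits over delta in (0, max_indentation_fraction * R], optionally also
    capped at max_force_cap_nN. Returns a non-converged record (with a
    reason) rather than raising when the data cannot support a fit.
    """
    delta = np.asarray(delta_um, dtype=float)
    force = np.asarray(force_nN, dtype=float)
    in_range = (delta > 0) & (delta <= config.max_indentation_fraction * radius_um)
    if config.max_force_cap_nN is not None:
        in_range &= force <= config.max_force_cap_nN
    n = int(in_range.sum())
    bad = IndentationFit(
        contact_point_um=np.nan,
        youngs_modulus_kpa=np.nan,
        residual_rms_nN=np.nan,
        n_points_fit=n,
        max_force_nN=float(force.max()) if force.size else np.nan,
        max_indentation_um=float(delta.max()) if delta.size else np.nan,
        converged=False,
    )
    if n < _MIN_FIT_POINTS:
        bad.reason = f"only {n} in-range samples (need {_MIN_FIT_POINTS})"
        return bad
    d, f = delta[in_range], force[in_range]
    d32 = d**1.5
    denom = float(np.sum(d32 * d32))  # = sum(delta^3)
    coeff = float(np.sum(f * d32)) / denom
    e_kpa = 0.75 * (1.0 - config.poisson_ratio**2) / np.sqrt(radius_um) * coeff
    if e_kpa <= 0:
        bad.reason = "non-positive modulus estimate (no contact signal)"
        return bad
    resid = f - coeff * d32
    fit = IndentationFit(
        contact_point_um=np.nan,
        youngs_modulus_kpa=e_kpa,
        residual_rms_nN=float(np.sqrt(np.mean(resid**2))),
        n_points_fit=n,
        max_force_nN=float(f.max()),
        max_indentation_um=float(d.max()),
        converged=True,
    )
    if e_kpa > config.max_modulus_kpa:
        fit.converged = False
        fit.reason = (
            f"modulus {e_kpa:.3g} kPa out of supported range "
            f"(> {config.max_modulus_kpa:g} kPa; rigid surface?)"
        )
    elif fit.residual_rms_nN > config.max_relative_residual * fit.max_force_nN:
        fit.converged = False
        fit.reason = (
            f"poor model fit: residual RMS {fit.residual_rms_nN:.3g} nN is "
            f"{fit.residual_rms_nN / fit.max_force_nN:.0%} of max force "
            f"(limit {config.max_relative_residual:.0%})"
        )
    return fit


def find_contact_point(
    curve: ForceCurve, config: FitConfig, radius_um: float
) -> float:
    """Locate z0 by grid search minimizing the Hertz-fit residual.

    The grid spans the approach z range at contact_search_grid_um steps;
    ties resolve to the smaller z0 (determinism). Raises
    ContactDetectionError when no candidate supports a converged fit
    (pure-baseline curve) or the residual profile never improves.
    """
    app = segment_approach(curve)
    z = app.piezo_position_um
    d_nm = app.deflection_nm()
    k = curve.spring_constant
    if k is None:
        raise ValidationError(
            f"curve {curve.curve_id!r}: spring_constant unset; calibrate first"
        )
    force_all = k * d_nm
    cap = config.max_indentation_fraction * radius_um

    def objective(z0: float) -> float:
        """Whole-curve residual RMS of the piecewise zero/Hertz model.

        The Hertz coefficient is estimated from the in-range contact
        samples only, but the residual is evaluated over every approach
        sample (zero predicted force before contact, extrapolated model
        past the fit cap), so candidates with different contact windows
        are compared on the same footing.
        """
        delta = np.clip((z - z0) - d_nm * 1e-3, 0.0, None)
        in_range = (delta > 0) & (delta <= cap)
        if config.max_force_cap_nN is not None:
            in_range &= force_all <= config.max_force_cap_nN
        if in_range.sum() < _MIN_FIT_POINTS:
            return _NO_CONTACT
        d32 = delta[in_range] ** 1.5
        denom = float(np.sum(d32 * d32))
        if denom <= 0:
            return _NO_CONTACT
        coeff = float(np.sum(force_all[in_range] * d32)) / denom
        if coeff <= 0:
            return _NO_CONTACT
        resid = force_all - coeff * delta**1.5
        return float(np.sqrt(np.mean(resid**2)))

    grid = np.arange(z[0], z[-1], config.contact_search_grid_um)
    best_z0, best_rms = None, np.inf
    for z0 in grid:
        rms = objective(float(z0))
        if rms < best_rms:  # strict: ties keep the earlier (smaller) z0
            best_rms, best_z0 = rms, float(z0)
    if best_z0 is None or best_rms >= _NO_CONTACT:
        raise ContactDetectionError(
            f"curve {curve.curve_id!r}: no contact detected "
            "(residual profile never improves)"
        )
    # continuous refinement between neighbouring grid nodes
    step = config.contact_search_grid_um
    res = optimize.minimize_scalar(
        objective,
        bounds=(best_z0 - step, best_z0 + step),
        method="bounded",
        options={"xatol": 1e-6},
    )
    if res.fun < _NO_CONTACT and res.fun <= best_rms:
        best_z0 = float(res.x)
    return best_z0


def fit_curve(curve: ForceCurve, config: FitConfig | None = None) -> IndentationFit:
    """Full per-curve pipeline: baseline -> contact point -> Hertz fit.

    Applies baseline correction if the curve has not been corrected yet.
    The probe radius comes from curve.probe.
    """
    config = config or FitConfig()
    if curve.probe is None:
        raise ValidationError(f"curve {curve.curve_id!r}: probe metadata unset")
    radius = curve.probe.radius_um
    try:
        if curve.baseline is None:
            curve = baseline_correct(curve)
        z0 = find_contact_point(curve, config, radius)
        delta, force = force_indentation(curve, z0)
        fit = fit_hertz(delta, force, config, radius)
    except (ValidationError, ContactDetectionError) as exc:
        raise type(exc)(f"curve {curve.curve_id!r}: {exc}") from exc
    fit.contact_point_um = z0
    fit.curve_id = curve.curve_id
    fit.cell_id = curve.cell_id
    fit.location_id = curve.location_id
    return fit


def point_stiffness_qc(
    fits: Sequence[IndentationFit],
    alpha: float = 0.05,
    drift_tolerance: float = 0.10,
) -> PointStiffnessQC:
    """Check an acquisition-ordered modulus series for drift and normality.

    Repeated indentation can damage a cell irreversibly; a stable cell
    yields per-curve moduli that scatter normally around a mean with no
    trend against measurement number. Drift fails QC when the fitted trend
    accumulates more than ``drift_tolerance`` of the mean modulus over the
    series; non-normality fails at Shapiro–Wilk p < alpha.
    """
    e = np.array(
        [f.youngs_modulus_kpa for f in fits if f.converged], dtype=float
    )
    if e.size < _MIN_FIT_POINTS:
        raise QCError(f"need >= {_MIN_FIT_POINTS} converged fits, got {e.size}")
    if np.ptp(e) == 0:
        return PointStiffnessQC(e, 0.0, 1.0, True)
    slope = float(stats.linregress(np.arange(e.size), e).slope)
    normality_p = float(stats.shapiro(e).pvalue)
    reasons = []
    if abs(slope) * e.size > drift_tolerance * float(e.mean()):
        reasons.append(
            f"drift: |slope|*n = {abs(slope) * e.size:.3g} kPa exceeds "
            f"{drift_tolerance:.0%} of mean ({e.mean():.3g} kPa)"
        )
    if normality_p < alpha:
        reasons.append(f"non-normal modulus distribution (p = {normality_p:.3g})")
    return PointStiffnessQC(
        modulus_sequence_kpa=e,
        drift_slope_kpa_per_curve=slope,
        normality_p=normality_p,
        passed=not reasons,
        reason="; ".join(reasons) or None,
    )


def aggregate_line(
    cells: Mapping[str, Mapping[str, Sequence[IndentationFit]]],
) -> CellLineStiffness:
    """Aggregate curve -> location -> cell -> line with SEM across cells.

    ``cells`` maps cell_id -> location_id -> fits. Location mean moduli
    are averaged into a cell mean; the line mean and SEM (sd/sqrt(n)) are
    taken across cell means. Cells with no converged fit are excluded
    with a warning. A single-cell line has no SEM (None).
    """
    per_cell: dict[str, float] = {}
    n_curves = 0
    n_excluded = 0
    for cell_id, locations in cells.items():
        loc_means = []
        for fits in locations.values():
            e = [f.youngs_modulus_kpa for f in fits if f.converged]
            n_curves += len(e)
            if e:
                loc_means.append(float(np.mean(e)))
        if not loc_means:
            n_excluded += 1
            warnings.warn(
                f"cell {cell_id!r} has no converged fits; excluded", stacklevel=2
            )
            continue
        per_cell[cell_id] = float(np.mean(loc_means))
    if not per_cell:
        raise ValidationError("no cell with converged fits")
    means = np.array(list(per_cell.values()))
    sem = float(np.std(means, ddof=1) / np.sqrt(means.size)) if means.size > 1 else None
    return CellLineStiffness(
        per_cell_means_kpa=per_cell,
        line_mean_kpa=float(means.mean()),
        line_sem_kpa=sem,
        n_cells=means.size,
        n_curves=n_curves,
        n_excluded_cells=n_excluded,
    )
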