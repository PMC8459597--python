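"""Synthetic inputs for every pipeline stage, with known ground truth.

The generators emulate the measurement protocols the pipeline is built
for, at the statistical structure the analysis assumes, so that every
stage has an exact or Monte-Carlo recovery oracle:

* force curves — sphere-Hertz forward model with a pre-contact baseline
  segment, optional linear drift, and additive Gaussian deflection noise;
  the cantilever obeys F = k d simultaneously with the contact law, so the
  generated deflection solves k*d = Hertz((z - z0) - d) exactly and the
  fitting pipeline can invert it to machine precision at zero noise;
* thermal deflection — i.i.d. Gaussian with the equipartition variance
  k_B T / k;
* viability plates — multiplicative-noise fluorescence proportional to
  the viable-cell fraction on top of a blank floor;
* tumor cohorts — exponential growth V0 exp(r (1 - e) t) with lognormal
  caliper noise and a fixed L = 1.3 W aspect ratio.

Every generator is a pure function of its config (seed included):
identical configs give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .calibration import BOLTZMANN_J_PER_K
from .dose import PlateReading
from .errors import ConfigError
from .forcecurves import APPROACH, ForceCurve, ProbeSpec
from .invivo import TumorMeasurement


# ---------------------------------------------------------------------------
# force curves

@dataclass
class CurveSimConfig:
    """Forward model for one batch of synthetic approach curves.

    Defaults mirror a typical soft-cell acquisition: 2 µm diameter
    borosilicate sphere (R = 1 µm) on a 0.1 N/m lever, contact at
    z0 = 2 µm after a 2 µm baseline run-in, and a z range chosen so the
    maximal load is ``target_max_force_nN`` (0.4 nN, mid protocol range).
    ``force_noise_fraction`` expresses deflection noise as a fraction of
    the target max force (it overrides ``noise_sd_nm`` when set).
    If ``e_cell_sigma_log`` > 0, each cell draws its own true modulus from
    a lognormal centred (in the mean) on ``e_kpa``.
    """

    seed: int = 0
    e_kpa: float = 6.2
    z0_um: float = 2.0
    radius_um: float = 1.0
    nu: float = 0.5
    spring_constant: float = 0.1          # N/m
    sensitivity_nm_per_v: float | None = None  # None -> deflection in nm
    z_start_um: float = 0.0
    z_step_um: float = 0.001
    z_max_um: float | None = None         # None -> derived from target force
    target_max_force_nN: float = 0.4
    baseline_offset: float = 0.0          # deflection units
    baseline_slope_per_um: float = 0.0
    noise_sd_nm: float = 0.0
    force_noise_fraction: float | None = None
    n_curves: int = 1
    n_locations: int = 3
    n_cells: int = 1
    e_cell_sigma_log: float = 0.0


def _hertz_coeff(e_kpa: float, nu: float, radius_um: float) -> float:
    return (4.0 / 3.0) * e_kpa / (1.0 - nu**2) * np.sqrt(radius_um)


def _solve_deflection_nm(
    separation_um: np.ndarray, a_coeff: float, spring_constant: float
) -> np.ndarray:
    """Solve k*d = A * ((s - d))^1.5 for the deflection d (nm) at each s.

    s = z - z0 is the piezo travel past contact (µm). Bisection on the
    indentation delta in [0, s]; monotone, so 90 halvings reach machine
    precision.
    """
    s = np.asarray(separation_um, dtype=float)
    lo = np.zeros_like(s)
    hi = s.copy()
    kk = 1000.0 * spring_constant  # nN per µm of deflection
    for _ in range(90):
        mid = 0.5 * (lo + hi)
        # g(delta) = A delta^1.5 - k (s - delta); root where contact force
        # balances the cantilever restoring force
        g = a_coeff * mid**1.5 - kk * (s - mid)
        hi = np.where(g > 0, mid, hi)
        lo = np.where(g > 0, lo, mid)
    delta = 0.5 * (lo + hi)
    return 1000.0 * (s - delta)  # µm -> nm


def gen_force_curves(config: CurveSimConfig) -> tuple[list[ForceCurve], dict]:
    """Generate approach curves plus a per-curve ground-truth record.

    Returns (curves, truth) where truth holds ``e_kpa`` and ``z0_um``
    arrays in curve order plus the config echo. Curves carry full
    calibration metadata so the fitting pipeline accepts them unchanged.
    """
    rng = np.random.default_rng(config.seed)
    a_nominal = _hertz_coeff(config.e_kpa, config.nu, config.radius_um)
    if config.z_max_um is None:
        delta_max = (config.target_max_force_nN / a_nominal) ** (2.0 / 3.0)
        d_max_um = config.target_max_force_nN / config.spring_constant * 1e-3
        z_max = config.z0_um + delta_max + d_max_um + config.z_step_um
    else:
        z_max = config.z_max_um
    if z_max <= config.z0_um:
        raise ConfigError(
            f"z range [{config.z_start_um}, {z_max}] does not cross z0 = "
            f"{config.z0_um}"
        )
    z = np.arange(config.z_start_um, z_max, config.z_step_um)

    noise_sd = config.noise_sd_nm
    if config.force_noise_fraction is not None:
        # force noise as deflection noise: F = k d  =>  sd_d = sd_F / k
        noise_sd = (
            config.force_noise_fraction
            * config.target_max_force_nN
            / config.spring_constant
            * 1e-3
            * 1000.0
        )

    probe = ProbeSpec(
        radius_um=config.radius_um,
        nominal_spring_constant=config.spring_constant,
    )
    n_total = config.n_curves
    cells = [f"cell{c}" for c in range(config.n_cells)]
    cell_e = {}
    for cid in cells:
        if config.e_cell_sigma_log > 0:
            # lognormal with mean e_kpa: mu = ln(mean) - sigma^2/2
            mu = np.log(config.e_kpa) - config.e_cell_sigma_log**2 / 2
            cell_e[cid] = float(rng.lognormal(mu, config.e_cell_sigma_log))
        else:
            cell_e[cid] = config.e_kpa

    curves: list[ForceCurve] = []
    truth_e, truth_z0 = [], []
    for i in range(n_total):
        cid = cells[i % config.n_cells]
        lid = f"loc{(i // config.n_cells) % config.n_locations}"
        e_true = cell_e[cid]
        a_coeff = _hertz_coeff(e_true, config.nu, config.radius_um)
        d_nm = np.zeros_like(z)
        contact = z > config.z0_um
        d_nm[contact] = _solve_deflection_nm(
            z[contact] - config.z0_um, a_coeff, config.spring_constant
        )
        d_nm = d_nm + rng.normal(0.0, noise_sd, size=z.size) if noise_sd > 0 else d_nm
        if config.sensitivity_nm_per_v is not None:
            defl = d_nm / config.sensitivity_nm_per_v
            units = "V"
        else:
            defl = d_nm
            units = "nm"
        defl = defl + config.baseline_offset + config.baseline_slope_per_um * z
        curves.append(
            ForceCurve(
                piezo_position_um=z.copy(),
                deflection=defl,
                segment=np.array([APPROACH] * z.size, dtype=object),
                deflection_units=units,
                deflection_sensitivity=config.sensitivity_nm_per_v,
                spring_constant=config.spring_constant,
                probe=probe,
                curve_id=f"sim{i}",
                cell_id=cid,
                location_id=lid,
            )
        )
        truth_e.append(e_true)
        truth_z0.append(config.z0_um)
    truth = {
        "e_kpa": np.array(truth_e),
        "z0_um": np.array(truth_z0),
        "noise_sd_nm": noise_sd,
        "config": config,
    }
    return curves, truth


def gen_glass_curve(
    seed: int = 0,
    sensitivity_nm_per_v: float = 50.0,
    z0_um: float = 2.0,
    z_max_um: float = 2.2,
    z_step_um: float = 0.005,
    spring_constant: float = 0.1,
    noise_sd_v: float = 0.0,
) -> tuple[ForceCurve, dict]:
    """Rigid-substrate approach curve in volts: past contact, dz = dd.

    deflection_V = (z - z0) * 1000 / sensitivity for z > z0, zero before.
    Used to exercise the deflection-sensitivity calibration.
    """
    rng = np.random.default_rng(seed)
    z = np.arange(0.0, z_max_um, z_step_um)
    d_v = np.where(z > z0_um, (z - z0_um) * 1000.0 / sensitivity_nm_per_v, 0.0)
    if noise_sd_v > 0:
        d_v = d_v + rng.normal(0.0, noise_sd_v, size=z.size)
    curve = ForceCurve(
        piezo_position_um=z,
        deflection=d_v,
        segment=np.array([APPROACH] * z.size, dtype=object),
        deflection_units="V",
        spring_constant=spring_constant,
        probe=ProbeSpec(radius_um=1.0, nominal_spring_constant=spring_constant),
        curve_id="glass",
    )
    return curve, {"sensitivity_nm_per_v": sensitivity_nm_per_v, "z0_um": z0_um}


# ---------------------------------------------------------------------------
# thermal series

@dataclass
class ThermalSimConfig:
    seed: int = 0
    k_true: float = 0.1          # N/m
    temperature: float = 310.15  # K
    n_samples: int = 100_000


def gen_thermal_series(config: ThermalSimConfig) -> tuple[np.ndarray, dict]:
    """i.i.d. Gaussian thermal deflection (m) with variance k_B T / k."""
    rng = np.random.default_rng(config.seed)
    variance = BOLTZMANN_J_PER_K * config.temperature / config.k_true
    series = rng.normal(0.0, np.sqrt(variance), size=config.n_samples)
    return series, {"k_true": config.k_true, "variance_m2": variance}


# ---------------------------------------------------------------------------
# viability plates

@dataclass
class PlateSimConfig:
    seed: int = 0
    true_viability_pct: float = 100.0
    n_wells: int = 3
    untreated_mean: float = 900.0
    blank_mean: float = 100.0
    noise_cv: float = 0.02


def gen_plate(config: PlateSimConfig) -> tuple[PlateReading, dict]:
    """Fluorescence plate with multiplicative noise around group means.

    treated mean = blank + (untreated - blank) * V / 100, each well scaled
    by (1 + CV * eps), eps ~ N(0, 1).
    """
    rng = np.random.default_rng(config.seed)
    t_mean = config.blank_mean + (
        config.untreated_mean - config.blank_mean
    ) * config.true_viability_pct / 100.0

    def wells(mean: float) -> np.ndarray:
        return mean * (1.0 + config.noise_cv * rng.standard_normal(config.n_wells))

    reading = PlateReading(
        treated=wells(t_mean),
        untreated=wells(config.untreated_mean),
        blank=wells(config.blank_mean),
    )
    return reading, {"true_viability_pct": config.true_viability_pct}


# ---------------------------------------------------------------------------
# tumor cohorts

@dataclass
class TumorSimConfig:
    """Exponential-growth cohort with a treatment-dependent rate reduction.

    Control volumes follow V0 exp(r t); treated follow V0 exp(r (1 - e) t)
    with effect fraction e in [0, 1]. Diameters are back-solved from the
    volume under a fixed L = aspect * W shape and perturbed with lognormal
    caliper noise of the given CV.
    """

    seed: int = 0
    v0_mm3: float = 30.0
    growth_rate_per_day: float = 0.15
    treatment_effect: float = 0.5
    measurement_cv: float = 0.05
    n_subjects: int = 6
    days: Sequence[int] = tuple(range(0, 12))
    aspect: float = 1.3
    treated_group: str = "twice-daily"


def gen_tumor_cohort(
    config: TumorSimConfig,
) -> tuple[list[TumorMeasurement], dict]:
    """Control + treated cohort of caliper measurements with known rates."""
    if not (0 <= config.treatment_effect <= 1):
        raise ConfigError("treatment_effect must be in [0, 1]")
    rng = np.random.default_rng(config.seed)
    sigma = np.sqrt(np.log1p(config.measurement_cv**2)) if config.measurement_cv else 0.0
    measurements: list[TumorMeasurement] = []
    for group, rate in (
        ("control", config.growth_rate_per_day),
        (
            config.treated_group,
            config.growth_rate_per_day * (1.0 - config.treatment_effect),
        ),
    ):
        for s in range(config.n_subjects):
            sid = f"{group}-{s}"
            for day in config.days:
                v = config.v0_mm3 * np.exp(rate * day)
                w = (6.0 * v / (np.pi * config.aspect)) ** (1.0 / 3.0)
                length = config.aspect * w
                if sigma > 0:
                    w = w * rng.lognormal(-sigma**2 / 2, sigma)
                    length = length * rng.lognormal(-sigma**2 / 2, sigma)
                length, w = max(length, w), min(length, w)
                measurements.append(
                    TumorMeasurement(
                        subject_id=sid,
                        day=int(day),
                        length_mm=float(length),
                        width_mm=float(w),
                        group=group,
                    )
                )
    truth = {
        "growth_rate_per_day": config.growth_rate_per_day,
        "treatment_effect": config.treatment_effect,
        "treated_rate_per_day": config.growth_rate_per_day
        * (1.0 - config.treatment_effect),
    }
    return measurements, truth
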