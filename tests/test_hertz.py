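"""Hertz model, contact-point detection, per-curve fitting and aggregation."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cellelast as ce
from cellelast.hertz import fit_hertz, force_indentation


def _si_hertz_force_nN(delta_um, e_kpa, nu, radius_um):
    """Independent SI-unit evaluation of the sphere contact law."""
    delta_m = delta_um * 1e-6
    r_m = radius_um * 1e-6
    e_pa = e_kpa * 1e3
    f_n = (4.0 / 3.0) * e_pa / (1.0 - nu**2) * np.sqrt(r_m) * delta_m**1.5
    return f_n * 1e9


class TestHertzForce:
    def test_matches_si_unit_evaluation(self):
        f = ce.hertz_force(0.3, e_kpa=6.2, nu=0.5, radius_um=1.0)
        assert f == pytest.approx(_si_hertz_force_nN(0.3, 6.2, 0.5, 1.0), rel=1e-12)
        assert f == pytest.approx(1.81, abs=0.005)

    def test_zero_indentation_zero_force(self):
        assert ce.hertz_force(0.0, e_kpa=10.0) == 0.0

    def test_linear_in_modulus(self):
        assert ce.hertz_force(0.2, e_kpa=20.0) == pytest.approx(
            2 * ce.hertz_force(0.2, e_kpa=10.0), rel=1e-12
        )

    def test_negative_indentation_is_domain_error(self):
        with pytest.raises(ce.ParameterError):
            ce.hertz_force(-0.1, e_kpa=10.0)

    @given(
        delta=st.floats(1e-4, 0.3),
        e=st.floats(0.5, 50.0),
        r=st.floats(0.5, 5.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_three_halves_scaling(self, delta, e, r):
        """F(4 delta) = 8 F(delta) and F strictly increasing."""
        f1 = ce.hertz_force(delta, e_kpa=e, radius_um=r)
        f4 = ce.hertz_force(4 * delta, e_kpa=e, radius_um=r)
        assert f4 == pytest.approx(8 * f1, rel=1e-9)
        assert ce.hertz_force(1.01 * delta, e_kpa=e, radius_um=r) > f1


class TestForceIndentation:
    def test_generator_inversion_noiseless(self):
        """(delta, F) recovered at the true z0 match the forward model."""
        curves, truth = ce.gen_force_curves(ce.CurveSimConfig(e_kpa=6.2))
        delta, force = force_indentation(curves[0], truth["z0_um"][0])
        model = ce.hertz_force(delta, e_kpa=6.2, nu=0.5, radius_um=1.0)
        np.testing.assert_allclose(force, model, atol=1e-9)

    def test_rigid_surface_gives_zero_indentation(self):
        curve, truth = ce.gen_glass_curve(sensitivity_nm_per_v=50.0)
        curve = dataclasses.replace(curve, deflection_sensitivity=50.0)
        delta, force = force_indentation(curve, truth["z0_um"])
        assert float(np.max(delta)) < 1e-9
        assert force.max() > 0

    def test_z0_beyond_range_gives_empty(self):
        curves, _ = ce.gen_force_curves(ce.CurveSimConfig())
        delta, force = force_indentation(curves[0], 1e6)
        assert delta.size == 0 and force.size == 0

    def test_unset_spring_constant_directs_to_calibration(self):
        curves, _ = ce.gen_force_curves(ce.CurveSimConfig())
        bare = dataclasses.replace(curves[0], spring_constant=None)
        with pytest.raises(ce.ValidationError, match="calibration"):
            force_indentation(bare, 2.0)


class TestFitHertz:
    @pytest.mark.parametrize("e_true", [6.2, 34.0])
    def test_noiseless_recovery(self, e_true):
        curves, truth = ce.gen_force_curves(ce.CurveSimConfig(e_kpa=e_true))
        delta, force = force_indentation(curves[0], truth["z0_um"][0])
        fit = fit_hertz(delta, force, ce.FitConfig(), radius_um=1.0)
        assert fit.converged
        assert fit.youngs_modulus_kpa == pytest.approx(e_true, rel=1e-3)

    def test_estimator_homogeneity_in_force(self):
        curves, truth = ce.gen_force_curves(ce.CurveSimConfig(e_kpa=6.2))
        delta, force = force_indentation(curves[0], truth["z0_um"][0])
        e1 = fit_hertz(delta, force, ce.FitConfig(), 1.0).youngs_modulus_kpa
        e3 = fit_hertz(delta, 3 * force, ce.FitConfig(), 1.0).youngs_modulus_kpa
        assert e3 == pytest.approx(3 * e1, rel=1e-12)

    def test_too_few_points_not_converged(self):
        delta = np.linspace(0.01, 0.1, 5)
        force = ce.hertz_force(delta, e_kpa=5.0)
        fit = fit_hertz(delta, force, ce.FitConfig(), 1.0)
        assert not fit.converged and "in-range" in fit.reason

    def test_closed_form_matches_iterative_least_squares(self):
        """The linear-in-E closed form equals an independent nonlinear fit."""
        lmfit = pytest.importorskip("lmfit")
        curves, truth = ce.gen_force_curves(
            ce.CurveSimConfig(seed=5, e_kpa=6.2, noise_sd_nm=0.0)
        )
        delta, force = force_indentation(curves[0], truth["z0_um"][0])
        closed = fit_hertz(delta, force, ce.FitConfig(), 1.0).youngs_modulus_kpa

        model = lmfit.Model(
            lambda d, e: (4.0 / 3.0) * e / (1 - 0.5**2) * np.sqrt(1.0) * d**1.5
        )
        mask = (delta > 0) & (delta <= 0.3)
        out = model.fit(force[mask], d=delta[mask], e=1.0)
        assert closed == pytest.approx(out.params["e"].value, rel=1e-6)

    def test_unit_consistency_si_vs_canonical(self):
        """Fitting in SI units throughout gives the same modulus."""
        curves, truth = ce.gen_force_curves(ce.CurveSimConfig(e_kpa=25.0))
        delta, force = force_indentation(curves[0], truth["z0_um"][0])
        e_canonical = fit_hertz(delta, force, ce.FitConfig(), 1.0).youngs_modulus_kpa
        # feed metres/newtons; estimator then returns pascals
        e_si = fit_hertz(
            delta * 1e-6,
            force * 1e-9,
            ce.FitConfig(max_indentation_fraction=0.3),
            radius_um=1e-6,
        ).youngs_modulus_kpa
        assert e_si / 1e3 == pytest.approx(e_canonical, rel=1e-9)


class TestFindContactPoint:
    def test_noiseless_recovery_within_grid_step(self):
        curves, truth = ce.gen_force_curves(ce.CurveSimConfig(e_kpa=6.2, z0_um=2.0))
        z0 = ce.find_contact_point(curves[0], ce.FitConfig(), radius_um=1.0)
        assert z0 == pytest.approx(2.0, abs=0.005)

    def test_translation_equivariance(self):
        curves, _ = ce.gen_force_curves(ce.CurveSimConfig(e_kpa=6.2, z0_um=2.0))
        z0_a = ce.find_contact_point(curves[0], ce.FitConfig(), 1.0)
        shifted = dataclasses.replace(
            curves[0], piezo_position_um=curves[0].piezo_position_um + 0.7
        )
        z0_b = ce.find_contact_point(shifted, ce.FitConfig(), 1.0)
        assert z0_b - z0_a == pytest.approx(0.7, abs=0.005)

    def test_pure_baseline_is_detection_error(self):
        n = 400
        curve = ce.ForceCurve(
            piezo_position_um=np.linspace(0, 2, n),
            deflection=np.zeros(n),
            segment=np.array(["approach"] * n, dtype=object),
            spring_constant=0.1,
            probe=ce.ProbeSpec(radius_um=1.0, nominal_spring_constant=0.1),
        )
        with pytest.raises(ce.ContactDetectionError):
            ce.find_contact_point(curve, ce.FitConfig(), 1.0)


class TestFitCurvePipeline:
    def test_end_to_end_noiseless_within_one_percent(self):
        curves, _ = ce.gen_force_curves(
            ce.CurveSimConfig(e_kpa=6.2, baseline_offset=5.0, baseline_slope_per_um=0.5)
        )
        fit = ce.fit_curve(curves[0])
        assert fit.converged
        assert fit.youngs_modulus_kpa == pytest.approx(6.2, rel=0.01)
        assert 0.2 <= fit.max_force_nN <= 0.6  # protocol load range

    def test_glass_curve_flagged_not_a_cell(self):
        curve, _ = ce.gen_glass_curve(sensitivity_nm_per_v=50.0, z_max_um=2.1)
        curve = dataclasses.replace(curve, deflection_sensitivity=50.0)
        fit = ce.fit_curve(curve)
        assert not fit.converged
        assert "supported range" in fit.reason or "poor model fit" in fit.reason

    def test_noisy_batch_mean_within_five_percent(self):
        curves, _ = ce.gen_force_curves(
            ce.CurveSimConfig(seed=42, e_kpa=6.2, n_curves=60, force_noise_fraction=0.05)
        )
        fits = [ce.fit_curve(c) for c in curves]
        est = np.array([f.youngs_modulus_kpa for f in fits if f.converged])
        assert est.size >= 50
        assert est.mean() == pytest.approx(6.2, rel=0.05)

    def test_recovery_ladder_preserves_line_ordering(self):
        """Recovered means over the four line moduli keep their order and
        each stays within 5% (median per-curve error) of its truth."""
        truths = [1.6, 6.2, 25.0, 34.0]
        means = []
        for i, e_true in enumerate(truths):
            curves, _ = ce.gen_force_curves(
                ce.CurveSimConfig(
                    seed=100 + i, e_kpa=e_true, n_curves=60, force_noise_fraction=0.05
                )
            )
            est = np.array(
                [f.youngs_modulus_kpa for f in map(ce.fit_curve, curves) if f.converged]
            )
            median_rel_err = np.median(np.abs(est - e_true) / e_true)
            assert median_rel_err < 0.05
            means.append(est.mean())
        assert means == sorted(means)


class TestPointStiffnessQC:
    def test_iid_gaussian_sequence_passes(self):
        rng = np.random.default_rng(0)
        fits = [
            ce.IndentationFit(2.0, e, 0.01, 50, 0.4, 0.1, True)
            for e in rng.normal(6.2, 0.5, size=60)
        ]
        qc = ce.point_stiffness_qc(fits)
        assert qc.passed
        assert abs(qc.drift_slope_kpa_per_curve) * 60 < 0.1 * 6.2

    def test_monotone_ramp_fails_with_drift_reason(self):
        fits = [
            ce.IndentationFit(2.0, 5.0 + 0.1 * i, 0.01, 50, 0.4, 0.1, True)
            for i in range(30)
        ]
        qc = ce.point_stiffness_qc(fits)
        assert not qc.passed and "drift" in qc.reason

    def test_constant_sequence_zero_slope(self):
        fits = [ce.IndentationFit(2.0, 6.2, 0.01, 50, 0.4, 0.1, True)] * 20
        qc = ce.point_stiffness_qc(fits)
        assert qc.drift_slope_kpa_per_curve == 0.0
        assert qc.passed

    def test_too_few_fits_is_qc_error(self):
        fits = [ce.IndentationFit(2.0, 6.2, 0.01, 50, 0.4, 0.1, True)] * 5
        with pytest.raises(ce.QCError):
            ce.point_stiffness_qc(fits)


class TestAggregateLine:
    @staticmethod
    def _fit(e):
        return ce.IndentationFit(2.0, e, 0.01, 50, 0.4, 0.1, True)

    def test_cell_mean_is_mean_of_location_means(self):
        cells = {"c1": {"l1": [self._fit(4.0)], "l2": [self._fit(6.0)],
                        "l3": [self._fit(8.0)]}}
        agg = ce.aggregate_line(cells)
        assert agg.per_cell_means_kpa["c1"] == pytest.approx(6.0)
        assert agg.line_sem_kpa is None  # single cell: SEM undefined

    def test_line_sem_across_cells(self):
        cells = {
            f"c{i}": {"l1": [self._fit(e)]} for i, e in enumerate([5.0, 6.0, 7.0])
        }
        agg = ce.aggregate_line(cells)
        assert agg.line_mean_kpa == pytest.approx(6.0)
        assert agg.line_sem_kpa == pytest.approx(1.0 / np.sqrt(3), rel=1e-6)
        assert agg.n_cells == 3

    def test_empty_cell_excluded_with_warning(self):
        bad = ce.IndentationFit(2.0, np.nan, np.nan, 0, 0.4, 0.1, False)
        cells = {"good": {"l1": [self._fit(6.0)]}, "dead": {"l1": [bad]}}
        with pytest.warns(UserWarning, match="dead"):
            agg = ce.aggregate_line(cells)
        assert agg.n_cells == 1 and agg.n_excluded_cells == 1
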