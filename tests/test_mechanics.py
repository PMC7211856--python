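"""Shell/film element laws and the frequency-domain ladder solver."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import corpusim as cs
from corpusim.exceptions import CalibrationError, ValidationError
from corpusim.mechanics import stiffness_damping_arrays


class TestElementLaws:
    def test_massless_membrane_has_zero_stiffness(self):
        assert cs.shell_stiffness(1400.0, 0.0, 1e-4, 0.49) == 0.0

    def test_stiffness_linear_in_modulus_and_thickness(self):
        k = cs.shell_stiffness(1400.0, 1e-6, 1e-4, 0.49)
        assert cs.shell_stiffness(2800.0, 1e-6, 1e-4, 0.49) == pytest.approx(2 * k)
        assert cs.shell_stiffness(1400.0, 2e-6, 1e-4, 0.49) == pytest.approx(2 * k)

    def test_stiffness_value_against_hand_evaluation(self):
        # 2 * 1400 * 0.24e-6 / ((1 - 0.49^2) * (100e-6)^2), evaluated separately
        assert cs.shell_stiffness(1400.0, 0.24e-6, 100e-6, 0.49) == pytest.approx(
            88432.68851164627, rel=1e-12)

    def test_zero_radius_rejected(self):
        with pytest.raises(ValidationError):
            cs.shell_stiffness(1400.0, 1e-6, 0.0, 0.49)

    def test_inviscid_film_has_zero_damping(self):
        assert cs.film_damping(0.0, 1e-4, 2e-6, 1.0) == 0.0

    def test_cubic_gap_law(self):
        c = cs.film_damping(3.5e-3, 1e-4, 2e-6, 1.0)
        assert cs.film_damping(3.5e-3, 1e-4, 1e-6, 1.0) == pytest.approx(8 * c)

    def test_damping_value_against_hand_evaluation(self):
        # 3.5e-3 * (100e-6)^2 / (2e-6)^3, evaluated separately
        assert cs.film_damping(3.5e-3, 100e-6, 2e-6, 1.0) == pytest.approx(
            4.375e6, rel=1e-12)

    def test_nonpositive_gap_rejected(self):
        with pytest.raises(ValidationError):
            cs.film_damping(3.5e-3, 1e-4, 0.0, 1.0)


class TestSingleLayerOracle:
    def test_solver_matches_closed_form_across_band(self):
        fx = cs.single_layer_fixture(k=1e5, c=300.0)
        for f in np.geomspace(2.0, 1000.0, 60):
            got = abs(cs.transfer_ratio(fx.geometry, fx.materials, f,
                                        core_stiffness=fx.core_stiffness).transfer)
            assert got == pytest.approx(fx.closed_form(f), abs=1e-10, rel=1e-10)

    def test_corner_frequency_gain(self):
        fx = cs.single_layer_fixture(k=5e4, c=120.0)
        got = abs(cs.transfer_ratio(fx.geometry, fx.materials,
                                    fx.corner_frequency_hz,
                                    core_stiffness=fx.core_stiffness).transfer)
        assert got == pytest.approx(1 / math.sqrt(2), rel=1e-12)

    def test_high_pass_zero_at_low_frequency(self):
        fx = cs.single_layer_fixture(k=1e5, c=300.0)
        lo = abs(cs.transfer_ratio(fx.geometry, fx.materials, 1e-3,
                                   core_stiffness=fx.core_stiffness).transfer)
        assert lo < 1e-4

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(k=st.floats(1e3, 1e7), c=st.floats(1.0, 1e5), f=st.floats(2.0, 1000.0))
    def test_random_triples_match_closed_form(self, k, c, f):
        fx = cs.single_layer_fixture(k=k, c=c)
        got = abs(cs.transfer_ratio(fx.geometry, fx.materials, f,
                                    core_stiffness=fx.core_stiffness).transfer)
        assert got == pytest.approx(fx.closed_form(f), abs=1e-10, rel=1e-10)


def random_stack(rng, n=5):
    radius = rng.uniform(50.0, 300.0)
    spacing = 0.8 * radius / (n + 1)
    h = rng.uniform(0.05, 0.8) * spacing
    return cs.layered_geometry(radius, n, h)


def dense_solve(geometry, materials, f, k_core=None):
    """Independent dense assembly of the same harmonic balance."""
    k, c, k_core = stiffness_damping_arrays(geometry, materials, k_core)
    n = geometry.n_lamellae
    w = 2 * math.pi * f
    A = np.zeros((n + 1, n + 1), dtype=complex)
    b = np.zeros(n + 1, dtype=complex)
    A[0, 0] = k_core + 1j * w * c[0]
    A[0, 1] = -1j * w * c[0]
    for i in range(1, n + 1):
        A[i, i] = k[i - 1] + 1j * w * (c[i - 1] + c[i])
        A[i, i - 1] = -1j * w * c[i - 1]
        if i < n:
            A[i, i + 1] = -1j * w * c[i]
    b[n] = 1j * w * c[n]
    return np.linalg.solve(A, b)


class TestLadderSolver:
    def test_matches_dense_solver_on_random_stacks(self, materials):
        rng = np.random.default_rng(7)
        for _ in range(10):
            geom = random_stack(rng)
            for f in rng.uniform(2.0, 1000.0, 5):
                expected = dense_solve(geom, materials, f)
                got = cs.transfer_ratio(geom, materials, f).layer_amplitudes
                np.testing.assert_allclose(got, expected, rtol=1e-10, atol=1e-14)

    def test_transfer_bounded_and_monotone_for_cat(self, cat_geometry, materials):
        grid = np.geomspace(2.0, 1000.0, 40)
        mags = [abs(cs.transfer_ratio(cat_geometry, materials, f).transfer) for f in grid]
        assert all(m <= 1 + 1e-9 for m in mags)
        assert all(m > 0 for m in mags)
        assert np.all(np.diff(mags) >= -1e-12)

    def test_low_frequency_attenuation_for_every_species(self, records, materials):
        for rec in records:
            geom = cs.build_geometry(rec)
            lo = abs(cs.transfer_ratio(geom, materials, 2.0).transfer)
            hi = abs(cs.transfer_ratio(geom, materials, 1000.0).transfer)
            assert lo < hi, rec.common_name

    def test_linearity_in_drive_amplitude(self, cat_geometry, materials):
        base = cs.transfer_ratio(cat_geometry, materials, 50.0, amplitude_m=1.0)
        scaled = cs.transfer_ratio(cat_geometry, materials, 50.0, amplitude_m=2.5e-6)
        np.testing.assert_allclose(scaled.layer_amplitudes,
                                   base.layer_amplitudes * 2.5e-6, rtol=1e-12)
        assert scaled.transfer == pytest.approx(base.transfer, rel=1e-12)

    def test_unit_system_invariance(self, cat_geometry, materials):
        """Micrometre/kPa bookkeeping gives the same dimensionless transfer."""
        si = cs.transfer_ratio(cat_geometry, materials, 48.0).transfer
        scaled_geom = cat_geometry.scaled(1e6)  # lengths in µm
        scaled_mat = dataclasses.replace(
            materials,
            youngs_modulus=materials.youngs_modulus * 1e-3,   # kPa
            viscosity=materials.viscosity * 1e-3)             # kPa s
        other = cs.transfer_ratio(scaled_geom, scaled_mat, 48.0).transfer
        assert abs(other - si) / abs(si) < 1e-9

    def test_viscous_lock_plateau_is_approached_from_below(self, cat_geometry, materials):
        mags = [abs(cs.transfer_ratio(cat_geometry, materials, f).transfer)
                for f in (1e3, 1e4, 1e5, 1e6)]
        assert np.all(np.diff(mags) >= 0)
        assert mags[-1] <= 1 + 1e-9


class TestCalibrationSearch:
    """Bisection logic exercised against a fast analytic stand-in pipeline."""

    @staticmethod
    def fake_evaluator(geometry, mats):
        # smooth, monotone decreasing peak-vs-kappa law
        return 400.0 / (1.0 + 10.0 * mats.kappa)

    def test_reaches_target_within_tolerance(self, cat_geometry, materials):
        kappa = cs.calibrate_kappa(cat_geometry, materials, self.fake_evaluator, 48.0)
        assert self.fake_evaluator(None, dataclasses.replace(materials, kappa=kappa)) \
            == pytest.approx(48.0, rel=0.02)

    def test_is_deterministic(self, cat_geometry, materials):
        k1 = cs.calibrate_kappa(cat_geometry, materials, self.fake_evaluator, 48.0)
        k2 = cs.calibrate_kappa(cat_geometry, materials, self.fake_evaluator, 48.0)
        assert k1 == k2

    def test_unreachable_target_reports_achievable_range(self, cat_geometry, materials):
        with pytest.raises(CalibrationError, match="achievable"):
            cs.calibrate_kappa(cat_geometry, materials, self.fake_evaluator, 2.5,
                               bracket=(1e-3, 1.0))
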