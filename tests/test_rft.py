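"""Unit and property tests for the single-cell RFT swimming model."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microswim.rft import (CellBody, DEFAULT_HELIX, HelixGeometry, ModelConfig,
                           MotorModel, PropulsionMatrix, SlenderBodyError,
                           SwimSolution, body_drag, bundle_geometry,
                           default_flagellar_length, friction_coefficients,
                           propulsion_matrix, solve_swim, torque_per_motor,
                           velocity_vs_flagella)

MU = 1e-3


from conftest import solve_closed_form


def helix_with_log_term(log_value: float) -> HelixGeometry:
    """Helix whose Gray–Hancock log term ln(2P/a) equals ``log_value``."""
    pitch = 2.2
    a = 2.0 * pitch / math.exp(log_value)
    return HelixGeometry(0.2, pitch, 6.0, a)


# ---------------------------------------------------------------------------
# Friction coefficients
# ---------------------------------------------------------------------------

class TestFrictionCoefficients:
    def test_gray_hancock_log_term_ten(self):
        """ln(2P/a) = 10 gives xi_par = 2 pi mu / 9.5, xi_perp = 4 pi mu / 10.5."""
        fc = friction_coefficients(helix_with_log_term(10.0), MU,
                                   "gray_hancock")
        assert fc.xi_par == pytest.approx(2 * math.pi * MU / 9.5, rel=1e-12)
        assert fc.xi_perp == pytest.approx(4 * math.pi * MU / 10.5, rel=1e-12)
        assert fc.xi_perp / fc.xi_par == pytest.approx(19 / 10.5, rel=1e-12)

    def test_thin_filament_limit_ratio_two(self):
        """The drag anisotropy approaches 2 for a vanishing filament radius."""
        helix = HelixGeometry(0.2, 2.2, 6.0, 1e-300)
        ratios = [friction_coefficients(helix, MU, v).xi_perp
                  / friction_coefficients(helix, MU, v).xi_par
                  for v in ("gray_hancock", "lighthill")]
        assert all(abs(r - 2.0) < 5e-3 for r in ratios)

    @pytest.mark.parametrize("variant", ["gray_hancock", "lighthill"])
    def test_slender_body_ordering_on_default_filament(self, variant):
        fc = friction_coefficients(DEFAULT_HELIX, MU, variant)
        assert 1.0 < fc.xi_perp / fc.xi_par < 2.0

    def test_thick_filament_rejected(self):
        """A filament comparable to the pitch is outside the slender regime."""
        thick = HelixGeometry(0.2, 0.004, 6.0, 0.01)
        with pytest.raises(SlenderBodyError):
            friction_coefficients(thick, MU, "gray_hancock")

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            friction_coefficients(DEFAULT_HELIX, MU, "slender_body_theory")


# ---------------------------------------------------------------------------
# Bundle geometry
# ---------------------------------------------------------------------------

class TestBundleGeometry:
    def test_single_flagellum_is_identity(self):
        b = bundle_geometry(1, DEFAULT_HELIX)
        assert b.effective_filament_radius_um == DEFAULT_HELIX.filament_radius_um
        assert b.effective_axial_length_um == default_flagellar_length(1)

    def test_sqrt_thickening_rule(self):
        base = replace(DEFAULT_HELIX, filament_radius_um=0.01)
        b = bundle_geometry(4, base)
        assert b.effective_filament_radius_um == pytest.approx(0.02)

    def test_thickness_and_length_monotone_in_n(self):
        bundles = [bundle_geometry(n, DEFAULT_HELIX) for n in range(1, 11)]
        radii = [b.effective_filament_radius_um for b in bundles]
        lengths = [b.effective_axial_length_um for b in bundles]
        assert all(r2 > r1 for r1, r2 in zip(radii, radii[1:]))
        assert all(l2 >= l1 for l1, l2 in zip(lengths, lengths[1:]))

    def test_explicit_length_override(self):
        b = bundle_geometry(3, DEFAULT_HELIX, length_rule=lambda n: 5.5)
        assert b.effective_axial_length_um == 5.5

    def test_invalid_count_rejected(self):
        with pytest.raises(ValueError):
            bundle_geometry(0, DEFAULT_HELIX)


# ---------------------------------------------------------------------------
# Propulsion matrix
# ---------------------------------------------------------------------------

class TestPropulsionMatrix:
    def test_zero_pitch_angle_limit(self):
        """A nearly straight filament produces no translation-rotation
        coupling: B -> 0, A -> Lambda xi_par, C -> Lambda R^2 xi_perp."""
        helix = HelixGeometry(1e-6, 2.2, 6.0, 1e-8)
        fc = friction_coefficients(helix, MU)
        pm = propulsion_matrix(helix, fc)
        lam = helix.contour_length_um
        R = helix.helix_radius_um
        assert pm.B == pytest.approx(0.0, abs=1e-12)
        assert pm.A == pytest.approx(lam * fc.xi_par, rel=1e-9)
        assert pm.C == pytest.approx(lam * R ** 2 * fc.xi_perp, rel=1e-9)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(R=st.floats(0.05, 0.5), P=st.floats(0.5, 5.0),
           ell=st.floats(1.0, 12.0), a=st.floats(0.005, 0.02))
    def test_determinant_identity(self, R, P, ell, a):
        """AC - B^2 = Lambda^2 R^2 xi_par xi_perp for all valid geometries."""
        if a >= R:
            return
        helix = HelixGeometry(R, P, ell, a)
        fc = friction_coefficients(helix, MU)
        pm = propulsion_matrix(helix, fc)
        lam = helix.contour_length_um
        expect = lam ** 2 * R ** 2 * fc.xi_par * fc.xi_perp
        assert pm.A * pm.C - pm.B ** 2 == pytest.approx(expect, rel=1e-12)

    def test_linear_in_contour_length(self):
        fc = friction_coefficients(DEFAULT_HELIX, MU)
        pm1 = propulsion_matrix(DEFAULT_HELIX, fc)
        doubled = replace(DEFAULT_HELIX,
                          axial_length_um=2 * DEFAULT_HELIX.axial_length_um)
        pm2 = propulsion_matrix(doubled, fc)
        assert pm2.A == pytest.approx(2 * pm1.A, rel=1e-12)
        assert pm2.B == pytest.approx(2 * pm1.B, rel=1e-12)
        assert pm2.C == pytest.approx(2 * pm1.C, rel=1e-12)

    def test_handedness_flips_coupling_sign(self):
        fc = friction_coefficients(DEFAULT_HELIX, MU)
        left = propulsion_matrix(DEFAULT_HELIX, fc)
        right = propulsion_matrix(replace(DEFAULT_HELIX, handedness="right"),
                                  fc)
        assert left.B > 0
        assert right.B == pytest.approx(-left.B, rel=1e-12)


# ---------------------------------------------------------------------------
# Body drag
# ---------------------------------------------------------------------------

class TestBodyDrag:
    def test_no_wobble_projection(self):
        bd = body_drag(CellBody(3.0, 0.9, 0.0), MU)
        assert bd.A0_eff == bd.A0_par
        assert bd.C0_eff == bd.C0_axial

    def test_stokes_sphere_limit(self):
        bd = body_drag(CellBody(1.0, 1.0, 0.0), MU)
        assert bd.A0_par == pytest.approx(6 * math.pi * MU * 0.5, rel=1e-6)
        assert bd.A0_perp == pytest.approx(6 * math.pi * MU * 0.5, rel=1e-6)
        assert bd.C0_axial == pytest.approx(8 * math.pi * MU * 0.125, rel=1e-6)

    def test_default_rod_anisotropy(self):
        bd = body_drag(CellBody(3.0, 0.9, 0.0), MU)
        assert 1.0 < bd.A0_perp / bd.A0_par < 2.0

    def test_wobble_mixes_drags(self):
        theta = math.radians(30.0)
        bd = body_drag(CellBody(3.0, 0.9, theta), MU)
        c2, s2 = math.cos(theta) ** 2, math.sin(theta) ** 2
        assert bd.A0_eff == pytest.approx(bd.A0_par * c2 + bd.A0_perp * s2)
        assert bd.C0_eff == pytest.approx(bd.C0_axial * c2
                                          + bd.C0_transverse * s2)
        assert bd.A0_eff > bd.A0_par


# ---------------------------------------------------------------------------
# Force/torque balance
# ---------------------------------------------------------------------------

class TestSolveSwim:
    def test_motor_frequency_conserved_for_default(self):
        cfg = ModelConfig()
        for n in range(1, 9):
            sol = cfg.solve_for_n(n)
            assert sol.omega_flag_hz + sol.omega_body_hz == pytest.approx(
                220.0, rel=1e-12)

    def test_matches_closed_form_oracle_on_random_draws(self, rng):
        """Dense linear solve equals the independent scalar elimination on
        100 random parameterizations, with residuals at tolerance."""
        for _ in range(100):
            R = rng.uniform(0.05, 0.5)
            helix = HelixGeometry(R, rng.uniform(0.5, 5.0),
                                  rng.uniform(1.0, 12.0),
                                  min(rng.uniform(0.005, 0.02), 0.5 * R))
            body = CellBody(rng.uniform(1.5, 5.0), rng.uniform(0.5, 1.2),
                            rng.uniform(0.0, 0.6))
            motor = MotorModel(rng.uniform(50.0, 400.0))
            fc = friction_coefficients(helix, MU)
            pm = propulsion_matrix(helix, fc)
            bd = body_drag(body, MU)
            sol = solve_swim(pm, bd, motor, MU)
            v, w, W = solve_closed_form(pm, bd.A0_eff, bd.C0_eff,
                                        motor.motor_frequency_hz)
            assert sol.v_um_s == pytest.approx(v, rel=1e-10)
            assert sol.omega_flag_hz == pytest.approx(w / (2 * math.pi),
                                                      rel=1e-10)
            assert sol.omega_body_hz == pytest.approx(W / (2 * math.pi),
                                                      rel=1e-10)
            assert sol.force_residual_rel <= 1e-10
            assert sol.torque_residual_rel <= 1e-10

    def test_achiral_bundle_produces_no_thrust(self):
        """B = 0 (achiral filament): v = 0 and the motor speed is split by
        the torque balance alone."""
        pm = PropulsionMatrix(A=0.05, B=0.0, C=0.002)
        bd = body_drag(CellBody(3.0, 0.9, 0.0), MU)
        sol = solve_swim(pm, bd, MotorModel(220.0), MU)
        assert sol.v_um_s == 0.0
        assert sol.omega_flag_hz + sol.omega_body_hz == pytest.approx(220.0)
        # torque balance partition: C omega = C0 Omega
        assert pm.C * sol.omega_flag_hz == pytest.approx(
            bd.C0_eff * sol.omega_body_hz, rel=1e-9)

    def test_viscosity_invariance_of_kinematics(self):
        cfg1 = ModelConfig()
        cfg2 = ModelConfig(viscosity_pa_s=2 * cfg1.viscosity_pa_s)
        s1, s2 = cfg1.solve_for_n(4), cfg2.solve_for_n(4)
        assert s2.v_um_s == pytest.approx(s1.v_um_s, rel=1e-12)
        assert s2.omega_flag_hz == pytest.approx(s1.omega_flag_hz, rel=1e-12)
        assert s2.omega_body_hz == pytest.approx(s1.omega_body_hz, rel=1e-12)
        assert s2.bundle_torque_pn_um == pytest.approx(
            2 * s1.bundle_torque_pn_um, rel=1e-12)

    def test_kinematics_linear_in_motor_speed(self):
        cfg1 = ModelConfig()
        cfg2 = ModelConfig(motor=MotorModel(440.0))
        s1, s2 = cfg1.solve_for_n(3), cfg2.solve_for_n(3)
        assert s2.v_um_s == pytest.approx(2 * s1.v_um_s, rel=1e-12)
        assert s2.omega_flag_hz == pytest.approx(2 * s1.omega_flag_hz,
                                                 rel=1e-12)
        assert s2.omega_body_hz == pytest.approx(2 * s1.omega_body_hz,
                                                 rel=1e-12)


class TestTorquePerMotor:
    def test_single_motor_carries_bundle_torque(self):
        sol = ModelConfig().solve_for_n(1)
        assert torque_per_motor(sol, 1) == sol.bundle_torque_pn_um

    def test_load_per_motor_decreases_with_n(self):
        cfg = ModelConfig()
        loads = [torque_per_motor(cfg.solve_for_n(n), n)
                 for n in range(1, 9)]
        assert all(l2 < l1 for l1, l2 in zip(loads, loads[1:]))

    def test_zero_torque_case(self):
        sol = SwimSolution(0.0, 100.0, 120.0, 0.0, MU, 0.0, 0.0)
        assert torque_per_motor(sol, 5) == 0.0


# ---------------------------------------------------------------------------
# Velocity vs flagellar number
# ---------------------------------------------------------------------------

class TestVelocityVsFlagella:
    def test_degenerate_sweep_equals_single_solve(self):
        cfg = ModelConfig()
        df = velocity_vs_flagella(cfg, [1])
        sol = cfg.solve_for_n(1)
        assert len(df) == 1
        assert df.loc[0, "v_um_s"] == sol.v_um_s

    def test_saturation_of_speed_with_n(self):
        """Speed rises with N then plateaus: early relative increments are
        large, late ones vanish."""
        v = velocity_vs_flagella().v_um_s.to_numpy()
        assert np.all(np.diff(v) >= 0)
        assert v[9] / v[4] < 1.10
        assert v[1] / v[0] > v[9] / v[8]

    def test_friction_variants_agree_on_normalized_curve(self):
        gh = velocity_vs_flagella(ModelConfig()).v_um_s.to_numpy()
        lh = velocity_vs_flagella(
            ModelConfig(friction_variant="lighthill")).v_um_s.to_numpy()
        gh_n, lh_n = gh / gh[0], lh / lh[0]
        assert np.max(np.abs(gh_n - lh_n) / gh_n) <= 0.15

    def test_saturation_mechanism_body_drag_negligible(self):
        """With body drag negligible, v/omega = B/A independent of N at
        fixed filament length: adding flagella buys no extra speed."""
        cfg = ModelConfig(length_rule=None)
        tiny = body_drag(CellBody(3.0, 0.9, 0.0), MU)
        tiny = replace(tiny, A0_eff=1e-12, C0_eff=tiny.C0_eff)
        ratios = []
        for n in (1, 4, 8):
            from microswim.rft import bundle_geometry as bg
            bundle = bg(n, cfg.helix, None)
            fc = friction_coefficients(bundle.helix, MU)
            pm = propulsion_matrix(bundle, fc)
            sol = solve_swim(pm, tiny, cfg.motor, MU)
            w = 2 * math.pi * sol.omega_flag_hz
            ratios.append((sol.v_um_s / w) / (pm.B / pm.A))
        assert all(r == pytest.approx(1.0, rel=1e-9) for r in ratios)
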