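"""Resistive-force-theory (RFT) model of a multi-flagellated bacterial swimmer.

A swimming bacterium is modelled as a rigid helical flagellar bundle attached
to a counter-rotating rod-shaped cell body.  The bundle is described by a
2x2 propulsion matrix (A, B; B, C) obtained from local anisotropic drag
coefficients (RFT); the body by prolate-spheroid (Perrin) drag coefficients,
projected onto the swimming axis through the wobble angle theta.  The three
kinematic unknowns -- swimming speed v, bundle rotation rate omega and body
counter-rotation rate Omega -- follow from

    force balance:    (A + A0_eff) * v = B * omega
    torque balance:   C * omega - B * v = C0_eff * Omega
    motor constraint: omega + Omega = omega_m   (constant motor speed)

Multiple flagella are treated as a single tight bundle: a thicker effective
filament (radius a * sqrt(N) by default) whose length follows the empirical
length-vs-number coupling.  The motor speed is held constant (default 220 Hz)
independent of flagellar number and load.

Unit conventions
----------------
Lengths in micrometres, viscosity in Pa*s, speeds in um/s, rotation rates
reported in Hz (revolutions/s), forces in pN and torques in pN*um.  These are
mutually consistent: with xi in Pa*s and lengths in um, drag * speed lands
directly in pN without conversion factors.  Internally the torque balance is
written in angular velocity (rad/s = 2*pi*Hz).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HelixGeometry",
    "BundleModel",
    "FrictionCoefficients",
    "PropulsionMatrix",
    "CellBody",
    "BodyDrag",
    "MotorModel",
    "SwimSolution",
    "ModelConfig",
    "SlenderBodyError",
    "friction_coefficients",
    "bundle_geometry",
    "propulsion_matrix",
    "body_drag",
    "solve_swim",
    "torque_per_motor",
    "velocity_vs_flagella",
    "default_flagellar_length",
    "DEFAULT_MOTOR_HZ",
    "DEFAULT_VISCOSITY_PA_S",
]

# Default wild-type parameterization: normal E. coli filament helix,
# 3.0 x 0.9 um cell body, water-like buffer, 220 Hz motor speed.
DEFAULT_MOTOR_HZ = 220.0
DEFAULT_VISCOSITY_PA_S = 1.0e-3
_RESIDUAL_RTOL = 1e-10


class SlenderBodyError(ValueError):
    """Filament too thick relative to the pitch: out of slender-body regime."""


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HelixGeometry:
    """Rigid helix: radius R, pitch P, axial extent ell, filament radius a.

    The pitch angle is psi = arctan(2*pi*R / P) and the contour length
    Lambda = ell / cos(psi) >= ell.
    """

    helix_radius_um: float
    pitch_um: float
    axial_length_um: float
    filament_radius_um: float
    handedness: str = "left"

    def __post_init__(self) -> None:
        for name in ("helix_radius_um", "pitch_um", "axial_length_um",
                     "filament_radius_um"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.filament_radius_um >= self.helix_radius_um:
            raise ValueError("filament radius must be smaller than helix radius")
        if self.handedness not in ("left", "right"):
            raise ValueError("handedness must be 'left' or 'right'")

    @property
    def pitch_angle_rad(self) -> float:
        return math.atan2(2.0 * math.pi * self.helix_radius_um, self.pitch_um)

    @property
    def contour_length_um(self) -> float:
        return self.axial_length_um / math.cos(self.pitch_angle_rad)


#: Normal E. coli flagellar filament: 0.2 um helix radius, 2.2 um pitch,
#: 10 nm filament radius, left-handed.
DEFAULT_HELIX = HelixGeometry(
    helix_radius_um=0.2,
    pitch_um=2.2,
    axial_length_um=6.0,
    filament_radius_um=0.010,
    handedness="left",
)


def default_flagellar_length(n_flagella: float) -> float:
    """Axial bundle length (um) vs flagellar number: saturating coupling.

    L(N) = L_max * N / (N_half + N) with L_max = 10 um, N_half = 2.5,
    i.e. ~2.9 um for a single filament rising to ~8 um at N = 10, mirroring
    the observed moderate increase of filament length with expression
    followed by saturation.
    """
    if n_flagella < 1:
        raise ValueError("n_flagella must be >= 1")
    return 10.0 * n_flagella / (2.5 + n_flagella)


@dataclass(frozen=True)
class BundleModel:
    """Effective single-helix description of an N-flagella bundle."""

    n_flagella: int
    base: HelixGeometry
    effective_filament_radius_um: float
    effective_axial_length_um: float

    def __post_init__(self) -> None:
        if self.n_flagella < 1:
            raise ValueError("n_flagella must be >= 1")
        if self.effective_filament_radius_um < self.base.filament_radius_um:
            raise ValueError("effective filament radius cannot shrink below "
                             "the single-filament radius")
        if self.effective_axial_length_um <= 0:
            raise ValueError("effective axial length must be > 0")

    @property
    def helix(self) -> HelixGeometry:
        """The effective helix carrying the bundle thickness and length."""
        return replace(
            self.base,
            filament_radius_um=self.effective_filament_radius_um,
            axial_length_um=self.effective_axial_length_um,
        )


def bundle_geometry(
    n_flagella: int,
    base: HelixGeometry = DEFAULT_HELIX,
    length_rule: Callable[[float], float] | None = default_flagellar_length,
    radius_exponent: float = 0.5,
) -> BundleModel:
    """Effective bundle for N flagella.

    The bundle thickens as a_b = a * N**radius_exponent (default square root:
    cross-sectional area of N close-packed filaments) and its axial length
    follows ``length_rule`` (default: the saturating length-vs-number
    coupling).  ``length_rule=None`` keeps the base axial length.
    """
    if n_flagella < 1:
        raise ValueError("n_flagella must be >= 1")
    a_b = base.filament_radius_um * float(n_flagella) ** radius_exponent
    ell_b = (base.axial_length_um if length_rule is None
             else float(length_rule(n_flagella)))
    return BundleModel(
        n_flagella=int(n_flagella),
        base=base,
        effective_filament_radius_um=a_b,
        effective_axial_length_um=ell_b,
    )


# ---------------------------------------------------------------------------
# Friction coefficients and propulsion matrix
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FrictionCoefficients:
    """Local drag per unit filament length, parallel and perpendicular."""

    xi_par: float
    xi_perp: float
    variant: str

    def __post_init__(self) -> None:
        if not (0 < self.xi_par < self.xi_perp <= 2.0 * self.xi_par + 1e-12):
            raise SlenderBodyError(
                "friction coefficients out of slender-body regime "
                f"(xi_par={self.xi_par:.3g}, xi_perp={self.xi_perp:.3g}); "
                "filament too thick for the chosen variant")


def friction_coefficients(
    helix: HelixGeometry,
    mu: float = DEFAULT_VISCOSITY_PA_S,
    variant: str = "gray_hancock",
) -> FrictionCoefficients:
    """RFT drag coefficients per unit length for a thin helical filament.

    Two classical variants:

    * ``gray_hancock``: xi_par = 2*pi*mu / (ln(2P/a) - 1/2),
      xi_perp = 4*pi*mu / (ln(2P/a) + 1/2)
    * ``lighthill``:    xi_par = 2*pi*mu / ln(0.18*P/(a*cos psi)),
      xi_perp = 4*pi*mu / (ln(0.18*P/(a*cos psi)) + 1/2)

    Raises :class:`SlenderBodyError` when the logarithm's argument drops to
    <= 1 (filament comparable to the pitch) or the resulting coefficients
    leave the slender-body ordering 0 < xi_par < xi_perp <= 2*xi_par.
    """
    if mu <= 0:
        raise ValueError("viscosity must be > 0")
    a = helix.filament_radius_um
    P = helix.pitch_um
    if variant == "gray_hancock":
        arg = 2.0 * P / a
    elif variant == "lighthill":
        arg = 0.18 * P / (a * math.cos(helix.pitch_angle_rad))
    else:
        raise ValueError(f"unknown friction variant {variant!r}")
    if arg <= 1.0:
        raise SlenderBodyError(
            f"log argument {arg:.3g} <= 1: filament too thick, "
            "out of slender-body regime")
    log = math.log(arg)
    if variant == "gray_hancock":
        denom_par, denom_perp = log - 0.5, log + 0.5
    else:
        denom_par, denom_perp = log, log + 0.5
    if denom_par <= 0:
        raise SlenderBodyError(
            "logarithmic denominator non-positive: out of slender-body regime")
    return FrictionCoefficients(
        xi_par=2.0 * math.pi * mu / denom_par,
        xi_perp=4.0 * math.pi * mu / denom_perp,
        variant=variant,
    )


@dataclass(frozen=True)
class PropulsionMatrix:
    """Symmetric helix propulsion matrix (A, B; B, C).

    A couples axial force to translation, C torque to rotation, and B is the
    thrust-generating translation-rotation coupling.  Units (with the module's
    conventions): A in Pa*s*um, B in Pa*s*um^2, C in Pa*s*um^3, so that
    A*v is in pN and C*omega in pN*um.
    """

    A: float
    B: float
    C: float

    def __post_init__(self) -> None:
        if self.A <= 0 or self.C <= 0:
            raise ValueError("diagonal propulsion coefficients must be > 0")
        if self.A * self.C - self.B ** 2 <= 0:
            raise ValueError("propulsion matrix must be positive definite")


def propulsion_matrix(
    bundle: BundleModel | HelixGeometry,
    coeffs: FrictionCoefficients,
) -> PropulsionMatrix:
    """Propulsion matrix of the (effective) helix from its RFT coefficients.

    With pitch angle psi, contour length Lambda and helix radius R:

        A = Lambda * (xi_par cos^2 psi + xi_perp sin^2 psi)
        B = sgn * Lambda * R * sin psi * cos psi * (xi_perp - xi_par)
        C = Lambda * R^2 * (xi_perp cos^2 psi + xi_par sin^2 psi)

    satisfying A*C - B^2 = Lambda^2 R^2 xi_par xi_perp exactly.  The sign of
    B follows handedness; the package convention (left-handed helix, thrust
    forward for positive bundle rotation) makes B > 0 for ``left``.
    """
    helix = bundle.helix if isinstance(bundle, BundleModel) else bundle
    psi = helix.pitch_angle_rad
    lam = helix.contour_length_um
    R = helix.helix_radius_um
    c, s = math.cos(psi), math.sin(psi)
    sign = 1.0 if helix.handedness == "left" else -1.0
    return PropulsionMatrix(
        A=lam * (coeffs.xi_par * c * c + coeffs.xi_perp * s * s),
        B=sign * lam * R * s * c * (coeffs.xi_perp - coeffs.xi_par),
        C=lam * R * R * (coeffs.xi_perp * c * c + coeffs.xi_par * s * s),
    )


# ---------------------------------------------------------------------------
# Cell body drag
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellBody:
    """Rod-shaped cell body with a wobble angle theta (radians) between the
    body axis and the swimming direction."""

    body_length_um: float = 3.0
    body_width_um: float = 0.9
    wobble_angle_rad: float = 0.0

    def __post_init__(self) -> None:
        if not self.body_width_um > 0:
            raise ValueError("body width must be > 0")
        if self.body_length_um < self.body_width_um:
            raise ValueError("body length must be >= body width")
        if not 0 <= self.wobble_angle_rad < math.pi / 2:
            raise ValueError("wobble angle must lie in [0, pi/2)")


@dataclass(frozen=True)
class BodyDrag:
    """Perrin drag coefficients of the body with wobble-projected effective
    values.  A0 entries in Pa*s*um, C0 entries in Pa*s*um^3."""

    A0_par: float
    A0_perp: float
    C0_axial: float
    C0_transverse: float
    A0_eff: float
    C0_eff: float

    def __post_init__(self) -> None:
        vals = (self.A0_par, self.A0_perp, self.C0_axial, self.C0_transverse,
                self.A0_eff, self.C0_eff)
        if any(v <= 0 for v in vals):
            raise ValueError("all body drag coefficients must be > 0")
        if self.A0_perp < self.A0_par:
            raise ValueError("perpendicular translational drag must exceed "
                             "parallel drag for an elongated body")


def _perrin_coefficients(a_semi: float, b_semi: float) -> tuple[float, float, float, float]:
    """Translational and rotational Stokes drags of a prolate spheroid with
    semi-axes a_semi >= b_semi, per unit viscosity.

    Returns (A_par, A_perp, C_axial, C_transverse) such that multiplying by
    mu gives the drag.  The near-spherical case is evaluated by the Stokes
    sphere limit to avoid catastrophic cancellation.
    """
    e2 = 1.0 - (b_semi / a_semi) ** 2
    e = math.sqrt(max(e2, 0.0))
    if e < 1e-5:
        r = 0.5 * (a_semi + b_semi)
        return (6 * math.pi * r, 6 * math.pi * r,
                8 * math.pi * r ** 3, 8 * math.pi * r ** 3)
    L = math.log((1 + e) / (1 - e))
    A_par = 16 * math.pi * a_semi * e ** 3 / (-2 * e + (1 + e2) * L)
    A_perp = 32 * math.pi * a_semi * e ** 3 / (2 * e + (3 * e2 - 1) * L)
    C_axial = (32.0 / 3.0) * math.pi * a_semi * b_semi ** 2 * e ** 3 \
        / (2 * e - (1 - e2) * L)
    C_trans = (32.0 / 3.0) * math.pi * a_semi ** 3 * e ** 3 * (2 - e2) \
        / (-2 * e + (1 + e2) * L)
    return A_par, A_perp, C_axial, C_trans


def body_drag(body: CellBody, mu: float = DEFAULT_VISCOSITY_PA_S) -> BodyDrag:
    """Drag operator of the cell body, modelled as a prolate spheroid with
    semi-axes (length/2, width/2).

    Wobbling at angle theta mixes parallel and perpendicular components:
    A0_eff = A0_par cos^2 theta + A0_perp sin^2 theta, and likewise for the
    rotational drag with the axial and transverse (tumbling) coefficients.
    A sphere (length = width) reduces to the Stokes limits 6*pi*mu*r and
    8*pi*mu*r^3.
    """
    if mu <= 0:
        raise ValueError("viscosity must be > 0")
    A_par, A_perp, C_ax, C_tr = _perrin_coefficients(
        body.body_length_um / 2.0, body.body_width_um / 2.0)
    th = body.wobble_angle_rad
    c2, s2 = math.cos(th) ** 2, math.sin(th) ** 2
    return BodyDrag(
        A0_par=mu * A_par,
        A0_perp=mu * A_perp,
        C0_axial=mu * C_ax,
        C0_transverse=mu * C_tr,
        A0_eff=mu * (A_par * c2 + A_perp * s2),
        C0_eff=mu * (C_ax * c2 + C_tr * s2),
    )


# ---------------------------------------------------------------------------
# Force/torque balance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotorModel:
    """Constant-speed flagellar motor: rotation rate of the flagellum
    relative to the cell body, in Hz, independent of load and of N."""

    motor_frequency_hz: float = DEFAULT_MOTOR_HZ

    def __post_init__(self) -> None:
        if not self.motor_frequency_hz > 0:
            raise ValueError("motor frequency must be > 0")


@dataclass(frozen=True)
class SwimSolution:
    """Kinematic output of the force/torque balance.

    ``omega_flag_hz`` and ``omega_body_hz`` are the lab-frame bundle and
    body rotation rates (body reported as a magnitude); their sum equals the
    motor frequency.  ``bundle_torque_pn_um`` is the hydrodynamic torque on
    the bundle, shared equally among the N motors.
    """

    v_um_s: float
    omega_flag_hz: float
    omega_body_hz: float
    bundle_torque_pn_um: float
    viscosity_pa_s: float
    force_residual_rel: float
    torque_residual_rel: float

    @property
    def motor_frequency_hz(self) -> float:
        return self.omega_flag_hz + self.omega_body_hz


def solve_swim(
    pm: PropulsionMatrix,
    bd: BodyDrag,
    motor: MotorModel,
    mu: float = DEFAULT_VISCOSITY_PA_S,
) -> SwimSolution:
    """Solve the linear force/torque balance under the constant-motor-speed
    constraint.

    Unknowns x = (v, omega, Omega) with omega, Omega angular velocities
    (rad/s) of bundle and body:

        (A + A0_eff) v - B omega             = 0      (force-free swimmer)
        -B v + C omega - C0_eff Omega        = 0      (torque-free swimmer)
        omega + Omega                        = 2*pi*f_m

    The system is solved densely; residuals are checked against a 1e-10
    relative tolerance and carried on the solution.
    """
    w_m = 2.0 * math.pi * motor.motor_frequency_hz
    M = np.array([
        [pm.A + bd.A0_eff, -pm.B, 0.0],
        [-pm.B, pm.C, -bd.C0_eff],
        [0.0, 1.0, 1.0],
    ])
    rhs = np.array([0.0, 0.0, w_m])
    try:
        v, w_flag, w_body = np.linalg.solve(M, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValueError("degenerate drag operators: singular balance "
                         "system") from exc
    f_scale = max(abs((pm.A + bd.A0_eff) * v), abs(pm.B * w_flag), 1e-300)
    t_scale = max(abs(pm.C * w_flag), abs(pm.B * v),
                  abs(bd.C0_eff * w_body), 1e-300)
    f_res = abs((pm.A + bd.A0_eff) * v - pm.B * w_flag) / f_scale
    t_res = abs(pm.C * w_flag - pm.B * v - bd.C0_eff * w_body) / t_scale
    if f_res > _RESIDUAL_RTOL or t_res > _RESIDUAL_RTOL:
        raise ValueError(
            f"balance residuals exceed tolerance (force {f_res:.2e}, "
            f"torque {t_res:.2e})")
    return SwimSolution(
        v_um_s=float(v),
        omega_flag_hz=float(w_flag / (2 * math.pi)),
        omega_body_hz=float(w_body / (2 * math.pi)),
        bundle_torque_pn_um=float(pm.C * w_flag - pm.B * v),
        viscosity_pa_s=mu,
        force_residual_rel=float(f_res),
        torque_residual_rel=float(t_res),
    )


def torque_per_motor(sol: SwimSolution, n_flagella: int) -> float:
    """Load per motor (pN*um): the bundle torque shared by the N motors."""
    if n_flagella < 1:
        raise ValueError("n_flagella must be >= 1")
    return sol.bundle_torque_pn_um / n_flagella


# ---------------------------------------------------------------------------
# Model configuration and N-sweep
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelConfig:
    """Full single-cell parameterization of the swimming model."""

    helix: HelixGeometry = DEFAULT_HELIX
    body: CellBody = CellBody()
    motor: MotorModel = MotorModel()
    viscosity_pa_s: float = DEFAULT_VISCOSITY_PA_S
    friction_variant: str = "gray_hancock"
    bundle_radius_exponent: float = 0.5
    length_rule: Callable[[float], float] | None = field(
        default=default_flagellar_length, compare=False)

    def solve_for_n(self, n_flagella: int,
                    body: CellBody | None = None) -> SwimSolution:
        """Bundle geometry -> propulsion matrix -> balance for one N."""
        bundle = bundle_geometry(n_flagella, self.helix, self.length_rule,
                                 self.bundle_radius_exponent)
        coeffs = friction_coefficients(bundle.helix, self.viscosity_pa_s,
                                       self.friction_variant)
        pm = propulsion_matrix(bundle, coeffs)
        bd = body_drag(body if body is not None else self.body,
                       self.viscosity_pa_s)
        return solve_swim(pm, bd, self.motor, self.viscosity_pa_s)


def velocity_vs_flagella(
    config: ModelConfig = ModelConfig(),
    n_range: Sequence[int] | Iterable[int] = range(1, 11),
) -> pd.DataFrame:
    """Model sweep over flagellar number.

    Returns a DataFrame with one row per N: swimming speed, bundle and body
    rotation rates, bundle torque and torque per motor.  Under the default
    couplings the speed rises with N and plateaus once the body drag becomes
    negligible against the flagellar drag.
    """
    rows = []
    for n in n_range:
        sol = config.solve_for_n(int(n))
        rows.append({
            "N": int(n),
            "v_um_s": sol.v_um_s,
            "omega_flag_hz": sol.omega_flag_hz,
            "omega_body_hz": sol.omega_body_hz,
            "bundle_torque_pN_um": sol.bundle_torque_pn_um,
            "torque_per_motor_pN_um": torque_per_motor(sol, int(n)),
        })
    return pd.DataFrame(rows)
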