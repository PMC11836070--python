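"""Shared fixtures.

The two criterion-scale synthetic movies (mixed population and pure
diffusion, 256 x 256 x 1000 frames) are expensive to build and analyse, so
they are generated once per session and shared between the DDM unit tests
and the acceptance suite.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import gamma

import microswim as ms


def solve_closed_form(pm, A0_eff, C0_eff, motor_hz):
    """Independent scalar elimination of the three-equation force/torque
    balance; the oracle against which the dense solver is checked."""
    w_m = 2 * math.pi * motor_hz
    omega = C0_eff * w_m / (pm.C + C0_eff - pm.B ** 2 / (pm.A + A0_eff))
    v = pm.B * omega / (pm.A + A0_eff)
    return v, omega, w_m - omega


def schulz_isf_quadrature(q, tau, v_bar, Z):
    """Independent oracle: direct adaptive quadrature of the Schulz speed
    average of sinc(q v tau).  The Schulz distribution is
    Gamma(Z+1, v_bar/(Z+1)); truncating at mean + 40 sd leaves negligible
    tail mass while keeping the oscillatory integrand on a finite interval.
    """
    dist = gamma(Z + 1, scale=v_bar / (Z + 1))
    v_max = v_bar + 40.0 * v_bar / np.sqrt(Z + 1)

    def integrand(v):
        x = q * v * tau
        return dist.pdf(v) * (np.sinc(x / np.pi))

    val, _ = quad(integrand, 0, v_max, limit=2000,
                  epsabs=1e-13, epsrel=1e-11)
    return val

MIXED_TRUTH = dict(alpha=0.5, v_bar_um_s=20.0, Z=3.0, D_um2_s=0.3)
MOVIE_SEED = 2024


@pytest.fixture(scope="session")
def mixed_movie():
    """Default mixed swimmer/diffuser movie with its ground truth."""
    stack, truth = ms.generate_motility_movie(
        ms.MovieParams(**MIXED_TRUTH), seed=MOVIE_SEED)
    return stack, truth


@pytest.fixture(scope="session")
def mixed_estimate(mixed_movie):
    stack, truth = mixed_movie
    sf = ms.image_structure_function(stack)
    return ms.fit_structure_function(sf), truth


@pytest.fixture(scope="session")
def diffusion_movie():
    """Pure-diffusion movie (no swimmers) with its ground truth."""
    stack, truth = ms.generate_motility_movie(
        ms.MovieParams(alpha=0.0, D_um2_s=0.3), seed=MOVIE_SEED + 1)
    return stack, truth


@pytest.fixture(scope="session")
def diffusion_estimate(diffusion_movie):
    stack, truth = diffusion_movie
    sf = ms.image_structure_function(stack)
    return ms.fit_structure_function(sf), truth


@pytest.fixture(scope="session")
def small_movie():
    """Cheap movie for structural/determinism tests."""
    params = ms.MovieParams(n_particles=80, n_frames=120, size_px=128)
    return ms.generate_motility_movie(params, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
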