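"""Seeded synthetic-data generators with attached ground truth.

Every generator is a pure function of (params, seed) and returns both the
dataset and a :class:`SyntheticGroundTruth` carrying the full parameter set
(and, where useful for oracle tests, the underlying trajectories), so every
analysis stage can be exercised end-to-end against known truth:

* :func:`generate_motility_movie` -- 2-D movie of a mixed population of
  ballistic swimmers (Schulz-distributed speeds, fixed random headings,
  Brownian jitter) and pure Brownian diffusers, rendered as Gaussian spots
  with periodic boundaries and additive Gaussian camera noise.
* :func:`generate_flicker_trace` -- two-tone intensity trace (body and
  flagellar rotation peaks) with Gaussian noise.
* :func:`generate_flagellation_table` -- per-cell flagellar counts (linear
  in expression) and filament lengths (saturating in expression) with
  configurable noise.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ddm import ImageStack
from .flicker import IntensityTrace

__all__ = [
    "SyntheticGroundTruth",
    "MovieParams",
    "FlickerParams",
    "FlagellationTableParams",
    "generate_motility_movie",
    "generate_flicker_trace",
    "generate_flagellation_table",
]


@dataclass(frozen=True)
class SyntheticGroundTruth:
    """Generator provenance: name, seed and the complete parameter set.

    (generator, seed, params) regenerate the dataset bit-exactly; ``extras``
    holds derived arrays (trajectories, drawn speeds) used by oracle tests
    and is excluded from JSON serialization.
    """

    generator: str
    seed: int
    params: Mapping[str, object]
    warnings: tuple[str, ...] = ()
    extras: Mapping[str, object] = field(default_factory=dict, compare=False)

    def to_json(self) -> str:
        return json.dumps(
            {"generator": self.generator, "seed": self.seed,
             "params": dict(self.params), "warnings": list(self.warnings)},
            indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# Motility movies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MovieParams:
    """Mixed swimmer/diffuser movie parameters.

    Defaults emulate the desk-scale phase-contrast acquisition geometry:
    100 fps, 0.7 um/px, 256 x 256 px, 1000 frames.
    """

    n_particles: int = 300
    alpha: float = 0.5            # fraction of swimmers
    v_bar_um_s: float = 20.0      # mean Schulz speed
    Z: float = 3.0                # Schulz shape
    D_um2_s: float = 0.3          # diffusivity (all particles)
    psf_sigma_px: float = 2.0
    noise_sigma: float = 0.05
    amplitude: float = 1.0
    frame_rate_hz: float = 100.0
    n_frames: int = 1000
    size_px: int = 256
    pixel_size_um: float = 0.7
    tumble_rate_hz: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if min(self.n_particles, self.n_frames, self.size_px) < 1:
            raise ValueError("counts and sizes must be >= 1")
        if min(self.v_bar_um_s, self.Z, self.D_um2_s, self.psf_sigma_px,
               self.noise_sigma, self.frame_rate_hz, self.pixel_size_um,
               self.tumble_rate_hz) < 0:
            raise ValueError("parameters must be non-negative")
        if self.Z <= 0 or self.frame_rate_hz <= 0 or self.pixel_size_um <= 0:
            raise ValueError("Z, frame rate and pixel size must be > 0")


def _schulz_speeds(rng: np.random.Generator, n: int, v_bar: float,
                   Z: float) -> np.ndarray:
    # Schulz(v_bar, Z) is Gamma with shape Z+1 and scale v_bar/(Z+1)
    return rng.gamma(Z + 1.0, v_bar / (Z + 1.0), n)


def _render_frames(pos_px: np.ndarray, size: int, sigma: float,
                   amplitude: float) -> np.ndarray:
    """Render Gaussian spots at sub-pixel positions with periodic wrap.

    pos_px: (n_frames, n_particles, 2) in pixel units.
    """
    n_frames, n_part, _ = pos_px.shape
    half = max(int(math.ceil(4.0 * sigma)), 1)
    win = np.arange(-half, half + 1)
    frames = np.zeros((n_frames, size, size), np.float64)
    for t in range(n_frames):
        xy = pos_px[t]
        ix = np.floor(xy).astype(int)
        frac = xy - ix
        # (n_part, win) offsets of the patch grid from the true center
        dx = win[None, :] - frac[:, 0:1]
        dy = win[None, :] - frac[:, 1:2]
        gx = np.exp(-0.5 * (dx / sigma) ** 2)
        gy = np.exp(-0.5 * (dy / sigma) ** 2)
        patch = amplitude * gy[:, :, None] * gx[:, None, :]
        cols = np.mod(ix[:, 0:1] + win[None, :], size)
        rows = np.mod(ix[:, 1:2] + win[None, :], size)
        flat = (rows[:, :, None] * size + cols[:, None, :]).reshape(n_part, -1)
        np.add.at(frames[t].reshape(-1), flat.ravel(), patch.reshape(n_part, -1).ravel())
    return frames


def generate_motility_movie(
    params: MovieParams = MovieParams(),
    seed: int = 0,
) -> tuple[ImageStack, SyntheticGroundTruth]:
    """Synthesize a movie of swimmers and diffusers with known ground truth.

    Swimmers move ballistically along fixed random headings at per-particle
    Schulz speeds, all particles carry Brownian jitter with diffusivity D,
    and positions wrap periodically onto the imaged box at render time.
    Spots are Gaussian; Gaussian read noise is added per pixel.  The
    ground-truth ``extras`` store the exact unwrapped trajectories (um),
    drawn speeds, 3-D headings and the swimmer mask.
    """
    p = params
    rng = np.random.default_rng(seed)
    box_um = p.size_px * p.pixel_size_um
    dt = 1.0 / p.frame_rate_hz

    n_swim = int(round(p.alpha * p.n_particles))
    is_swimmer = np.zeros(p.n_particles, bool)
    is_swimmer[:n_swim] = True

    speeds = np.zeros(p.n_particles)
    speeds[is_swimmer] = _schulz_speeds(rng, n_swim, p.v_bar_um_s, p.Z)
    # 3-D isotropic headings rendered in-plane: swimmers live in 3-D but the
    # camera sees their projection, which is what makes the in-plane ISF the
    # sinc (speed-projected) form the Schulz swimmer model assumes
    headings = rng.standard_normal((p.n_particles, 3))
    headings /= np.linalg.norm(headings, axis=1, keepdims=True)

    pos = rng.uniform(0.0, box_um, (p.n_particles, 2))
    traj = np.empty((p.n_frames, p.n_particles, 2))
    sigma_step = math.sqrt(2.0 * p.D_um2_s * dt)
    for t in range(p.n_frames):
        traj[t] = pos
        if t == p.n_frames - 1:
            break
        if p.tumble_rate_hz > 0:
            tumbling = rng.random(p.n_particles) < p.tumble_rate_hz * dt
            new_headings = rng.standard_normal((p.n_particles, 3))
            new_headings /= np.linalg.norm(new_headings, axis=1, keepdims=True)
            headings = np.where((tumbling & is_swimmer)[:, None],
                                new_headings, headings)
        drift = speeds[:, None] * dt * headings[:, :2]
        jitter = sigma_step * rng.standard_normal((p.n_particles, 2))
        # positions accumulate unwrapped (so stored trajectories support
        # MSD oracles); rendering wraps them onto the periodic box
        pos = pos + drift + jitter

    frames = _render_frames(traj / p.pixel_size_um, p.size_px,
                            p.psf_sigma_px, p.amplitude)
    if p.noise_sigma > 0:
        frames += rng.normal(0.0, p.noise_sigma, frames.shape)

    warnings: list[str] = []
    if p.v_bar_um_s * dt > 2.0 * p.pixel_size_um:
        warnings.append(
            "mean displacement per frame exceeds 2 px: ballistic motion "
            "under-sampled at this frame rate/magnification")

    stack = ImageStack(frames=frames, frame_rate_hz=p.frame_rate_hz,
                       pixel_size_um=p.pixel_size_um)
    truth = SyntheticGroundTruth(
        generator="motility_movie",
        seed=seed,
        params=dataclasses.asdict(p),
        warnings=tuple(warnings),
        extras={"trajectories_um": traj, "speeds_um_s": speeds,
                "headings": headings, "is_swimmer": is_swimmer},
    )
    return stack, truth


# ---------------------------------------------------------------------------
# Flicker traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FlickerParams:
    """Two-tone rotation-flicker trace parameters (800 fps default)."""

    body_freq_hz: float = 22.0
    flag_freq_hz: float = 178.0
    body_amplitude: float = 1.0
    flag_amplitude: float = 0.5
    noise_sigma: float = 0.2
    sample_rate_hz: float = 800.0
    duration_s: float = 10.0

    def __post_init__(self) -> None:
        if min(self.body_freq_hz, self.flag_freq_hz) <= 0:
            raise ValueError("frequencies must be > 0")
        if self.duration_s <= 0 or self.sample_rate_hz <= 0:
            raise ValueError("duration and sample rate must be > 0")


def generate_flicker_trace(
    params: FlickerParams = FlickerParams(),
    seed: int = 0,
) -> tuple[IntensityTrace, SyntheticGroundTruth]:
    """Sum of two random-phase sinusoids plus Gaussian noise, seeded.

    Raises on Nyquist violation (either frequency >= sample_rate / 2).
    """
    p = params
    nyq = p.sample_rate_hz / 2.0
    if p.body_freq_hz >= nyq or p.flag_freq_hz >= nyq:
        raise ValueError("injected frequency at or above Nyquist "
                         f"({nyq} Hz)")
    rng = np.random.default_rng(seed)
    n = int(round(p.duration_s * p.sample_rate_hz))
    t = np.arange(n) / p.sample_rate_hz
    phi1, phi2 = rng.uniform(0.0, 2.0 * math.pi, 2)
    values = (p.body_amplitude * np.sin(2 * math.pi * p.body_freq_hz * t + phi1)
              + p.flag_amplitude * np.sin(2 * math.pi * p.flag_freq_hz * t + phi2))
    if p.noise_sigma > 0:
        values = values + rng.normal(0.0, p.noise_sigma, n)
    trace = IntensityTrace(values=values, sample_rate_hz=p.sample_rate_hz)
    truth = SyntheticGroundTruth(
        generator="flicker_trace", seed=seed, params=dataclasses.asdict(p))
    return trace, truth


# ---------------------------------------------------------------------------
# Flagellation tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FlagellationTableParams:
    """Expression -> (flagellar number, filament length) table parameters.

    Mean count is linear in expression (slope k, intercept); mean length is
    saturating, L_max * E / (K + E).  ``cells_per_level`` cells are drawn
    per expression level.
    """

    expression_grid: Sequence[float] = tuple(float(x) for x in
                                             (0, 10, 20, 30, 50, 75, 100))
    number_slope: float = 0.1
    number_intercept: float = 0.0
    length_max_um: float = 10.0
    length_halfsat: float = 25.0
    count_noise: float = 0.0
    length_noise_um: float = 0.0
    cells_per_level: int = 20

    def __post_init__(self) -> None:
        if any(e < 0 for e in self.expression_grid):
            raise ValueError("expression grid must be non-negative")
        if self.cells_per_level < 1:
            raise ValueError("cells_per_level must be >= 1")
        if min(self.count_noise, self.length_noise_um) < 0:
            raise ValueError("noise levels must be >= 0")


def generate_flagellation_table(
    params: FlagellationTableParams = FlagellationTableParams(),
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticGroundTruth]:
    """Per-cell flagellation table with known coupling parameters.

    With noise, counts are Gaussian-perturbed, rounded, non-negative
    integers and lengths Gaussian-perturbed non-negative reals; with zero
    noise both columns sit exactly on the coupling curves (counts left
    unrounded so the generating parameters are exactly recoverable).
    """
    p = params
    rng = np.random.default_rng(seed)
    rows = []
    for e in p.expression_grid:
        mean_n = max(0.0, p.number_slope * e + p.number_intercept)
        mean_len = p.length_max_um * e / (p.length_halfsat + e)
        for _ in range(p.cells_per_level):
            if p.count_noise > 0:
                n = max(0.0, round(mean_n + rng.normal(0.0, p.count_noise)))
            else:
                n = mean_n
            if p.length_noise_um > 0:
                length = max(0.0, mean_len
                             + rng.normal(0.0, p.length_noise_um))
            else:
                length = mean_len
            rows.append({"expression": float(e), "n_flagella": float(n),
                         "length": float(length)})
    table = pd.DataFrame(rows)
    truth = SyntheticGroundTruth(
        generator="flagellation_table", seed=seed,
        params={**dataclasses.asdict(p),
                "expression_grid": list(p.expression_grid)})
    return table, truth
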