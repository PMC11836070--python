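"""Differential dynamic microscopy (DDM) of mixed swimmer/diffuser populations.

DDM characterises population motility from an ordinary time-lapse movie
without tracking: Fourier-transforming frame differences yields the image
structure function

    D(q, tau) = < |FT[I(t+tau)] - FT[I(t)]|^2 >_t
              = A(q) * [1 - f(q, tau)] + B(q),

where f(q, tau) is the intermediate scattering function (ISF) of the imaged
particles, A(q) carries the optical signal and B(q) the camera noise floor.
For a population in which a fraction alpha swims ballistically with speeds
drawn from a Schulz distribution (mean v_bar, shape Z) while all cells also
diffuse with diffusivity D_diff,

    f(q, tau) = exp(-q^2 D_diff tau) * [(1 - alpha) + alpha * f_s(q, tau)],

with the closed-form swimmer ISF

    f_s = (Z+1)/(Z q v_bar tau) * sin(Z arctan(lam)) / (1 + lam^2)^(Z/2),
    lam = q v_bar tau / (Z + 1).

Per-q bounded least-squares fits of this model to D(q, tau), aggregated as
medians over a q window, give the swimming fraction, mean swimmer speed,
Schulz shape and diffusivity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "ImageStack",
    "StructureFunction",
    "MotilityEstimate",
    "default_lags",
    "image_structure_function",
    "schulz_swimmer_isf",
    "isf_model",
    "fit_structure_function",
    "population_velocity",
]

DEFAULT_Q_WINDOW = (0.4, 2.0)  # 1/um, at 0.7 um/px magnification


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class ImageStack:
    """Grayscale time-lapse movie: frames (time, y, x) at a fixed frame rate
    and pixel size."""

    frames: np.ndarray
    frame_rate_hz: float
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("need a (time, y, x) array with >= 2 frames")
        if not (self.frame_rate_hz > 0 and self.pixel_size_um > 0):
            raise ValueError("frame rate and pixel size must be > 0")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frame intensities must be finite")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])


@dataclass(frozen=True)
class StructureFunction:
    """Radially averaged image structure function D(q, tau).

    ``plateau`` is the long-lag limit 2*Var F(q) estimated from the full
    record's power spectrum; anchoring the fits to it suppresses the
    noise-induced bias of a freely fitted plateau.
    """

    q: np.ndarray          # 1/um, strictly increasing bin centers
    tau: np.ndarray        # s, strictly increasing lags
    D: np.ndarray          # (n_q, n_tau), >= 0
    frame_rate_hz: float
    pixel_size_um: float
    plateau: np.ndarray | None = None   # per-q, same normalization as D

    def __post_init__(self) -> None:
        if np.any(np.diff(self.q) <= 0) or np.any(np.diff(self.tau) <= 0):
            raise ValueError("q and tau must be strictly increasing")
        if self.D.shape != (len(self.q), len(self.tau)):
            raise ValueError("D must have shape (n_q, n_tau)")
        if np.any(self.D < 0):
            raise ValueError("structure function must be non-negative")
        if self.plateau is not None and len(self.plateau) != len(self.q):
            raise ValueError("plateau must align with the q grid")


@dataclass(frozen=True)
class MotilityEstimate:
    """Aggregated DDM motility parameters with the per-q fit table."""

    alpha: float
    v_bar_um_s: float
    Z: float
    D_um2_s: float
    q_window: tuple[float, float]
    per_q: pd.DataFrame = field(compare=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.v_bar_um_s < 0 or self.D_um2_s < 0:
            raise ValueError("speed and diffusivity must be >= 0")

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "v_bar_um_s": self.v_bar_um_s,
            "Z": self.Z,
            "D_um2_s": self.D_um2_s,
            "q_window": list(self.q_window),
            "per_q": self.per_q.to_dict(orient="list"),
        }


# ---------------------------------------------------------------------------
# Image structure function
# ---------------------------------------------------------------------------

def default_lags(n_frames: int, per_decade: int = 30) -> np.ndarray:
    """Log-spaced integer frame lags, ~30 per decade, up to n_frames // 2."""
    max_lag = max(n_frames // 2, 1)
    n_pts = max(int(per_decade * math.log10(max_lag)) + 1, 1)
    lags = np.unique(np.rint(np.logspace(0, math.log10(max_lag),
                                         n_pts)).astype(int))
    return lags[lags >= 1]


def image_structure_function(
    stack: ImageStack,
    lags: Sequence[int] | None = None,
    max_couples: int = 100,
    subtract_mean: bool = False,
    bin_width: int = 2,
) -> StructureFunction:
    """Compute D(q, tau) from a movie.

    For each integer frame lag, |FT[I(t+tau)] - FT[I(t)]|^2 is averaged over
    up to ``max_couples`` evenly spaced start frames and radially averaged
    into annular bins ``bin_width`` FFT pixels wide (zero frequency
    excluded).  Wider bins pool more Fourier modes, which suppresses the
    speckle noise that would otherwise bias the downstream nonlinear fits;
    the default of two pixels trades a negligible within-bin spread of decay
    rates for that noise reduction.  Deterministic: no random subsampling.
    """
    frames = stack.frames.astype(np.float64, copy=False)
    n_t, ny, nx = frames.shape
    if subtract_mean:
        frames = frames - frames.mean(axis=0, keepdims=True)
    if lags is None:
        lag_arr = default_lags(n_t)
    else:
        lag_arr = np.unique(np.asarray(lags, int))
    if lag_arr.min() < 1 or lag_arr.max() > n_t - 1:
        raise ValueError("lags must lie in [1, n_frames - 1]")

    # precompute half-plane FFTs once; real input => half plane suffices
    ft = np.fft.rfft2(frames)

    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    # annular bins on the half-plane grid; bin j spans radii
    # ((j-1)*w, j*w] with w = bin_width, centered at (j - 1/2)*w
    ky = np.fft.fftfreq(ny) * ny
    kx = np.arange(ft.shape[2])
    k_rad = np.sqrt(ky[:, None] ** 2 + kx[None, :] ** 2)
    k_idx = np.ceil(k_rad / bin_width).astype(int)
    # conjugate-symmetry weights: interior kx columns stand for two entries
    weights = np.full(ft.shape[1:], 2.0)
    weights[:, 0] = 1.0
    if nx % 2 == 0:
        weights[:, -1] = 1.0
    n_bins = (min(ny, nx) // 2) // bin_width
    flat_idx = k_idx.ravel()
    keep = (flat_idx >= 1) & (flat_idx <= n_bins)
    bin_counts = np.bincount(flat_idx[keep], weights=weights.ravel()[keep],
                             minlength=n_bins + 1)[1:]

    # mean spectral power per mode -> the long-lag plateau of D(q, tau):
    # D -> 2 <|F|^2>; using every frame makes this far more precise than
    # letting the fit infer the plateau from the few independent long-lag
    # couples.  (A static background inflates <|F|^2> without contributing
    # to D: remove it with subtract_mean before anchoring.)
    var_f = (ft.real ** 2 + ft.imag ** 2).mean(axis=0) / (nx * ny)
    plateau = 2.0 * np.bincount(
        flat_idx[keep], weights=(weights * var_f).ravel()[keep],
        minlength=n_bins + 1)[1:] / bin_counts

    D = np.empty((n_bins, len(lag_arr)))
    for j, lag in enumerate(lag_arr):
        starts = np.unique(np.linspace(0, n_t - 1 - lag,
                                       min(max_couples, n_t - lag),
                                       dtype=int))
        acc = np.zeros(ft.shape[1:])
        for t0 in starts:
            diff = ft[t0 + lag] - ft[t0]
            acc += diff.real ** 2 + diff.imag ** 2
        acc /= len(starts) * (nx * ny)     # normalized spectral power
        radial = np.bincount(flat_idx[keep],
                             weights=(weights * acc).ravel()[keep],
                             minlength=n_bins + 1)[1:]
        D[:, j] = radial / bin_counts

    q = 2.0 * math.pi * (np.arange(1, n_bins + 1) - 0.5) * bin_width \
        / (min(ny, nx) * stack.pixel_size_um)
    return StructureFunction(q=q, tau=lag_arr / stack.frame_rate_hz, D=D,
                             frame_rate_hz=stack.frame_rate_hz,
                             pixel_size_um=stack.pixel_size_um,
                             plateau=plateau)


# ---------------------------------------------------------------------------
# ISF models
# ---------------------------------------------------------------------------

def schulz_swimmer_isf(q, tau, v_bar, Z):
    """Closed-form ISF of ballistic swimmers with Schulz-distributed speeds.

    Equals the speed average of sinc(q v tau) over the Schulz (Gamma)
    distribution with mean ``v_bar`` and shape ``Z``:

        f_s = (Z+1)/(Z q v_bar tau) * sin(Z arctan lam) / (1+lam^2)^(Z/2),
        lam = q v_bar tau / (Z+1),

    with f_s -> 1 as q v_bar tau -> 0.  Broadcasts over array arguments.
    """
    q = np.asarray(q, float)
    tau = np.asarray(tau, float)
    if np.any(q < 0) or np.any(tau < 0):
        raise ValueError("q and tau must be >= 0")
    if not Z > 0:
        raise ValueError("Z must be > 0")
    if v_bar < 0:
        raise ValueError("v_bar must be >= 0")
    x = q * v_bar * tau
    lam = x / (Z + 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        full = (Z + 1.0) / (Z * x) * np.sin(Z * np.arctan(lam)) \
            / (1.0 + lam ** 2) ** (Z / 2.0)
    # second-order series around x = 0: 1 - x^2 (Z+2) / (6 (Z+1))
    series = 1.0 - x ** 2 * (Z + 2.0) / (6.0 * (Z + 1.0))
    return np.where(x < 1e-4, series, full)


def isf_model(q, tau, params: Mapping[str, float]):
    """Structure-function model A*(1 - f) + B for the mixed population.

    ``params`` carries A, B, alpha, v_bar, Z, D_diff.  The diffusive factor
    multiplies both sub-populations; alpha weights the swimmer ISF.
    """
    A, B = params["A"], params["B"]
    alpha, v_bar = params["alpha"], params["v_bar"]
    Z, D_diff = params["Z"], params["D_diff"]
    q = np.asarray(q, float)
    tau = np.asarray(tau, float)
    f = np.exp(-q ** 2 * D_diff * tau) * (
        (1.0 - alpha) + alpha * schulz_swimmer_isf(q, tau, v_bar, Z))
    return A * (1.0 - f) + B


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

_SWIMMER_SSE_GAIN = 0.8     # mixed model must cut the SSE below this ratio
# a swimmer component is only identifiable if the sinc oscillation is at
# least half-sampled within the lag range; slower "swimmers" are degenerate
# with diffusion and get folded back into the diffusion-only model
_MIN_SWIMMER_PHASE = math.pi


def _fit_single_q(q: float, tau: np.ndarray, d: np.ndarray,
                  bounds: Mapping[str, tuple[float, float]],
                  plateau: float | None = None) -> dict:
    """Bounded least squares of the mixed ISF model at one q.

    Deterministic initialization; nested model selection guards against the
    degenerate swimmer mode (alpha -> 1 with vanishing speed) that can mimic
    a slow relaxation: the swimmer component is only accepted when the mixed
    model clearly out-fits a diffusion-only model.  When the record variance
    is available the plateau A + B is anchored to it instead of being fitted,
    which removes the softest (and most bias-prone) direction of the problem.
    """
    b_lo = np.array([bounds[k][0] for k in _PARAM_ORDER])
    b_hi = np.array([bounds[k][1] for k in _PARAM_ORDER])
    anchored = plateau is not None and plateau > 0

    plat0 = float(plateau) if anchored \
        else float(np.mean(d[max(len(d) - max(len(d) // 4, 1), 0):]))
    b0 = float(min(d[0], d.min(), plat0))
    b0 = max(b0, 0.0)
    a0 = max(plat0 - b0, 1e-3 * max(plat0, 1.0))

    # diffusion-only prefit on a deterministic D grid
    d_grid = np.logspace(-4, math.log10(bounds["D_diff"][1]), 40)
    sse = [np.sum((a0 * (1 - np.exp(-q * q * dd * tau)) + b0 - d) ** 2)
           for dd in d_grid]
    d0 = float(d_grid[int(np.argmin(sse))])

    # first drop of the normalized signal locates q*v_bar*tau ~ 2
    norm = (d - b0) / a0
    above = np.nonzero(norm >= 0.5)[0]
    tau_half = tau[above[0]] if len(above) else tau[len(tau) // 2]
    v0 = min(max(2.0 / (q * tau_half), bounds["v_bar"][0] + 1e-9),
             bounds["v_bar"][1] - 1e-9)

    if anchored:
        # parameters (B, alpha, v_bar, Z, D) with A = plateau - B
        lo = np.array([0.0, b_lo[2], b_lo[3], b_lo[4], b_lo[5]])
        hi = np.array([plat0, b_hi[2], b_hi[3], b_hi[4], b_hi[5]])

        def diff_resid(x):
            b, dd = x
            return (plat0 - b) * (1 - np.exp(-q * q * dd * tau)) + b - d

        res_diff = least_squares(
            diff_resid, np.clip([b0, d0], [0.0, b_lo[5]], [plat0, b_hi[5]]),
            bounds=([0.0, b_lo[5]], [plat0, b_hi[5]]), max_nfev=2000)

        def resid(x):
            p = dict(zip(_PARAM_ORDER, np.concatenate(([plat0 - x[0]], x))))
            return isf_model(q, tau, p) - d

        x0 = np.clip(np.array([b0, 0.5, v0, 2.0, d0]),
                     lo + 1e-12, hi - 1e-12)
        res = least_squares(resid, x0, bounds=(lo, hi), max_nfev=2000)
        swimmer = (res.success
                   and res.cost < _SWIMMER_SSE_GAIN * float(res_diff.cost)
                   and q * res.x[2] * tau[-1] >= _MIN_SWIMMER_PHASE)
        if swimmer:
            out = dict(zip(_PARAM_ORDER,
                           np.concatenate(([plat0 - res.x[0]], res.x))))
            cost, success = float(res.cost), bool(res.success)
        else:
            b_fit, d_fit = res_diff.x
            out = {"A": float(plat0 - b_fit), "B": float(b_fit),
                   "alpha": 0.0, "v_bar": 0.0, "Z": float("nan"),
                   "D_diff": float(d_fit)}
            cost, success = float(res_diff.cost), bool(res_diff.success)
    else:
        def diff_resid(x):
            a, b, dd = x
            return a * (1.0 - np.exp(-q * q * dd * tau)) + b - d

        res_diff = least_squares(
            diff_resid, np.clip([a0, b0, d0],
                                [b_lo[0], b_lo[1], b_lo[5]],
                                [b_hi[0] if np.isfinite(b_hi[0]) else 1e30,
                                 b_hi[1] if np.isfinite(b_hi[1]) else 1e30,
                                 b_hi[5]]),
            bounds=([b_lo[0], b_lo[1], b_lo[5]],
                    [b_hi[0], b_hi[1], b_hi[5]]),
            max_nfev=2000)

        x0 = np.clip(np.array([a0, b0, 0.5, v0, 2.0, d0]),
                     b_lo + 1e-12, b_hi - 1e-12)

        def resid(x):
            p = dict(zip(_PARAM_ORDER, x))
            return isf_model(q, tau, p) - d

        res = least_squares(resid, x0, bounds=(b_lo, b_hi), max_nfev=2000)
        swimmer = (res.success
                   and res.cost < _SWIMMER_SSE_GAIN * float(res_diff.cost)
                   and q * res.x[3] * tau[-1] >= _MIN_SWIMMER_PHASE)
        if swimmer:
            out = dict(zip(_PARAM_ORDER, res.x))
            cost, success = float(res.cost), bool(res.success)
        else:
            a_fit, b_fit, d_fit = res_diff.x
            out = {"A": float(a_fit), "B": float(b_fit), "alpha": 0.0,
                   "v_bar": 0.0, "Z": float("nan"), "D_diff": float(d_fit)}
            cost, success = float(res_diff.cost), bool(res_diff.success)
    # a bin is resolved only if the fitted dynamics decorrelate within the
    # lag range; otherwise A and D are degenerate and the fit untrustworthy
    f_end = math.exp(-q * q * out["D_diff"] * tau[-1])
    if swimmer:
        f_end *= (1.0 - out["alpha"]) + out["alpha"] * float(
            schulz_swimmer_isf(q, tau[-1], out["v_bar"], out["Z"]))
    out.update(q=q, cost=cost, converged=success,
               swimmer_detected=bool(swimmer),
               resolved=bool(success and f_end < 0.5),
               z_at_bound=bool(swimmer and
                               (abs(out["Z"] - bounds["Z"][0]) < 1e-9
                                or abs(out["Z"] - bounds["Z"][1]) < 1e-9)))
    return out


_PARAM_ORDER = ("A", "B", "alpha", "v_bar", "Z", "D_diff")

_DEFAULT_BOUNDS = {
    "A": (0.0, np.inf),
    "B": (0.0, np.inf),
    "alpha": (0.0, 1.0),
    "v_bar": (0.0, 200.0),
    "Z": (0.5, 50.0),
    "D_diff": (1e-4, 20.0),
}


def fit_structure_function(
    sf: StructureFunction,
    q_window: tuple[float, float] = DEFAULT_Q_WINDOW,
    bounds: Mapping[str, tuple[float, float]] | None = None,
) -> MotilityEstimate:
    """Fit the mixed swimmer/diffuser model per q and aggregate.

    Each q bin inside ``q_window`` is fitted independently with a
    deterministic initialization; the reported alpha, v_bar, Z and D are
    medians over the converged fits in the window.  Raises if no q bin
    converges, carrying the per-q diagnostics in the message.
    """
    bounds = dict(_DEFAULT_BOUNDS, **(bounds or {}))
    lo, hi = q_window
    sel = np.nonzero((sf.q >= lo) & (sf.q <= hi))[0]
    if len(sel) == 0:
        raise ValueError("q window contains no structure-function bins")
    rows = [_fit_single_q(
        float(sf.q[i]), sf.tau, sf.D[i], bounds,
        plateau=None if sf.plateau is None else float(sf.plateau[i]))
        for i in sel]
    per_q = pd.DataFrame(rows)
    good = per_q[per_q["resolved"]]
    if len(good) < 3:           # fall back on merely-converged fits
        good = per_q[per_q["converged"]]
    # bins whose dynamic amplitude sits below the noise floor carry no
    # usable signal; drop them when enough informative bins remain
    signal = good[good["A"] >= good["B"]]
    if len(signal) >= 3:
        good = signal
    if good.empty:
        raise RuntimeError(
            "no q bin converged in the fit window; diagnostics: "
            + per_q.to_string(index=False))
    # swimmer speed/shape only mean anything where a swimmer component was
    # accepted; alpha and D aggregate over every trusted bin
    swim = good[good["swimmer_detected"]]
    return MotilityEstimate(
        alpha=float(good["alpha"].median()),
        v_bar_um_s=float(swim["v_bar"].median()) if len(swim) else 0.0,
        Z=float(swim["Z"].median()) if len(swim) else float("nan"),
        D_um2_s=float(good["D_diff"].median()),
        q_window=(float(lo), float(hi)),
        per_q=per_q,
    )


def population_velocity(est: MotilityEstimate) -> float:
    """Population-averaged velocity: swimming fraction times swimmer speed."""
    return est.alpha * est.v_bar_um_s
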