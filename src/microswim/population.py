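"""Population-level predictions: cell ensembles, expression couplings,
ensemble-averaged velocity curves and single-parameter calibration.

The single-cell swimming model (:mod:`microswim.rft`) is exercised over an
ensemble of modelled cells whose body size and wobble angle are drawn from
configurable distributions, mirroring the variability of real cultures.  The
link between flagellar gene expression and flagellation is empirical: the
mean flagellar number rises linearly with reporter activity while the mean
filament length rises and saturates; both couplings are fitted from data
tables and fed into the model.  A single multiplicative velocity scale is
the calibration degree of freedom against observed speed-vs-number curves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .rft import CellBody, ModelConfig, solve_swim, body_drag, \
    bundle_geometry, friction_coefficients, propulsion_matrix

__all__ = [
    "DistributionSpec",
    "EnsembleSpec",
    "CouplingModel",
    "PopulationPrediction",
    "sample_cells",
    "fit_couplings",
    "predict_population_curve",
    "population_average_velocity",
    "calibrate_scale",
]

_MAX_CONSECUTIVE_REJECTIONS = 10_000


# ---------------------------------------------------------------------------
# Ensembles of model cells
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistributionSpec:
    """Named scalar distribution.

    Supported names: ``lognormal`` (params mean, cv), ``normal`` (mean, sd),
    ``uniform`` (low, high), ``constant`` (value).
    """

    name: str
    params: Mapping[str, float]

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        p = self.params
        if self.name == "lognormal":
            mean, cv = float(p["mean"]), float(p["cv"])
            if cv == 0.0:
                return np.full(size, mean)
            sigma2 = math.log1p(cv * cv)
            mu = math.log(mean) - sigma2 / 2.0
            return rng.lognormal(mu, math.sqrt(sigma2), size)
        if self.name == "normal":
            return rng.normal(float(p["mean"]), float(p["sd"]), size)
        if self.name == "uniform":
            return rng.uniform(float(p["low"]), float(p["high"]), size)
        if self.name == "constant":
            return np.full(size, float(p["value"]))
        raise ValueError(f"unknown distribution {self.name!r}")

    @property
    def mean(self) -> float:
        p = self.params
        if self.name in ("lognormal", "normal"):
            return float(p["mean"])
        if self.name == "uniform":
            return 0.5 * (float(p["low"]) + float(p["high"]))
        return float(p["value"])


@dataclass(frozen=True)
class EnsembleSpec:
    """Distributions over cell body geometry and wobble angle.

    Defaults: body length lognormal(3.0 um, cv 0.15), width lognormal
    (0.9 um, cv 0.10), wobble angle uniform on [0, 40] degrees, 5000 cells.
    """

    n_cells: int = 5000
    body_length_dist: DistributionSpec = field(default_factory=lambda:
        DistributionSpec("lognormal", {"mean": 3.0, "cv": 0.15}))
    body_width_dist: DistributionSpec = field(default_factory=lambda:
        DistributionSpec("lognormal", {"mean": 0.9, "cv": 0.10}))
    wobble_dist_deg: DistributionSpec = field(default_factory=lambda:
        DistributionSpec("uniform", {"low": 0.0, "high": 40.0}))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")


def sample_cells(spec: EnsembleSpec) -> list[CellBody]:
    """Draw ``spec.n_cells`` cell bodies; deterministic given ``spec.seed``.

    Draws violating the body invariants (length >= width > 0, wobble in
    [0, 90) degrees) are rejected and redrawn; more than 10^4 consecutive
    rejections raise a distribution-misconfiguration error.
    """
    rng = np.random.default_rng(spec.seed)
    cells: list[CellBody] = []
    consecutive = 0
    while len(cells) < spec.n_cells:
        n_draw = spec.n_cells - len(cells)
        lengths = spec.body_length_dist.sample(rng, n_draw)
        widths = spec.body_width_dist.sample(rng, n_draw)
        thetas = np.deg2rad(spec.wobble_dist_deg.sample(rng, n_draw))
        ok = (widths > 0) & (lengths >= widths) & (thetas >= 0) \
            & (thetas < math.pi / 2)
        for L, w, th in zip(lengths[ok], widths[ok], thetas[ok]):
            cells.append(CellBody(float(L), float(w), float(th)))
        n_bad = int(n_draw - ok.sum())
        consecutive = consecutive + n_bad if ok.sum() == 0 else n_bad
        if consecutive > _MAX_CONSECUTIVE_REJECTIONS:
            raise ValueError(
                "distribution misconfiguration: more than "
                f"{_MAX_CONSECUTIVE_REJECTIONS} consecutive rejected draws")
    return cells


# ---------------------------------------------------------------------------
# Expression -> flagellation couplings
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CouplingModel:
    """Empirical couplings between reporter activity E and flagellation.

    Flagellar number: N(E) = max(0, k*E + intercept), approximately linear.
    Filament length: L(E) = L_max * E / (K + E), saturating at L_max; when a
    saturating fit is non-identifiable the length model degrades to linear
    (``length_model == "linear"`` with slope/intercept).
    """

    number_slope: float = 0.1
    number_intercept: float = 0.0
    length_max_um: float = 10.0
    length_halfsat: float = 25.0
    length_model: str = "saturating"
    length_linear_slope: float = 0.0
    length_linear_intercept: float = 0.0
    residuals: Mapping[str, float] = field(default_factory=dict, compare=False)

    def count_mean(self, expression: float | np.ndarray) -> np.ndarray:
        return np.maximum(0.0, self.number_slope * np.asarray(expression, float)
                          + self.number_intercept)

    def count_int(self, expression: float | np.ndarray) -> np.ndarray:
        """Integer flagellar number (rounded, floored at 0)."""
        return np.rint(self.count_mean(expression)).astype(int)

    def expression_for_count(self, n: float | np.ndarray) -> np.ndarray:
        if self.number_slope == 0:
            raise ValueError("zero number slope: coupling not invertible")
        return (np.asarray(n, float) - self.number_intercept) / self.number_slope

    def length_for_expression(self, expression: float | np.ndarray) -> np.ndarray:
        e = np.asarray(expression, float)
        if self.length_model == "linear":
            return np.maximum(0.0, self.length_linear_slope * e
                              + self.length_linear_intercept)
        return self.length_max_um * e / (self.length_halfsat + e)

    def length_for_count(self, n: float | np.ndarray) -> np.ndarray:
        """Mean filament length at the expression producing mean number n."""
        return self.length_for_expression(self.expression_for_count(n))


def _fit_saturating(e: np.ndarray, length: np.ndarray):
    def model(x, l_max, k):
        return l_max * x / (k + x)
    p0 = (max(1.2 * float(length.max()), 1e-6),
          max(float(np.median(e)), 1e-6))
    popt, _ = curve_fit(model, e, length, p0=p0, maxfev=20_000,
                        bounds=([1e-9, 1e-9], [np.inf, np.inf]))
    resid = length - model(e, *popt)
    return popt, float(np.sqrt(np.mean(resid ** 2)))


def fit_couplings(table: pd.DataFrame) -> CouplingModel:
    """Fit number and length couplings from a (expression, n_flagella,
    length) table.

    Number: ordinary least squares line.  Length: least-squares saturating
    curve L_max*E/(K+E); if the saturating fit is non-identifiable (no
    curvature, e.g. constant length or too-few distinct levels) the model
    falls back to a linear length fit and flags it.
    """
    required = {"expression", "n_flagella", "length"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    e = np.asarray(table["expression"], float)
    n = np.asarray(table["n_flagella"], float)
    length = np.asarray(table["length"], float)
    if len(np.unique(e)) < 3:
        raise ValueError("need >= 3 distinct expression levels")

    slope, intercept = np.polyfit(e, n, 1)
    n_rms = float(np.sqrt(np.mean((n - (slope * e + intercept)) ** 2)))

    lin_slope, lin_icpt = np.polyfit(e, length, 1)
    lin_rms = float(np.sqrt(np.mean((length - (lin_slope * e + lin_icpt)) ** 2)))
    try:
        (l_max, k_half), sat_rms = _fit_saturating(e, length)
        # a saturating fit that cannot beat the straight line (or needs an
        # absurd half-saturation far beyond the data) carries no curvature
        identifiable = sat_rms <= lin_rms + 1e-12 and \
            k_half < 100.0 * max(e.max(), 1e-9)
    except RuntimeError:
        identifiable = False
    if identifiable:
        return CouplingModel(
            number_slope=float(slope), number_intercept=float(intercept),
            length_max_um=float(l_max), length_halfsat=float(k_half),
            length_model="saturating",
            residuals={"number_rms": n_rms, "length_rms": sat_rms},
        )
    return CouplingModel(
        number_slope=float(slope), number_intercept=float(intercept),
        length_max_um=float(length.max()), length_halfsat=float("inf"),
        length_model="linear",
        length_linear_slope=float(lin_slope),
        length_linear_intercept=float(lin_icpt),
        residuals={"number_rms": n_rms, "length_rms": lin_rms},
    )


# ---------------------------------------------------------------------------
# Ensemble velocity curve and calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationPrediction:
    """Mean +/- sd swimming speed per flagellar number over the ensemble."""

    n_range: tuple[int, ...]
    mean_v_um_s: tuple[float, ...]
    sd_v_um_s: tuple[float, ...]
    calibration_scale: float = 1.0
    metadata: Mapping[str, object] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.sd_v_um_s):
            raise ValueError("standard deviations must be >= 0")
        if not self.calibration_scale > 0:
            raise ValueError("calibration scale must be > 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "N": self.n_range,
            "v_um_s": np.asarray(self.mean_v_um_s) * self.calibration_scale,
            "sd_um_s": np.asarray(self.sd_v_um_s) * self.calibration_scale,
        })


def predict_population_curve(
    spec: EnsembleSpec,
    coupling: CouplingModel | None = None,
    config: ModelConfig = ModelConfig(),
    n_range: Sequence[int] = range(1, 11),
) -> PopulationPrediction:
    """Ensemble-averaged speed vs flagellar number.

    For each N, the bundle geometry (thickness from N, length from the
    coupling) is solved against every sampled cell body; mean and standard
    deviation of the speed over the ensemble are reported.  Deterministic
    given ``spec.seed``.
    """
    cells = sample_cells(spec)
    if coupling is not None:
        length_rule = lambda n: float(coupling.length_for_count(n))  # noqa: E731
    else:
        length_rule = config.length_rule
    means, sds = [], []
    for n in n_range:
        bundle = bundle_geometry(int(n), config.helix, length_rule,
                                 config.bundle_radius_exponent)
        coeffs = friction_coefficients(bundle.helix, config.viscosity_pa_s,
                                       config.friction_variant)
        pm = propulsion_matrix(bundle, coeffs)
        v = np.empty(len(cells))
        for i, cell in enumerate(cells):
            bd = body_drag(cell, config.viscosity_pa_s)
            v[i] = solve_swim(pm, bd, config.motor,
                              config.viscosity_pa_s).v_um_s
        means.append(float(v.mean()))
        sds.append(float(v.std()))
    return PopulationPrediction(
        n_range=tuple(int(n) for n in n_range),
        mean_v_um_s=tuple(means),
        sd_v_um_s=tuple(sds),
        metadata={"n_cells": spec.n_cells, "seed": spec.seed,
                  "friction_variant": config.friction_variant},
    )


def population_average_velocity(fraction_motile: float,
                                mean_speed_motile: float) -> float:
    """Population-averaged velocity: swimming fraction times the mean speed
    of the motile cells."""
    if not 0.0 <= fraction_motile <= 1.0:
        raise ValueError("fraction_motile must lie in [0, 1]")
    if mean_speed_motile < 0:
        raise ValueError("mean speed must be >= 0")
    return fraction_motile * mean_speed_motile


def calibrate_scale(predicted: PopulationPrediction | Sequence[float],
                    observed: pd.DataFrame | Sequence[tuple[int, float]],
                    ) -> float:
    """Least-squares multiplicative velocity scale against observed (N, v).

    Closed form: s = sum(v_obs * v_pred) / sum(v_pred^2), the single adjusted
    parameter matching the model to data.
    """
    if isinstance(observed, pd.DataFrame):
        pairs = list(zip(observed["n_flagella"].astype(int),
                         observed["v_um_s"].astype(float)))
    else:
        pairs = [(int(n), float(v)) for n, v in observed]
    if not pairs:
        raise ValueError("need at least one observed (N, v) pair")
    if isinstance(predicted, PopulationPrediction):
        lookup = dict(zip(predicted.n_range, predicted.mean_v_um_s))
        try:
            v_pred = np.array([lookup[n] for n, _ in pairs])
        except KeyError as exc:
            raise ValueError(f"no prediction for N={exc.args[0]}") from exc
    else:
        v_pred = np.asarray(predicted, float)
        if len(v_pred) != len(pairs):
            raise ValueError("prediction/observation length mismatch")
    v_obs = np.array([v for _, v in pairs])
    denom = float(np.sum(v_pred ** 2))
    if denom == 0.0:
        raise ValueError("all-zero predictions: scale undefined")
    return float(np.sum(v_obs * v_pred) / denom)
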