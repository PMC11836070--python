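"""Flicker spectroscopy of rotating cells.

A swimming bacterium under dark-field illumination flickers as its
anisotropic body and flagellar bundle rotate, putting two spectral peaks in
the intensity time series of a cell: the body counter-rotation (tens of Hz)
and the flagellar rotation (one to a few hundred Hz).  The motor rotation
rate -- flagellum relative to body -- is the sum of the two.

This module estimates both frequencies from a trace by Welch-averaged,
linearly detrended periodograms with band-limited, prominence-thresholded
peak picking, and reports the motor frequency as the sum.  If either band
holds no prominent peak the result says so explicitly rather than guessing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal

__all__ = [
    "IntensityTrace",
    "RotationEstimate",
    "power_spectrum",
    "detect_rotation",
    "DEFAULT_BODY_BAND_HZ",
    "DEFAULT_FLAG_BAND_HZ",
]

DEFAULT_BODY_BAND_HZ = (5.0, 40.0)
DEFAULT_FLAG_BAND_HZ = (50.0, 350.0)
DEFAULT_SEGMENT_LENGTH = 1024
DEFAULT_PEAK_FACTOR = 5.0     # peak must exceed this multiple of band median


@dataclass
class IntensityTrace:
    """Intensity vs time sampled uniformly at ``sample_rate_hz``."""

    values: np.ndarray
    sample_rate_hz: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float).ravel()
        if self.values.size < 2:
            raise ValueError("trace needs at least two samples")
        if not self.sample_rate_hz > 0:
            raise ValueError("sample rate must be > 0")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("intensities must be finite")

    @property
    def duration_s(self) -> float:
        return self.values.size / self.sample_rate_hz


@dataclass(frozen=True)
class RotationEstimate:
    """Per-trace rotation readout.

    ``body_freq_hz`` / ``flagellar_freq_hz`` are None when no prominent peak
    exists in the corresponding band; ``motor_freq_hz`` is their sum and is
    None whenever either component is missing.
    """

    body_freq_hz: float | None
    flagellar_freq_hz: float | None
    motor_freq_hz: float | None
    body_peak_power: float | None
    flagellar_peak_power: float | None
    body_band_hz: tuple[float, float]
    flag_band_hz: tuple[float, float]
    frequency_resolution_hz: float

    def __post_init__(self) -> None:
        if self.body_freq_hz is not None and self.flagellar_freq_hz is not None:
            s = self.body_freq_hz + self.flagellar_freq_hz
            if self.motor_freq_hz is None or abs(self.motor_freq_hz - s) > 1e-9:
                raise ValueError("motor frequency must equal body + flagellar")
        elif self.motor_freq_hz is not None:
            raise ValueError("motor frequency undefined without both peaks")


def power_spectrum(
    trace: IntensityTrace,
    segment_length: int = DEFAULT_SEGMENT_LENGTH,
    overlap: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Welch-averaged power spectral density of a trace.

    Segments are linearly detrended and Hann-windowed; frequency resolution
    is sample_rate / segment_length.  Raises if the trace is shorter than a
    single segment.
    """
    if segment_length < 2:
        raise ValueError("segment length must be >= 2")
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must lie in [0, 1)")
    if trace.values.size < segment_length:
        raise ValueError(
            f"trace of {trace.values.size} samples is shorter than one "
            f"segment ({segment_length})")
    freqs, power = signal.welch(
        trace.values,
        fs=trace.sample_rate_hz,
        window="hann",
        nperseg=segment_length,
        noverlap=int(overlap * segment_length),
        detrend="linear",
    )
    return freqs, power


def _band_peak(freqs: np.ndarray, power: np.ndarray,
               band: tuple[float, float],
               peak_factor: float) -> tuple[float, float] | None:
    """Highest prominent in-band peak, or None.  Band edges are inclusive."""
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if not np.any(sel):
        return None
    p_band = power[sel]
    f_band = freqs[sel]
    threshold = peak_factor * float(np.median(p_band))
    # local maxima within the band; the band edges themselves count
    peaks, _ = signal.find_peaks(np.concatenate(([0.0], p_band, [0.0])))
    peaks -= 1
    if len(peaks) == 0:
        return None
    best = peaks[np.argmax(p_band[peaks])]
    if p_band[best] < threshold:
        return None
    return float(f_band[best]), float(p_band[best])


def detect_rotation(
    trace: IntensityTrace,
    body_band_hz: Sequence[float] = DEFAULT_BODY_BAND_HZ,
    flag_band_hz: Sequence[float] = DEFAULT_FLAG_BAND_HZ,
    segment_length: int = DEFAULT_SEGMENT_LENGTH,
    overlap: float = 0.5,
    peak_factor: float = DEFAULT_PEAK_FACTOR,
) -> RotationEstimate:
    """Estimate body and flagellar rotation frequencies from one trace.

    The highest peak exceeding ``peak_factor`` times the median in-band
    power is reported per band (closed intervals); the motor frequency is
    the sum of the two and is reported as missing when either band is empty.
    """
    body_band = (float(body_band_hz[0]), float(body_band_hz[1]))
    flag_band = (float(flag_band_hz[0]), float(flag_band_hz[1]))
    nyquist = trace.sample_rate_hz / 2.0
    for lo, hi in (body_band, flag_band):
        if not 0 <= lo < hi:
            raise ValueError("bands must satisfy 0 <= lo < hi")
        if hi > nyquist:
            raise ValueError(
                f"band edge {hi} Hz exceeds Nyquist ({nyquist} Hz)")
    if not (body_band[1] <= flag_band[0] or flag_band[1] <= body_band[0]):
        raise ValueError("body and flagellar bands must be disjoint")

    freqs, power = power_spectrum(trace, segment_length, overlap)
    body = _band_peak(freqs, power, body_band, peak_factor)
    flag = _band_peak(freqs, power, flag_band, peak_factor)
    body_f, body_p = body if body else (None, None)
    flag_f, flag_p = flag if flag else (None, None)
    motor = body_f + flag_f if (body_f is not None and flag_f is not None) \
        else None
    return RotationEstimate(
        body_freq_hz=body_f,
        flagellar_freq_hz=flag_f,
        motor_freq_hz=motor,
        body_peak_power=body_p,
        flagellar_peak_power=flag_p,
        body_band_hz=body_band,
        flag_band_hz=flag_band,
        frequency_resolution_hz=trace.sample_rate_hz / segment_length,
    )
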