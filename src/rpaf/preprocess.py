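"""Segment normalization and adaptive wavelet denoising.

The denoiser follows the classic universal-threshold recipe: decompose the
segment with db5 to a level set by the sampling rate and the lowest ECG
frequency of interest (0.5 Hz), estimate the noise scale from the finest
detail band with the MAD estimator, soft-threshold every detail band, zero
the deepest approximation band to remove baseline drift, and reconstruct.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil, log, log2, sqrt

import numpy as np

from rpaf.ecg import ECGSignal, ParameterError
from rpaf.wavelet import dwt_max_level, wavedec, waverec

__all__ = [
    "WaveletConfig",
    "ThresholdParams",
    "minmax_normalize",
    "decomposition_level",
    "noise_sigma",
    "universal_threshold",
    "soft_threshold",
    "denoise",
]


@dataclass
class WaveletConfig:
    """Denoiser settings.

    ``level=None`` derives the depth from ``fs`` and ``f_low`` via
    :func:`decomposition_level` (10 for 500 Hz / 0.5 Hz). ``remove_baseline``
    zeroes the deepest approximation band, whose passband at that depth lies
    below ``f_low`` and therefore carries the drift.
    """

    wavelet: str = "db5"
    level: int | None = None
    f_low: float = 0.5
    remove_baseline: bool = True
    threshold_scale: float = 1.0  # multiplies the universal threshold; 0 disables

    def __post_init__(self) -> None:
        if self.level is not None and self.level < 1:
            raise ParameterError("level must be >= 1")
        if not self.f_low > 0:
            raise ParameterError("f_low must be > 0")
        if self.threshold_scale < 0:
            raise ParameterError("threshold_scale must be >= 0")


@dataclass
class ThresholdParams:
    """Noise scale and threshold actually applied to a segment."""

    sigma: float
    threshold: float
    mode: str = "soft"

    def __post_init__(self) -> None:
        if self.sigma < 0 or self.threshold < 0:
            raise ParameterError("sigma and threshold must be >= 0")


def minmax_normalize(samples: np.ndarray) -> np.ndarray:
    """Map samples affinely onto [0, 1]; a constant segment maps to zeros."""
    x = np.asarray(samples, dtype=np.float64)
    if x.size == 0:
        raise ParameterError("cannot normalize an empty array")
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def decomposition_level(fs: float, f_low: float, n: int | None = None) -> int:
    """Decomposition depth ceil(log2(fs / f_low)).

    After that many halvings the approximation band ends below ``f_low``.
    If ``n`` is given the result is clamped to the depth the length permits.
    """
    if not fs > f_low or not f_low > 0:
        raise ParameterError(f"need fs > f_low > 0, got fs={fs}, f_low={f_low}")
    level = ceil(log2(fs / f_low))
    if n is not None:
        level = min(level, dwt_max_level(n))
    return max(level, 1)


def noise_sigma(detail: np.ndarray) -> float:
    """MAD noise-scale estimate median(|d|) / 0.6745 from a detail band."""
    d = np.asarray(detail, dtype=np.float64)
    if d.size == 0:
        raise ParameterError("empty coefficient sequence")
    return float(np.median(np.abs(d)) / 0.6745)


def universal_threshold(sigma: float, n: int) -> float:
    """Donoho's universal threshold T = sigma * sqrt(2 ln n)."""
    if sigma < 0:
        raise ParameterError("sigma must be >= 0")
    if n < 2:
        raise ParameterError("need n >= 2")
    return sigma * sqrt(2.0 * log(n))


def soft_threshold(w: np.ndarray | float, t: float) -> np.ndarray | float:
    """Shrink towards zero: sgn(w) * max(|w| - t, 0)."""
    if t < 0:
        raise ParameterError("threshold must be >= 0")
    w_arr = np.asarray(w, dtype=np.float64)
    out = np.sign(w_arr) * np.maximum(np.abs(w_arr) - t, 0.0)
    return float(out) if np.isscalar(w) or w_arr.ndim == 0 else out


def denoise(signal: ECGSignal, config: WaveletConfig | None = None) -> ECGSignal:
    """Wavelet-denoise one segment; returns a signal of identical length.

    The threshold is estimated per segment from the finest detail band and
    applied to every detail level. With ``threshold_scale=0`` and
    ``remove_baseline=False`` this is a pure decompose/reconstruct round
    trip, exact to float rounding.
    """
    config = config or WaveletConfig()
    x = signal.samples
    level = config.level
    if level is None:
        level = decomposition_level(signal.fs, config.f_low, n=x.size)
    elif level > dwt_max_level(x.size):
        raise ParameterError(
            f"signal of length {x.size} is too short for {level} levels"
        )
    coeffs = wavedec(x, level, config.wavelet)
    sigma = noise_sigma(coeffs.details[0])
    t = config.threshold_scale * universal_threshold(sigma, x.size)
    coeffs.details = [soft_threshold(d, t) for d in coeffs.details]
    if config.remove_baseline:
        # the drift band is [0, f_low); zero the approximation plus every
        # detail band lying entirely below f_low (band of level j is
        # [fs/2^(j+1), fs/2^j])
        coeffs.approx = np.zeros_like(coeffs.approx)
        for j in range(1, level + 1):
            if signal.fs / 2**j <= config.f_low:
                coeffs.details[j - 1] = np.zeros_like(coeffs.details[j - 1])
    out = signal.with_samples(waverec(coeffs))
    out.meta = {**signal.meta, "threshold": ThresholdParams(sigma=sigma, threshold=t)}
    return out
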