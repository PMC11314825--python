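"""Orthonormal discrete wavelet transform (Daubechies family).

A minimal Mallat cascade sufficient for wavelet denoising of ECG segments.
Filters are derived numerically from the Daubechies defining polynomial by
spectral factorisation, so no coefficient tables are hard-coded. Boundaries
use periodized extension: for every even input length the single-level
analysis map is an orthogonal matrix, hence reconstruction is exact to
machine precision. Odd-length inputs are padded by replicating the last
sample; the pad is tracked per level and removed on reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from math import comb, sqrt

import numpy as np

__all__ = [
    "daubechies_filter",
    "quadrature_mirror",
    "dwt_max_level",
    "wavedec",
    "waverec",
    "WaveletCoeffs",
]


@lru_cache(maxsize=None)
def daubechies_filter(p: int) -> np.ndarray:
    """Return the length-2p orthonormal Daubechies scaling filter.

    Built by spectral factorisation: the half-band polynomial
    ``P(y) = sum_k C(p-1+k, k) y^k`` is rooted, each root ``y`` is mapped to
    the pair ``z, 1/z`` solving ``z^2 - (2 - 4y) z + 1 = 0``, and the
    minimum-phase factor (all ``|z| < 1``) is kept together with the ``p``
    zeros at ``z = -1`` that give ``p`` vanishing moments. Normalised so the
    coefficients sum to sqrt(2).
    """
    if p < 1:
        raise ValueError("order must be >= 1")
    if p == 1:  # Haar
        return np.array([1.0, 1.0]) / sqrt(2.0)
    # roots of P(y), highest degree first for np.roots
    pc = np.array([comb(p - 1 + k, k) for k in range(p - 1, -1, -1)], dtype=float)
    z_roots = []
    for y in np.roots(pc):
        # z^2 - (2 - 4y) z + 1 = 0; roots multiply to 1, keep |z| < 1
        b = 2.0 - 4.0 * y
        disc = np.sqrt(b * b - 4.0 + 0j)
        for z in ((b + disc) / 2.0, (b - disc) / 2.0):
            if abs(z) < 1.0:
                z_roots.append(z)
    # p zeros at z = -1 plus the p-1 minimum-phase roots
    poly = np.polynomial.polynomial.polyfromroots([-1.0] * p + z_roots)
    h = np.real(poly[::-1])
    h = h / h.sum() * sqrt(2.0)
    return h[::-1].copy()  # ascending-index convention


def quadrature_mirror(h: np.ndarray) -> np.ndarray:
    """Wavelet (high-pass) filter from the scaling filter: g[k] = (-1)^k h[L-1-k]."""
    L = len(h)
    signs = np.where(np.arange(L) % 2 == 0, 1.0, -1.0)
    return signs * h[::-1]


_FAMILY_ORDERS = {f"db{p}": p for p in range(1, 21)}
_FAMILY_ORDERS["haar"] = 1


def _filters(wavelet: str) -> tuple[np.ndarray, np.ndarray]:
    try:
        p = _FAMILY_ORDERS[wavelet.lower()]
    except KeyError:
        raise ValueError(f"unsupported wavelet {wavelet!r}; use haar or db1..db20") from None
    h = daubechies_filter(p)
    return h, quadrature_mirror(h)


def dwt_max_level(n: int) -> int:
    """Deepest usable decomposition level for a length-n signal."""
    if n < 2:
        return 0
    return int(np.floor(np.log2(n)))


def _dwt_level(x: np.ndarray, h: np.ndarray, g: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """One periodized analysis step; returns (approx, detail, original length)."""
    n0 = x.size
    if n0 % 2:
        x = np.concatenate([x, x[-1:]])
    n = x.size
    L = h.size
    idx = (2 * np.arange(n // 2)[:, None] + np.arange(L)) % n
    window = x[idx]
    return window @ h, window @ g, n0


def _idwt_level(a: np.ndarray, d: np.ndarray, h: np.ndarray, g: np.ndarray, n_out: int) -> np.ndarray:
    """Inverse of :func:`_dwt_level` (transpose of the orthogonal map)."""
    n = 2 * a.size
    L = h.size
    idx = (2 * np.arange(a.size)[:, None] + np.arange(L)) % n
    x = np.zeros(n)
    np.add.at(x, idx, a[:, None] * h + d[:, None] * g)
    return x[:n_out]


@dataclass
class WaveletCoeffs:
    """Multi-level DWT coefficients.

    ``approx`` is the deepest approximation band; ``details[j]`` holds the
    detail band of level ``j+1`` (``details[0]`` is the finest scale).
    ``lengths[j]`` is the input length that entered level ``j+1``, needed to
    undo odd-length padding on reconstruction.
    """

    approx: np.ndarray
    details: list[np.ndarray]
    lengths: list[int]
    wavelet: str

    @property
    def level(self) -> int:
        return len(self.details)


def wavedec(x: np.ndarray, level: int, wavelet: str = "db5") -> WaveletCoeffs:
    """Multi-level periodized DWT."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("input must be one-dimensional")
    if level < 1:
        raise ValueError("level must be >= 1")
    if level > dwt_max_level(x.size):
        raise ValueError(
            f"signal of length {x.size} supports at most {dwt_max_level(x.size)} levels"
        )
    h, g = _filters(wavelet)
    details: list[np.ndarray] = []
    lengths: list[int] = []
    a = x
    for _ in range(level):
        a, d, n0 = _dwt_level(a, h, g)
        details.append(d)
        lengths.append(n0)
    return WaveletCoeffs(approx=a, details=details, lengths=lengths, wavelet=wavelet)


def waverec(coeffs: WaveletCoeffs) -> np.ndarray:
    """Exact inverse of :func:`wavedec` (up to float rounding)."""
    h, g = _filters(coeffs.wavelet)
    a = coeffs.approx
    for d, n0 in zip(reversed(coeffs.details), reversed(coeffs.lengths)):
        a = _idwt_level(a, d, h, g, n0)
    return a
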