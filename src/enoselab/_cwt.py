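"""Continuous wavelet transform with Daubechies mother wavelets.

Self-contained: Daubechies scaling filters are built by spectral
factorization, the wavelet function by the cascade algorithm, and the CWT by
the standard integrated-wavelet convolution with symmetric signal extension.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.special import comb

__all__ = ["daubechies_filter", "wavelet_function", "cwt", "parse_wavelet_name"]


def parse_wavelet_name(name: str) -> int:
    """``"dbN"`` -> N; anything else is a configuration error."""
    if name.startswith("db"):
        try:
            order = int(name[2:])
        except ValueError:
            order = 0
        if order >= 1:
            return order
    raise ValueError(f"unknown wavelet {name!r}; expected 'dbN' with N >= 1")


@lru_cache(maxsize=None)
def daubechies_filter(order: int) -> np.ndarray:
    """Orthonormal Daubechies low-pass (scaling) filter of length ``2*order``.

    Built by spectral factorization of the halfband polynomial: the roots of
    ``P(y) = sum_k C(order-1+k, k) y^k`` are mapped to z-plane root pairs and
    the minimum-phase root of each pair is kept.  Coefficients sum to
    ``sqrt(2)``.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    if order == 1:
        return np.array([1.0, 1.0]) / np.sqrt(2.0)
    # polynomial in y, highest degree first for np.roots
    p = [comb(order - 1 + k, k, exact=True) for k in range(order)]
    yroots = np.roots(p[::-1])
    poly = np.poly1d([1.0])
    for _ in range(order):
        poly = poly * np.poly1d([1.0, 1.0])  # (z + 1)^order
    for y in yroots:
        # y = (2 - z - 1/z)/4  =>  z^2 + (4y - 2) z + 1 = 0
        zr = np.roots([1.0, 4.0 * y - 2.0, 1.0])
        z = zr[np.argmin(np.abs(zr))]  # keep the root inside the unit circle
        poly = poly * np.poly1d([1.0, -z])
    h = np.real(poly.coeffs)
    return h * np.sqrt(2.0) / h.sum()


@lru_cache(maxsize=None)
def wavelet_function(order: int, precision: int = 10) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sampled scaling/wavelet functions ``(phi, psi, x)`` by cascade.

    ``x`` covers the support ``[0, 2*order - 1]`` with ``2**precision``
    samples per unit; phi is normalized to unit integral (which also gives
    psi unit L2 norm for orthonormal filters).
    """
    h = daubechies_filter(order)
    g = h[::-1].copy()
    g[1::2] *= -1.0  # quadrature mirror high-pass

    def refine(first: np.ndarray) -> np.ndarray:
        data = first.copy()
        for _ in range(precision - 1):
            up = np.zeros(2 * data.size - 1)
            up[::2] = data
            data = np.convolve(up, h)
        return data

    raw_phi = refine(h)
    raw_psi = refine(g)
    n = raw_phi.size
    x = np.linspace(0.0, 2.0 * order - 1.0, n)
    dx = x[1] - x[0]
    scale = 1.0 / (raw_phi.sum() * dx)
    return raw_phi * scale, raw_psi * scale, x


def cwt(
    signal: np.ndarray,
    scales: np.ndarray,
    order: int = 4,
    precision: int = 10,
) -> np.ndarray:
    """CWT coefficients, shape ``(len(scales), len(signal))``.

    Coefficient at scale ``a`` and position ``b`` approximates
    ``a**-0.5 * integral f(t) psi((t - b)/a) dt`` via the cumulative wavelet
    (convolve with the integrated wavelet, then differentiate).  The signal
    is extended symmetrically at both ends before convolution.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1:
        raise ValueError("signal must be 1-D")
    scales = np.atleast_1d(np.asarray(scales, dtype=float))
    if np.any(scales <= 0):
        raise ValueError("scales must be positive")
    _, psi, x = wavelet_function(order, precision)
    dx = x[1] - x[0]
    int_psi = np.cumsum(psi) * dx
    n = signal.size
    out = np.empty((scales.size, n))
    for i, a in enumerate(scales):
        idx = np.arange(int(a * (x[-1] - x[0])) + 1) / (a * dx)
        idx = idx.astype(np.intp)
        idx = idx[idx < int_psi.size]
        kern = int_psi[idx][::-1]
        pad = kern.size
        ext = np.pad(signal, pad, mode="symmetric")
        conv = np.convolve(ext, kern)
        coef = -np.sqrt(a) * np.diff(conv)
        start = (coef.size - n) // 2
        out[i] = coef[start : start + n]
    return out
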