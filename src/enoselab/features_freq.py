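"""Frequency-domain indices: CWT scalogram power summarized into scale
packages x temperature windows x layers.

With the default 160-degree relative span, 10-degree windows (letters A..P),
6 packages of 5 integer scales and 3 layers, the scheme yields 16 x 6 x 3 =
288 named indices ``W{letter}{package}_S{layer}``.
"""

from __future__ import annotations

import re
import string
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from . import _cwt
from .preprocess import RepresentativeCurve

__all__ = [
    "Scalogram",
    "cwt_curve",
    "package_power",
    "extract_freq_features",
    "render_wavelet_name",
    "parse_wavelet_index",
    "all_wavelet_names",
    "freq_index_support",
]

WINDOW_WIDTH_C = 10.0
SCALES_PER_PACKAGE = 5
DEFAULT_MAX_SCALE = 30
DEFAULT_WAVELET = "db4"

_LETTERS = string.ascii_uppercase


@dataclass
class Scalogram:
    layer: int
    scales: np.ndarray
    grid: np.ndarray
    coefficients: np.ndarray

    def __post_init__(self) -> None:
        self.scales = np.asarray(self.scales)
        self.grid = np.asarray(self.grid, dtype=float)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (self.scales.size, self.grid.size):
            raise ValueError(
                f"coefficient matrix {self.coefficients.shape} does not match "
                f"(scales, grid) = ({self.scales.size}, {self.grid.size})"
            )


def cwt_curve(
    curve: RepresentativeCurve,
    wavelet: str = DEFAULT_WAVELET,
    max_scale: int = DEFAULT_MAX_SCALE,
) -> Scalogram:
    """Continuous wavelet transform at integer scales ``1..max_scale``."""
    if max_scale < 1:
        raise ValueError("max_scale must be >= 1")
    order = _cwt.parse_wavelet_name(wavelet)
    scales = np.arange(1, max_scale + 1)
    coef = _cwt.cwt(curve.values, scales, order=order)
    return Scalogram(layer=curve.layer, scales=scales, grid=curve.grid, coefficients=coef)


def render_wavelet_name(letter: str, package: int, layer: int) -> str:
    return f"W{letter}{package}_S{layer}"


def parse_wavelet_index(name: str) -> tuple[str, int, int]:
    """Inverse of :func:`render_wavelet_name`; raises on malformed names."""
    m = re.match(r"^W([A-Z])(\d+)_S(\d+)$", name)
    if m is None:
        raise ValueError(f"wavelet index name {name!r} does not parse")
    return m.group(1), int(m.group(2)), int(m.group(3))


def all_wavelet_names(n_windows: int = 16, n_packages: int = 6, layers: int = 3) -> list[str]:
    if n_windows > len(_LETTERS):
        raise ValueError("more temperature windows than window letters")
    return [
        render_wavelet_name(_LETTERS[w], p, layer)
        for layer in range(1, layers + 1)
        for w in range(n_windows)
        for p in range(1, n_packages + 1)
    ]


def package_power(
    scalogram: Scalogram,
    window_width: float = WINDOW_WIDTH_C,
    scales_per_package: int = SCALES_PER_PACKAGE,
    power: str = "square",
) -> dict[str, float]:
    """Summed coefficient power per (scale package, temperature window) block.

    Package ``p`` covers integer scales ``5(p-1)+1 .. 5p``; window ``k``
    covers relative degrees ``[10(k-1), 10k)`` (half-open, letter A at the
    low-temperature end).  ``power`` is ``"square"`` (sum of squared
    coefficients) or ``"abs"`` (sum of absolute values).
    """
    if power not in ("square", "abs"):
        raise ValueError("power: must be 'square' or 'abs'")
    n_scales = scalogram.scales.size
    if n_scales % scales_per_package:
        raise ValueError(
            f"{n_scales} scales do not split into packages of {scales_per_package}"
        )
    n_packages = n_scales // scales_per_package
    rel = scalogram.grid - scalogram.grid[0]
    span = rel[-1]
    n_windows = int(np.floor(span / window_width + 1e-9))
    if n_windows < 1:
        raise ValueError(f"span {span:g} shorter than one {window_width:g}-degree window")
    if n_windows > len(_LETTERS):
        raise ValueError("more temperature windows than window letters")
    mat = scalogram.coefficients**2 if power == "square" else np.abs(scalogram.coefficients)
    out: dict[str, float] = {}
    for k in range(n_windows):
        cols = (rel >= k * window_width) & (rel < (k + 1) * window_width)
        for p in range(1, n_packages + 1):
            rows = slice((p - 1) * scales_per_package, p * scales_per_package)
            name = render_wavelet_name(_LETTERS[k], p, scalogram.layer)
            out[name] = float(mat[rows][:, cols].sum())
    return out


def extract_freq_features(
    curves: Iterable[RepresentativeCurve],
    wavelet: str = DEFAULT_WAVELET,
    max_scale: int = DEFAULT_MAX_SCALE,
    window_width: float = WINDOW_WIDTH_C,
    scales_per_package: int = SCALES_PER_PACKAGE,
    power: str = "square",
) -> pd.DataFrame:
    """Feature table of wavelet power indices, one row per subject."""
    by_subject: dict[str, list[RepresentativeCurve]] = {}
    for c in curves:
        by_subject.setdefault(c.subject_id, []).append(c)
    rows = []
    for sid, subject_curves in by_subject.items():
        row: dict[str, object] = {
            "subject_id": sid,
            "group": subject_curves[0].group,
        }
        for c in sorted(subject_curves, key=lambda c: c.layer):
            scal = cwt_curve(c, wavelet=wavelet, max_scale=max_scale)
            row.update(
                package_power(
                    scal,
                    window_width=window_width,
                    scales_per_package=scales_per_package,
                    power=power,
                )
            )
        rows.append(row)
    df = pd.DataFrame(rows)
    feature_cols = [c for c in df.columns if c not in ("subject_id", "group")]
    if df[feature_cols].isna().any().any():
        raise ValueError("missing values in extracted frequency features")
    return df


def freq_index_support(name: str, window_width: float = WINDOW_WIDTH_C) -> tuple[int, tuple[float, float]]:
    """Layer and relative-degree window covered by a wavelet index."""
    letter, _, layer = parse_wavelet_index(name)
    k = _LETTERS.index(letter)
    return layer, (k * window_width, (k + 1) * window_width)
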