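"""Time-domain curve indices: total areas, 10/40-degree subareas, and
windowed steepest slopes with their temperatures.

Index naming grammar (layer L, window ordinal k, window points p):

* ``AS{L}`` — trapezoidal area under the full curve
* ``A{w}S{L}_{k}`` — area over the k-th consecutive ``w``-degree window
  (half-open in relative degrees, k starts at 1 at the low-temperature end)
* ``Max_slope_{p}_S{L}`` / ``Tmax_slope_{p}_S{L}`` — signed maximum
  least-squares slope over any contiguous window of ``p`` grid points, and
  the center temperature of the (first) maximizing window
"""

from __future__ import annotations

import re
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .preprocess import RepresentativeCurve

__all__ = [
    "total_area",
    "subareas",
    "steepest_slope",
    "extract_time_features",
    "parse_time_index",
    "time_index_support",
    "SUBAREA_WIDTHS",
    "SLOPE_POINTS",
]

SUBAREA_WIDTHS = (10.0, 40.0)
SLOPE_POINTS = (3, 5)

_NAME_RE = re.compile(
    r"^(?:"
    r"AS(?P<total_layer>\d+)"
    r"|A(?P<width>\d+)S(?P<area_layer>\d+)_(?P<window>\d+)"
    r"|Max_slope_(?P<mp>\d+)_S(?P<mlayer>\d+)"
    r"|Tmax_slope_(?P<tp>\d+)_S(?P<tlayer>\d+)"
    r")$"
)


def total_area(curve: RepresentativeCurve) -> float:
    """Trapezoidal integral of conductance over the full temperature span."""
    if curve.grid.size < 2:
        raise ValueError("total_area needs at least 2 grid points")
    return float(np.trapezoid(curve.values, curve.grid))


def _window_slices(curve: RepresentativeCurve, width: float) -> list[slice]:
    span = curve.span
    if width > span + 1e-9:
        raise ValueError(f"window width {width:g} exceeds curve span {span:g}")
    n_windows = round(span / width)
    if not np.isclose(n_windows * width, span, rtol=0, atol=1e-9):
        raise ValueError(f"window width {width:g} does not divide span {span:g}")
    per = round(width / curve.step)
    if not np.isclose(per * curve.step, width, rtol=0, atol=1e-9):
        raise ValueError(f"window width {width:g} is not a multiple of grid step")
    return [slice(k * per, k * per + per + 1) for k in range(n_windows)]


def subareas(curve: RepresentativeCurve, width: float) -> dict[str, float]:
    """Trapezoidal areas over consecutive ``width``-degree windows.

    Windows share boundary grid points, so the 10-degree subareas sum exactly
    to the total area and each 40-degree subarea to its four 10-degree parts.
    """
    out = {}
    for k, sl in enumerate(_window_slices(curve, width), start=1):
        name = f"A{int(width)}S{curve.layer}_{k}"
        out[name] = float(np.trapezoid(curve.values[sl], curve.grid[sl]))
    return out


def steepest_slope(curve: RepresentativeCurve, points: int) -> tuple[float, float]:
    """Signed maximum least-squares slope over ``points``-sample windows.

    Returns ``(max_slope, t_center)`` where ``t_center`` is the center
    temperature of the first maximizing window (ties broken toward the
    low-temperature end).  The maximum is signed: on a strictly decreasing
    curve it is the least negative slope, not the largest magnitude.
    """
    n = curve.grid.size
    if points < 2:
        raise ValueError("points: need at least 2")
    if n < points:
        raise ValueError(f"curve has {n} points, window needs {points}")
    # equidistant grid: least-squares slope = correlation with centered ramp
    x = np.arange(points) - (points - 1) / 2.0
    denom = float(np.sum(x * x)) * curve.step
    slopes = np.correlate(curve.values, x, mode="valid") / denom
    i = int(np.argmax(slopes))
    t_center = float(curve.grid[i] + (points - 1) / 2.0 * curve.step)
    return float(slopes[i]), t_center


def time_feature_row(
    curves: Sequence[RepresentativeCurve],
    widths: Sequence[float] = SUBAREA_WIDTHS,
    slope_points: Sequence[int] = SLOPE_POINTS,
) -> dict[str, float]:
    """All time-domain indices of one subject (one curve per layer)."""
    row: dict[str, float] = {}
    for c in sorted(curves, key=lambda c: c.layer):
        row[f"AS{c.layer}"] = total_area(c)
    for w in widths:
        for c in sorted(curves, key=lambda c: c.layer):
            row.update(subareas(c, w))
    for p in slope_points:
        for c in sorted(curves, key=lambda c: c.layer):
            m, t = steepest_slope(c, p)
            row[f"Max_slope_{p}_S{c.layer}"] = m
            row[f"Tmax_slope_{p}_S{c.layer}"] = t
    return row


def extract_time_features(
    curves: Iterable[RepresentativeCurve],
    widths: Sequence[float] = SUBAREA_WIDTHS,
    slope_points: Sequence[int] = SLOPE_POINTS,
) -> pd.DataFrame:
    """Feature table: one row per subject, columns subject_id, group, indices."""
    by_subject: dict[str, list[RepresentativeCurve]] = {}
    for c in curves:
        by_subject.setdefault(c.subject_id, []).append(c)
    rows = []
    for sid, subject_curves in by_subject.items():
        row: dict[str, object] = {
            "subject_id": sid,
            "group": subject_curves[0].group,
        }
        row.update(time_feature_row(subject_curves, widths, slope_points))
        rows.append(row)
    df = pd.DataFrame(rows)
    feature_cols = [c for c in df.columns if c not in ("subject_id", "group")]
    if df[feature_cols].isna().any().any():
        raise ValueError("missing values in extracted time features")
    for name in feature_cols:
        parse_time_index(name)  # every column must obey the grammar
    return df


def parse_time_index(name: str) -> dict:
    """Parse an index name into its components; raise on grammar violation."""
    m = _NAME_RE.match(name)
    if m is None:
        raise ValueError(f"index name {name!r} does not parse")
    g = m.groupdict()
    if g["total_layer"] is not None:
        return {"kind": "total_area", "layer": int(g["total_layer"])}
    if g["area_layer"] is not None:
        return {
            "kind": "subarea",
            "width": float(g["width"]),
            "layer": int(g["area_layer"]),
            "window": int(g["window"]),
        }
    if g["mlayer"] is not None:
        return {"kind": "max_slope", "points": int(g["mp"]), "layer": int(g["mlayer"])}
    return {"kind": "tmax_slope", "points": int(g["tp"]), "layer": int(g["tlayer"])}


def time_index_support(name: str, span: float = 160.0) -> tuple[int, tuple[float, float]]:
    """Layer and relative-degree support window of a time-domain index.

    Whole-curve indices (totals, slopes) report the full span.
    """
    info = parse_time_index(name)
    if info["kind"] == "subarea":
        w, k = info["width"], info["window"]
        return info["layer"], ((k - 1) * w, k * w)
    return info["layer"], (0.0, span)
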