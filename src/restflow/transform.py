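"""Flow/no-flow log-ratios, time averaging and the 45-degree rotated
common/differential decomposition.

Each gene is placed in a 2D expression space: ``x`` is its time-averaged
log2 flow/no-flow ratio under continuous flow, ``y`` the same under
rest-inserted flow.  Genes responding identically to both regimens lie on
the diagonal ``y = x``.  Rotating the frame by 45 degrees yields ``x'``
(change common to both flow types, along the diagonal) and ``y'``
(differential change attributable to rest insertion, distance from the
diagonal, positive when rest up-regulates).
"""
from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = [
    "CONDITIONS",
    "ROTATION_SCALE",
    "flow_ratios",
    "time_average",
    "rotate",
    "rotate_inverse",
    "rotated_profile",
    "summarize_geometry",
]

#: Fixed condition order: no flow, rest-inserted flow, continuous flow, each
#: at time 0 (immediately post-flow) and time 1 (one hour post-flow).
CONDITIONS = ("NF0", "NF1", "RF0", "RF1", "CF0", "CF1")

#: Unitary rotation normalisation (1/sqrt(2)); with this choice the rotation
#: is an isometry (x'^2 + y'^2 == x^2 + y^2).  Configurable because the
#: coordinates only need to *scale* with distance along/from the diagonal.
ROTATION_SCALE = 1.0 / math.sqrt(2.0)


def flow_ratios(log2_expr: pd.DataFrame) -> pd.DataFrame:
    """Per-time-point log2 flow/no-flow ratios from six-condition expression.

    Returns a frame with columns ``x0, x1`` (continuous flow over no flow at
    each time point) and ``y0, y1`` (rest-inserted flow over no flow).
    Input values must already be log2 intensities, so ratios are plain
    column differences.
    """
    missing = [c for c in CONDITIONS if c not in log2_expr.columns]
    if missing:
        raise ValueError(f"missing condition columns: {missing}")
    out = pd.DataFrame(index=log2_expr.index)
    out["x0"] = log2_expr["CF0"] - log2_expr["NF0"]
    out["x1"] = log2_expr["CF1"] - log2_expr["NF1"]
    out["y0"] = log2_expr["RF0"] - log2_expr["NF0"]
    out["y1"] = log2_expr["RF1"] - log2_expr["NF1"]
    return out


def time_average(ratios: pd.DataFrame) -> pd.DataFrame:
    """Add time-averaged ratios ``x = (x0+x1)/2`` and ``y = (y0+y1)/2``.

    Averaging the two time points halves the variance contributed by
    independent per-time-point fluctuations, which is why downstream
    analysis works on ``x`` and ``y``.
    """
    for col in ("x0", "x1", "y0", "y1"):
        if col not in ratios.columns:
            raise ValueError(f"missing ratio column {col!r}")
    out = ratios.copy()
    out["x"] = (out["x0"] + out["x1"]) / 2.0
    out["y"] = (out["y0"] + out["y1"]) / 2.0
    return out


def rotate(x, y, scale: float = ROTATION_SCALE):
    """Rotate (x, y) by 45 degrees into common/differential coordinates.

    ``x' = scale*(x + y)`` measures the response shared by both flow types;
    ``y' = scale*(y - x)`` measures the differential response, positive when
    the rest-inserted response exceeds the continuous one.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return scale * (x + y), scale * (y - x)


def rotate_inverse(x_prime, y_prime, scale: float = ROTATION_SCALE):
    """Inverse of :func:`rotate`: recover (x, y) from (x', y')."""
    x_prime = np.asarray(x_prime, dtype=float)
    y_prime = np.asarray(y_prime, dtype=float)
    factor = 1.0 / (2.0 * scale)
    return factor * (x_prime - y_prime), factor * (x_prime + y_prime)


def rotated_profile(ratios: pd.DataFrame, scale: float = ROTATION_SCALE) -> pd.DataFrame:
    """Append ``x_prime``/``y_prime`` columns to a time-averaged ratio table."""
    for col in ("x", "y"):
        if col not in ratios.columns:
            raise ValueError(f"missing time-averaged column {col!r}; run time_average first")
    out = ratios.copy()
    xp, yp = rotate(out["x"].to_numpy(), out["y"].to_numpy(), scale=scale)
    out["x_prime"] = xp
    out["y_prime"] = yp
    return out


def summarize_geometry(table: pd.DataFrame) -> dict[str, float]:
    """Bounding-box/ellipse and variance summaries of the rotated cloud.

    The "ellipse fit" is literal: the axis-aligned extents in the rotated
    frame, ``extent_x_prime = x'max - x'min`` and likewise for ``y'``.
    Both the full ranges and their halves (``semi_axis_*``) are reported
    because the ranges play the role of ellipse axes.  ``var_timeavg``
    pools the variances of the time-averaged profiles x and y;
    ``var_single_timepoint`` pools those of x0, x1, y0, y1.
    """
    if table.shape[0] < 1:
        raise ValueError("summarize_geometry requires at least one gene")
    needed = ("x0", "x1", "y0", "y1", "x", "y", "x_prime", "y_prime")
    missing = [c for c in needed if c not in table.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    xp = table["x_prime"].to_numpy(dtype=float)
    yp = table["y_prime"].to_numpy(dtype=float)
    extent_x = float(xp.max() - xp.min())
    extent_y = float(yp.max() - yp.min())
    aspect = extent_x / extent_y if extent_y > 0 else float("nan")

    def _pooled_var(columns: tuple[str, ...]) -> float:
        if table.shape[0] < 2:
            return float("nan")
        return float(
            np.mean([table[c].to_numpy(dtype=float).var(ddof=1) for c in columns])
        )

    return {
        "n_genes": int(table.shape[0]),
        "extent_x_prime": extent_x,
        "extent_y_prime": extent_y,
        "semi_axis_x_prime": extent_x / 2.0,
        "semi_axis_y_prime": extent_y / 2.0,
        "aspect_ratio": aspect,
        "var_timeavg": _pooled_var(("x", "y")),
        "var_single_timepoint": _pooled_var(("x0", "x1", "y0", "y1")),
    }
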