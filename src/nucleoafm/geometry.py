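"""Entry/exit DNA arm angles via the polar theta(r) spline method.

Each arm's pixels are expressed in polar coordinates around the NCP
center; a smoothing spline fitted to theta(r) and evaluated at the
NCP border radius gives the arm orientation at the entry (theta2, long
arm) or exit (theta1, short arm) site, measured counterclockwise from the
image +X axis.  Because the absolute origin is arbitrary per movie, only
changes relative to the first frame (delta series) are compared across
molecules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import UnivariateSpline

__all__ = ["AngleSeries", "arm_angle", "ncp_border_radius", "delta_series",
           "wrap_degrees"]


def wrap_degrees(a):
    """Wrap angle(s) to (-180, 180]."""
    return -((-np.asarray(a) + 180.0) % 360.0 - 180.0)


def ncp_border_radius(ncp_mask, pixel_size: float) -> float:
    """Radius (nm) of the circle with the NCP component's area."""
    area = np.count_nonzero(ncp_mask) * pixel_size**2
    return math.sqrt(area / math.pi)


def arm_angle(arm_pixels, ncp_center, border_radius_nm: float,
              pixel_size: float, min_outside: int = 5,
              smooth_deg: float = 5.0):
    """Smoothed theta(r) evaluated at the NCP border, in degrees [0, 360).

    ``arm_pixels`` are (row, col) pixel coordinates of one arm;
    ``ncp_center`` is the (row, col) core center (px).  Angles are measured
    counterclockwise from +X (columns) with rows as +Y.  Returns NaN when
    fewer than ``min_outside`` arm pixels lie outside the border.
    """
    pix = np.asarray(arm_pixels, float)
    if pix.size == 0:
        return float("nan")
    dy = (pix[:, 0] - ncp_center[0]) * pixel_size
    dx = (pix[:, 1] - ncp_center[1]) * pixel_size
    r = np.hypot(dy, dx)
    theta = np.degrees(np.arctan2(dy, dx))

    # pixels inside the border are core-contaminated; fit theta(r) on the
    # free arm only and evaluate the smoothed value at the border
    outside = r > border_radius_nm
    if outside.sum() < min_outside:
        return float("nan")
    r, theta = r[outside], theta[outside]

    # center angles on their circular mean so the spline never sees a wrap
    mean = math.degrees(math.atan2(np.mean(np.sin(np.radians(theta))),
                                   np.mean(np.cos(np.radians(theta)))))
    theta_c = wrap_degrees(theta - mean)

    order = np.argsort(r)
    r_s, th_s = r[order], theta_c[order]
    # aggregate duplicate radii (spline needs strictly increasing x)
    r_u, inv = np.unique(np.round(r_s, 6), return_inverse=True)
    th_u = np.bincount(inv, weights=th_s) / np.bincount(inv)
    if len(r_u) < 4:
        value = float(np.mean(th_u))
    else:
        spl = UnivariateSpline(r_u, th_u, k=min(3, len(r_u) - 1),
                               s=len(r_u) * smooth_deg**2)
        # never extrapolate a cubic: evaluate at the nearest sampled radius
        r_eval = float(np.clip(border_radius_nm, r_u[0], r_u[-1]))
        value = float(spl(r_eval))
    return float((value + mean) % 360.0)


@dataclass
class AngleSeries:
    """Per-frame arm angles and their changes relative to time zero."""

    theta1: np.ndarray   # exit site (short arm), deg; NaN = undefined
    theta2: np.ndarray   # entry site (long arm), deg
    delta1: np.ndarray   # theta1(t) - theta1(t0), stepwise-unwrapped
    delta2: np.ndarray
    display_offset: float = 0.0  # added to theta2 traces when plotting


def _unwrapped_delta(theta):
    """Delta series relative to the first defined frame.

    Consecutive defined-frame steps are wrapped to (-180, 180] before
    cumulative summation, so the series never jumps by more than half a
    turn between frames; undefined frames stay NaN.
    """
    theta = np.asarray(theta, float)
    delta = np.full_like(theta, np.nan)
    idx = np.nonzero(np.isfinite(theta))[0]
    if len(idx) == 0:
        return delta
    steps = wrap_degrees(np.diff(theta[idx]))
    delta[idx] = np.concatenate([[0.0], np.cumsum(steps)])
    return delta


def delta_series(theta1, theta2, display_offset: float = 0.0) -> AngleSeries:
    """Assemble an AngleSeries with stepwise-unwrapped delta traces."""
    theta1 = np.asarray(theta1, float)
    theta2 = np.asarray(theta2, float)
    return AngleSeries(theta1, theta2, _unwrapped_delta(theta1),
                       _unwrapped_delta(theta2), display_offset)
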