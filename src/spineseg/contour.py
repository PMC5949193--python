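"""Closed centripetal Catmull-Rom interpolation of vertebral-body landmarks.

The 16 fitted landmarks are interpolated with a closed Catmull-Rom spline
using centripetal knot spacing (knot increments proportional to the square
root of chord length, ``alpha = 0.5``).  The centripetal parameterization
guarantees no cusps or local self-intersections and keeps the curve tight
around the control polygon, which is what makes it suitable for outlining
compact anatomical structures.  The sampled polyline is rasterized into a
binary mask with the even-odd rule for area-overlap evaluation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from spineseg.imgio import BinaryMask

logger = logging.getLogger(__name__)


@dataclass
class Contour:
    """A closed interpolating spline through ordered control points.

    Attributes
    ----------
    control_points : (n, 2) array
        The cyclic control points (x, y).
    alpha : float
        Knot exponent; 0.5 is the centripetal parameterization.
    samples_per_segment : int
        Polyline density per control-point segment.
    polyline : (n * samples_per_segment + 1, 2) array
        Densely sampled closed curve; first sample equals the last.
    knots : (n + 1,) array
        Strictly increasing knot values; ``knots[i+1] - knots[i]`` equals
        the chord length between consecutive control points raised to alpha.
    """

    control_points: np.ndarray
    alpha: float
    samples_per_segment: int
    polyline: np.ndarray
    knots: np.ndarray


def _barry_goldman(p: np.ndarray, t: np.ndarray, ts: np.ndarray) -> np.ndarray:
    """Evaluate one Catmull-Rom segment by the recursive pyramid.

    ``p`` is the 4x2 block of control points with knots ``t`` (length 4);
    ``ts`` are parameter values in [t[1], t[2]].
    """
    ts = ts[:, None]

    def lerp(pa, pb, ta, tb):
        w = (ts - ta) / (tb - ta)
        return (1.0 - w) * pa + w * pb

    a1 = lerp(p[0], p[1], t[0], t[1])
    a2 = lerp(p[1], p[2], t[1], t[2])
    a3 = lerp(p[2], p[3], t[2], t[3])
    b1 = lerp(a1, a2, t[0], t[2])
    b2 = lerp(a2, a3, t[1], t[3])
    return lerp(b1, b2, t[1], t[2])


def catmull_rom_closed(
    points: np.ndarray,
    alpha: float = 0.5,
    samples_per_segment: int = 20,
) -> Contour:
    """Build a closed centripetal Catmull-Rom contour through ``points``.

    Consecutive duplicate points are collapsed (with a warning); at least
    4 distinct points are required.  The returned polyline starts and ends
    at the first control point.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("control points must be an (n, 2) array")
    # collapse cyclically-consecutive duplicates
    keep = np.ones(len(pts), dtype=bool)
    for i in range(len(pts)):
        if np.allclose(pts[i], pts[(i + 1) % len(pts)]):
            keep[(i + 1) % len(pts)] = False
    if not keep.all():
        logger.warning("collapsed %d duplicate control point(s)", (~keep).sum())
        pts = pts[keep]
    n = len(pts)
    if n < 4:
        raise ValueError(f"need at least 4 distinct control points, got {n}")

    chords = np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1)
    increments = chords**alpha
    knots = np.concatenate([[0.0], np.cumsum(increments)])

    # per segment i: control block (i-1, i, i+1, i+2) with cyclically
    # unwrapped knots so the block's knot sequence is increasing
    samples = []
    for i in range(n):
        idx = [(i - 1) % n, i, (i + 1) % n, (i + 2) % n]
        block = pts[idx]
        t1 = knots[i]
        t2 = knots[i + 1]
        t0 = t1 - increments[(i - 1) % n]
        t3 = t2 + increments[(i + 1) % n]
        tseg = np.linspace(t1, t2, samples_per_segment, endpoint=False)
        samples.append(_barry_goldman(block, np.array([t0, t1, t2, t3]), tseg))
    samples.append(pts[:1])  # close the curve
    polyline = np.vstack(samples)
    return Contour(
        control_points=pts,
        alpha=alpha,
        samples_per_segment=samples_per_segment,
        polyline=polyline,
        knots=knots,
    )


def self_intersects(contour: Contour) -> bool:
    """True if any two non-adjacent polyline segments cross."""
    p = contour.polyline[:-1]
    q = contour.polyline[1:]
    n = len(p)

    d = q - p
    # vectorized orientation tests over all segment pairs
    def cross(o, a, b):
        return (a[..., 0] - o[..., 0]) * (b[..., 1] - o[..., 1]) - (
            a[..., 1] - o[..., 1]
        ) * (b[..., 0] - o[..., 0])

    p_i = p[:, None, :]
    q_i = q[:, None, :]
    p_j = p[None, :, :]
    q_j = q[None, :, :]
    d1 = cross(p_i, q_i, p_j)
    d2 = cross(p_i, q_i, q_j)
    d3 = cross(p_j, q_j, p_i)
    d4 = cross(p_j, q_j, q_i)
    proper = (d1 * d2 < 0) & (d3 * d4 < 0)

    i_idx, j_idx = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    adjacent = (np.abs(i_idx - j_idx) <= 1) | (np.abs(i_idx - j_idx) == n - 1)
    return bool((proper & ~adjacent).any())


def _point_in_polygon_grid(
    polyline: np.ndarray, xs: np.ndarray, ys: np.ndarray
) -> np.ndarray:
    """Even-odd test of pixel centers (xs x ys grid) against a closed polyline."""
    x1, y1 = polyline[:-1, 0], polyline[:-1, 1]
    x2, y2 = polyline[1:, 0], polyline[1:, 1]
    nonhoriz = y1 != y2
    x1, y1, x2, y2 = x1[nonhoriz], y1[nonhoriz], x2[nonhoriz], y2[nonhoriz]
    inside = np.zeros((len(ys), len(xs)), dtype=bool)
    if len(x1) == 0:
        return inside
    # half-open crossing rule per edge: y in [min, max) handles shared vertices
    yy = ys[:, None]  # (H, 1) vs (1, E)
    crosses = (y1[None, :] <= yy) != (y2[None, :] <= yy)
    with np.errstate(divide="ignore", invalid="ignore"):
        xi = x1 + (yy - y1) / (y2 - y1) * (x2 - x1)  # (H, E)
    xi = np.where(crosses, xi, np.nan)
    # pixel (y, x) is inside iff the count of edge crossings right of x is odd
    counts = np.zeros((len(ys), len(xs)), dtype=int)
    for r in range(len(ys)):
        row_xi = xi[r][crosses[r]]
        if row_xi.size:
            counts[r] = (row_xi[None, :] > xs[:, None]).sum(axis=1)
    inside = counts % 2 == 1
    return inside


def rasterize(
    contour: Contour,
    shape: tuple[int, int],
    spacing: tuple[float, float] = (1.0, 1.0),
) -> BinaryMask:
    """Rasterize a closed contour to a pixel mask (even-odd rule).

    A pixel belongs to the mask iff its center is inside the sampled
    polyline.  Contours reaching outside the image are clipped to it; a
    contour entirely outside yields an empty mask and a warning.
    """
    h, w = shape
    poly = contour.polyline
    xmin = max(0, int(np.floor(poly[:, 0].min())))
    xmax = min(w - 1, int(np.ceil(poly[:, 0].max())))
    ymin = max(0, int(np.floor(poly[:, 1].min())))
    ymax = min(h - 1, int(np.ceil(poly[:, 1].max())))
    mask = np.zeros((h, w), dtype=bool)
    if xmin > xmax or ymin > ymax:
        logger.warning("contour lies entirely outside the %dx%d image", h, w)
        return BinaryMask(pixels=mask, spacing=spacing)
    xs = np.arange(xmin, xmax + 1, dtype=float)
    ys = np.arange(ymin, ymax + 1, dtype=float)
    mask[ymin : ymax + 1, xmin : xmax + 1] = _point_in_polygon_grid(poly, xs, ys)
    return BinaryMask(pixels=mask, spacing=spacing)


def area_mm2(obj: Contour | BinaryMask, spacing: tuple[float, float] | None = None) -> float:
    """Physical area in mm^2 of a contour (shoelace) or a mask (pixel count).

    For a :class:`Contour`, ``spacing`` must be given; for a
    :class:`BinaryMask` its own spacing is used unless overridden.
    """
    if isinstance(obj, BinaryMask):
        sp = spacing if spacing is not None else obj.spacing
        return float(obj.area_px * sp[0] * sp[1])
    if spacing is None:
        raise ValueError("spacing is required for contour area")
    poly = obj.polyline
    x, y = poly[:-1, 0], poly[:-1, 1]
    xn, yn = poly[1:, 0], poly[1:, 1]
    shoelace = 0.5 * abs(np.sum(x * yn - xn * y))
    return float(shoelace * spacing[0] * spacing[1])
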