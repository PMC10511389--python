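"""Planar contours: the ordered closed point sets exchanged between pipeline stages.

A contour is an ordered sequence of 2D points in micrometres with a role
(``lumen``, ``outer``, ``region_boundary`` or ``auxiliary``).  Closed contours
are stored counterclockwise; construction normalizes orientation.  The module
also provides the biharmonic-spline resampling used to densify segmentation
contours, nearest-neighbour RMSE between contours, and the point-ordering
check applied after non-rigid registration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from scipy.interpolate import CubicSpline
from scipy.spatial import cKDTree

ROLES = ("lumen", "outer", "region_boundary", "auxiliary")


class ContourError(ValueError):
    """Raised for geometrically invalid contours."""


def shoelace_area(points: np.ndarray) -> float:
    """Signed polygon area (positive for counterclockwise orientation)."""
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polygon_centroid(points: np.ndarray) -> np.ndarray:
    """Area-weighted centroid of a simple closed polygon."""
    x, y = points[:, 0], points[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * np.sum(cross)
    if abs(a) < 1e-12:
        return points.mean(axis=0)
    cx = np.sum((x + xn) * cross) / (6.0 * a)
    cy = np.sum((y + yn) * cross) / (6.0 * a)
    return np.array([cx, cy])


@dataclass
class Contour:
    """Ordered 2D point set in micrometres.

    Closed contours are normalized to counterclockwise orientation on
    construction.  Consecutive duplicate points are rejected; a repeated
    closing point (first == last) is stripped.
    """

    points: np.ndarray
    role: str = "auxiliary"
    region_label: str | None = None
    closed: bool = True

    def __post_init__(self) -> None:
        pts = np.ascontiguousarray(np.asarray(self.points, dtype=float))
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ContourError("contour points must be an (n, 2) array")
        if self.role not in ROLES:
            raise ContourError(f"unknown contour role {self.role!r}")
        if self.closed and len(pts) > 1 and np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        if len(pts) < 3:
            raise ContourError("a contour needs at least 3 distinct points")
        if np.any(np.all(pts[1:] == pts[:-1], axis=1)):
            raise ContourError("contour has duplicated consecutive points")
        if self.closed and shoelace_area(pts) < 0.0:
            pts = pts[::-1].copy()
        self.points = pts

    def __len__(self) -> int:
        return len(self.points)

    @property
    def centroid(self) -> np.ndarray:
        return polygon_centroid(self.points) if self.closed else self.points.mean(axis=0)

    @property
    def area(self) -> float:
        return shoelace_area(self.points)

    def replace_points(self, points: np.ndarray) -> "Contour":
        return Contour(points, role=self.role, region_label=self.region_label, closed=self.closed)

    def as_ring(self) -> shapely.LinearRing:
        return shapely.LinearRing(self.points)


def arc_parameters(points: np.ndarray, closed: bool) -> np.ndarray:
    """Normalized cumulative chord-length parameter in [0, 1] for each point.

    For closed contours the parameter of the (virtual) repeated first point
    is 1, so knots cover [0, 1) and the curve is periodic.
    """
    if closed:
        seg = np.linalg.norm(np.diff(np.vstack([points, points[:1]]), axis=0), axis=1)
        total = seg.sum()
        t = np.concatenate([[0.0], np.cumsum(seg)]) / total
        return t  # length n + 1, t[-1] == 1
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    total = seg.sum()
    return np.concatenate([[0.0], np.cumsum(seg)]) / total


def curve_interpolant(contour: Contour):
    """Biharmonic spline interpolant of the contour against its chord parameter.

    The 1D Green's function of the biharmonic operator, |t|^3, yields exactly
    the cubic spline, so the interpolant is built as a (periodic for closed
    contours, natural otherwise) cubic spline through all input points.
    Returns ``(spline, knots)`` where ``knots`` are the parameters of the
    input points.
    """
    pts = contour.points
    if contour.closed:
        t = arc_parameters(pts, closed=True)
        data = np.vstack([pts, pts[:1]])
        spline = CubicSpline(t, data, axis=0, bc_type="periodic")
        return spline, t[:-1]
    t = arc_parameters(pts, closed=False)
    spline = CubicSpline(t, pts, axis=0, bc_type="natural")
    return spline, t


def resample_contour_biharmonic(contour: Contour, n: int, check_simple: bool = True) -> Contour:
    """Resample a contour to ``n`` points at equal parameter spacing.

    The interpolant passes through every input point, so resampling never
    moves the curve at the original parameters; orientation is preserved.

    Raises
    ------
    ContourError
        If ``n`` is below the input point count, or if the resampled closed
        curve self-intersects (a pathology of the input contour).
    """
    if n < len(contour):
        raise ContourError(f"cannot resample {len(contour)} points down to {n}")
    spline, _ = curve_interpolant(contour)
    if contour.closed:
        u = np.arange(n) / n
    else:
        u = np.linspace(0.0, 1.0, n)
    pts = spline(u)
    out = contour.replace_points(pts)
    if check_simple and contour.closed and not shapely.LineString(
        np.vstack([out.points, out.points[:1]])
    ).is_simple:
        raise ContourError("resampled contour is self-intersecting")
    return out


def contour_rmse(moved: Contour, target: Contour) -> float:
    """RMS of the distance from each moved point to its nearest target point.

    The target should be densely resampled relative to the moved contour so
    that the nearest-point distance approximates the distance to the curve.
    """
    d, _ = cKDTree(target.points).query(moved.points)
    return float(np.sqrt(np.mean(d**2)))


def ordering_preserved(before: Contour, after: Contour) -> bool:
    """Whether the angular order of points about the centroid is unchanged.

    True iff the angular sequence of ``after`` about its centroid is strictly
    monotone with the same winding sense as ``before``.  Both contours must
    have identical point counts and indexing.
    """
    if len(before) != len(after):
        raise ContourError("ordering check requires equal point counts")

    def wrapped_steps(c: Contour) -> np.ndarray:
        rel = c.points - c.points.mean(axis=0)
        ang = np.arctan2(rel[:, 1], rel[:, 0])
        d = np.diff(np.concatenate([ang, ang[:1]]))
        return (d + np.pi) % (2.0 * np.pi) - np.pi

    sense = np.sign(wrapped_steps(before).sum())
    steps = wrapped_steps(after)
    return bool(np.all(sense * steps > 0.0))


def spacing_uniformity(points: np.ndarray, closed: bool = True) -> float:
    """Uniformity score of point spacing: 1 - CV of arc-length gaps, clipped to [0, 1]."""
    if closed:
        seg = np.linalg.norm(np.diff(np.vstack([points, points[:1]]), axis=0), axis=1)
    else:
        seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    m = seg.mean()
    if m <= 0:
        return 0.0
    cv = seg.std() / m
    return float(np.clip(1.0 - cv, 0.0, 1.0))


def polyline_radius_interpolant(points: np.ndarray, center: np.ndarray):
    """Radius of a closed polyline along rays from ``center`` (star-shaped).

    The returned callable interpolates along the polygon chords, so evaluated
    points lie exactly on the polyline, not on a smoothed curve.
    """
    rel = np.asarray(points, dtype=float) - np.asarray(center, dtype=float)
    theta = np.arctan2(rel[:, 1], rel[:, 0])
    order = np.argsort(theta)
    theta = theta[order]
    pts = rel[order]
    theta_ext = np.concatenate([[theta[-1] - 2 * np.pi], theta, [theta[0] + 2 * np.pi]])
    pts_ext = np.vstack([pts[-1], pts, pts[0]])

    def radius(t):
        scalar = np.ndim(t) == 0
        t = np.atleast_1d(np.asarray(t, dtype=float))
        t = np.mod(t - theta[0], 2.0 * np.pi) + theta[0]
        idx = np.clip(np.searchsorted(theta_ext, t, side="right") - 1, 0, len(theta_ext) - 2)
        p1, p2 = pts_ext[idx], pts_ext[idx + 1]
        ct, st = np.cos(t), np.sin(t)
        num = p1[:, 0] * p2[:, 1] - p2[:, 0] * p1[:, 1]
        den = (p2[:, 1] - p1[:, 1]) * ct - (p2[:, 0] - p1[:, 0]) * st
        exact = np.abs(den) < 1e-30
        r = np.where(exact, np.hypot(p1[:, 0], p1[:, 1]), num / np.where(exact, 1.0, den))
        return float(r[0]) if scalar else r

    return radius


def distance_to_polyline(points: np.ndarray, polyline: np.ndarray, closed: bool = True) -> np.ndarray:
    """Distance from each query point to a polyline (the curve, not its vertices)."""
    if closed:
        geom = shapely.LinearRing(polyline)
    else:
        geom = shapely.LineString(polyline)
    return shapely.distance(shapely.points(points), geom)
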