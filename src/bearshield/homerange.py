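"""Minimum convex polygon home ranges and availability sampling.

Availability is defined at third order (within each mother's 100% MCP —
the convex hull of all her retained fixes) or at second order (over the
whole study area, taken as the union extent of all MCPs unless a polygon
is supplied).  Availability samples are matched in size to each
bear-year's retained used points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import Polygon

__all__ = [
    "HomeRangePolygon",
    "AvailabilitySample",
    "convex_hull",
    "point_in_polygon",
    "mcp_home_range",
    "sample_availability",
    "study_area_polygon",
]


@dataclass(frozen=True)
class HomeRangePolygon:
    """A bear-year's 100% minimum convex polygon (closed CCW ring, planar m)."""

    bear_id: str
    year: int
    vertices: np.ndarray  # (k, 2), first vertex not repeated

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    @property
    def area(self) -> float:
        return self.polygon.area


@dataclass(frozen=True)
class AvailabilitySample:
    bear_id: str
    year: int
    points: np.ndarray  # (n, 2)
    order: str  # "third" | "second"


def convex_hull(points) -> np.ndarray:
    """Vertices of the convex hull, counter-clockwise, collinear points dropped.

    Requires >= 3 non-collinear points; degenerate input raises
    ``ValueError("degenerate hull")``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ValueError("degenerate hull: need at least three 2-D points")
    try:
        hull = ConvexHull(pts)
    except QhullError as err:
        raise ValueError("degenerate hull: points are collinear") from err
    verts = pts[hull.vertices]  # qhull returns CCW order in 2-D, extreme points only
    # drop any residual collinear vertices (ties on a hull edge)
    keep = []
    k = len(verts)
    for i in range(k):
        a, b, c = verts[i - 1], verts[i], verts[(i + 1) % k]
        cross = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
        if abs(cross) > 1e-12 * max(1.0, np.abs(verts).max() ** 2):
            keep.append(i)
    if len(keep) < 3:
        raise ValueError("degenerate hull: points are collinear")
    return verts[keep]


def point_in_polygon(p, ring) -> bool:
    """Boundary-inclusive point-in-polygon test (hull vertices count as inside)."""
    poly = Polygon(np.asarray(ring, dtype=float))
    return bool(shapely.covers(poly, shapely.Point(p)))


def mcp_home_range(record) -> HomeRangePolygon:
    """100% MCP of a bear-year's fixes."""
    ring = convex_hull(record.fixes[["x", "y"]].to_numpy(dtype=float))
    return HomeRangePolygon(bear_id=record.bear_id, year=record.year, vertices=ring)


def study_area_polygon(home_ranges) -> Polygon:
    """Second-order availability domain: bounding extent of all MCPs."""
    xs, ys = [], []
    for hr in home_ranges:
        xs.extend(hr.vertices[:, 0])
        ys.extend(hr.vertices[:, 1])
    return shapely.box(min(xs), min(ys), max(xs), max(ys))


def sample_availability(
    record,
    region,
    seed,
    order: str = "third",
    n_points: int | None = None,
) -> AvailabilitySample:
    """Uniform availability points matched in number to the retained used points.

    ``region`` is a HomeRangePolygon (third order) or a shapely polygon
    (second order).  Sampling is uniform rejection from the region's
    bounding box; an acceptance rate below 1e-4 (degenerate sliver region)
    raises.  The random stream depends only on ``seed``, never on the used
    locations.
    """
    poly = region.polygon if isinstance(region, HomeRangePolygon) else region
    if poly.area <= 0:
        raise ValueError("availability region has zero area")
    n = record.n_fixes if n_points is None else n_points
    if n == 0:
        return AvailabilitySample(record.bear_id, record.year, np.empty((0, 2)), order)
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = poly.bounds
    shapely.prepare(poly)  # speeds up the covers() calls below
    out = np.empty((n, 2))
    filled = 0
    tried = 0
    while filled < n:
        m = max(2 * (n - filled), 512)
        px = rng.uniform(xmin, xmax, m)
        py = rng.uniform(ymin, ymax, m)
        inside = shapely.covers(poly, shapely.points(px, py))
        tried += m
        px, py = px[inside], py[inside]
        take = min(len(px), n - filled)
        out[filled : filled + take, 0] = px[:take]
        out[filled : filled + take, 1] = py[:take]
        filled += take
        if tried > 1e4 and filled / tried < 1e-4:
            raise ValueError("availability region is a degenerate sliver (acceptance < 1e-4)")
    return AvailabilitySample(record.bear_id, record.year, out, order)


def availability_frame(samples) -> pd.DataFrame:
    """Flatten availability samples to a points table (bear_id, year, x, y)."""
    frames = []
    for s in samples:
        frames.append(
            pd.DataFrame(
                {"bear_id": s.bear_id, "year": s.year, "x": s.points[:, 0], "y": s.points[:, 1]}
            )
        )
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["bear_id", "year", "x", "y"]
    )
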