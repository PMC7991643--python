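"""Polygon helpers shared by the simulator and the cell profiler.

Coordinates are in pixel units: x runs along columns, y along rows, and
the centre of pixel (row r, col c) is at (c + 0.5, r + 0.5).
"""

from __future__ import annotations

import numpy as np
import shapely

from virtustain.errors import ValidationError


def as_polygon_array(poly) -> np.ndarray:
    arr = np.asarray(poly, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValidationError(
            f"polygon must be an (n>=3, 2) vertex array, got shape {arr.shape}"
        )
    return arr


def to_shapely(poly) -> shapely.Polygon:
    p = shapely.Polygon(as_polygon_array(poly))
    if not p.is_valid:
        raise ValidationError("polygon is self-intersecting or degenerate")
    if p.area <= 0:
        raise ValidationError("polygon area must be positive")
    return p


def rasterize_polygon(poly, field_size) -> np.ndarray:
    """Boolean mask of pixels whose centres fall inside the polygon."""
    h, w = int(field_size[0]), int(field_size[1])
    p = to_shapely(poly)
    minx, miny, maxx, maxy = p.bounds
    r0 = max(int(np.floor(miny - 0.5)), 0)
    r1 = min(int(np.ceil(maxy + 0.5)), h)
    c0 = max(int(np.floor(minx - 0.5)), 0)
    c1 = min(int(np.ceil(maxx + 0.5)), w)
    mask = np.zeros((h, w), dtype=bool)
    if r1 <= r0 or c1 <= c0:
        return mask
    cc, rr = np.meshgrid(np.arange(c0, c1), np.arange(r0, r1))
    inside = shapely.contains_xy(p, cc.ravel() + 0.5, rr.ravel() + 0.5)
    mask[r0:r1, c0:c1] = inside.reshape(rr.shape)
    return mask


def polygon_moments(poly) -> dict:
    """Exact area, centroid and inertia-equivalent ellipse of a polygon.

    Uses Green's-theorem formulas for the area and second moments about
    the centroid, then converts the central moments to the axes of the
    equivalent (same second moments, same area) ellipse, matching the
    convention used for raster region moments.
    """
    v = as_polygon_array(poly)
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * np.sum(cross)
    if a == 0:
        raise ValidationError("degenerate polygon (zero area)")
    sign = 1.0 if a > 0 else -1.0
    area = abs(a)
    cx = np.sum((x + xn) * cross) / (6.0 * a)
    cy = np.sum((y + yn) * cross) / (6.0 * a)
    # second moments about the origin
    ixx = np.sum((y * y + y * yn + yn * yn) * cross) / 12.0 * sign
    iyy = np.sum((x * x + x * xn + xn * xn) * cross) / 12.0 * sign
    ixy = np.sum((x * yn + 2 * x * y + 2 * xn * yn + xn * y) * cross) / 24.0 * sign
    # central normalized second moments (per unit area)
    mu_xx = iyy - area * cx * cx
    mu_yy = ixx - area * cy * cy
    mu_xy = ixy - area * cx * cy
    u20, u02, u11 = mu_xx / area, mu_yy / area, mu_xy / area
    common = np.sqrt(max((u20 - u02) ** 2 + 4 * u11 * u11, 0.0))
    l1 = (u20 + u02 + common) / 2.0
    l2 = (u20 + u02 - common) / 2.0
    major = 4.0 * np.sqrt(max(l1, 0.0))
    minor = 4.0 * np.sqrt(max(l2, 0.0))
    ecc = np.sqrt(1.0 - (l2 / l1)) if l1 > 0 else 0.0
    return {
        "area": float(area),
        "centroid": (float(cx), float(cy)),
        "major_axis": float(major),
        "minor_axis": float(minor),
        "aspect_ratio": float(major / minor) if minor > 0 else np.inf,
        "eccentricity": float(ecc),
    }
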