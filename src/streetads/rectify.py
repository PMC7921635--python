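"""Frontal-view rectification of extracted crops.

A learned warping module could fill this seam; the default here is purely
geometric: fit a minimum-area enclosing quadrilateral to the instance hull,
then apply the homography taking that quad onto a fixed-size upright
rectangle. Deterministic, training-free, and sufficient to give the
classifier consistently framed inputs.
"""

from __future__ import annotations

from typing import Protocol, runtime_checkable

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from skimage.transform import ProjectiveTransform, warp

from .core import AdInstance

DEFAULT_OUT_SIZE = (224, 224)  # (height, width)


class DegenerateGeometryError(ValueError):
    """Raised for hulls with no area (collinear or fewer than 3 points)."""


@runtime_checkable
class RectifierContract(Protocol):
    def rectify(self, crop: np.ndarray, hull: np.ndarray) -> np.ndarray: ...


def _line_intersection(p1, p2, p3, p4):
    """Intersection of lines (p1,p2) and (p3,p4); None if near-parallel."""
    d1 = p2 - p1
    d2 = p4 - p3
    denom = d1[0] * d2[1] - d1[1] * d2[0]
    norm = max(np.hypot(*d1) * np.hypot(*d2), 1e-12)
    if abs(denom) < 1e-9 * norm:
        return None
    t = ((p3[0] - p1[0]) * d2[1] - (p3[1] - p1[1]) * d2[0]) / denom
    return p1 + t * d1


def _order_clockwise_from_tl(quad: np.ndarray) -> np.ndarray:
    """Order corners clockwise on screen (y down) starting near top-left."""
    centre = quad.mean(axis=0)
    ang = np.arctan2(quad[:, 1] - centre[1], quad[:, 0] - centre[0])
    quad = quad[np.argsort(ang)]  # clockwise when y points down
    start = int(np.argmin(quad.sum(axis=1)))
    return np.roll(quad, -start, axis=0)


def fit_quad(hull: np.ndarray) -> np.ndarray:
    """Minimum-area enclosing quadrilateral of a convex hull.

    Uses the classic edge-collapse heuristic: while more than four vertices
    remain, remove the edge whose replacement by the intersection of its
    neighbouring edges' support lines adds the least area. Triangles are
    promoted to quadrilaterals by splitting their longest edge, so the
    result always encloses the hull. Corners come back ordered clockwise
    from (approximately) the top-left.
    """
    pts = np.asarray(hull, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise DegenerateGeometryError("hull needs at least 3 vertices")
    try:
        ch = ConvexHull(pts)
    except QhullError as e:
        raise DegenerateGeometryError(f"degenerate hull: {e}") from None
    if ch.volume <= 0:  # 2-D "volume" is the polygon area
        raise DegenerateGeometryError("hull has zero area")
    v = pts[ch.vertices]  # counter-clockwise in math axes

    while len(v) > 4:
        n = len(v)
        best = None  # (added_area, edge_index, new_point)
        for i in range(n):
            a, b = v[(i - 1) % n], v[i]          # previous edge
            c, d = v[(i + 1) % n], v[(i + 2) % n]  # next edge
            p = _line_intersection(a, b, d, c)
            if p is None:
                continue
            # added area = triangle (b, p, c)
            added = 0.5 * abs(
                (p[0] - b[0]) * (c[1] - b[1]) - (c[0] - b[0]) * (p[1] - b[1])
            )
            if best is None or added < best[0]:
                best = (added, i, p)
        if best is None:
            raise DegenerateGeometryError("cannot collapse hull to a quadrilateral")
        _, i, p = best
        v = np.delete(v, [i, (i + 1) % len(v)], axis=0)
        v = np.insert(v, i % (len(v) + 1), p, axis=0)

    if len(v) == 3:
        lengths = [np.hypot(*(v[(i + 1) % 3] - v[i])) for i in range(3)]
        i = int(np.argmax(lengths))
        mid = (v[i] + v[(i + 1) % 3]) / 2
        v = np.insert(v, i + 1, mid, axis=0)

    return _order_clockwise_from_tl(v)


def warp_frontal(
    crop: np.ndarray,
    quad: np.ndarray,
    out_size: tuple[int, int] = DEFAULT_OUT_SIZE,
) -> np.ndarray:
    """Warp the quad region of a crop onto an upright out_size rectangle.

    Bilinear interpolation; pixels sampled outside the crop are zero,
    consistent with hull masking upstream. Degenerate 1-pixel-wide outputs
    are served as the mean colour over the quad's bounding region.
    """
    quad = np.asarray(quad, dtype=float)
    if quad.shape != (4, 2):
        raise ValueError("quad must be 4x2")
    h, w = out_size
    if h < 1 or w < 1:
        raise ValueError("out_size must be positive")
    crop = np.asarray(crop)
    if h < 2 or w < 2:
        x0, y0 = np.floor(quad.min(axis=0)).astype(int)
        x1, y1 = np.ceil(quad.max(axis=0)).astype(int) + 1
        region = crop[max(y0, 0) : y1, max(x0, 0) : x1]
        mean = region.reshape(-1, crop.shape[2]).mean(axis=0) if crop.ndim == 3 else region.mean()
        out = np.empty((h, w) + crop.shape[2:], dtype=crop.dtype)
        out[...] = np.round(mean) if np.issubdtype(crop.dtype, np.integer) else mean
        return out
    rect = np.array([[0, 0], [w - 1, 0], [w - 1, h - 1], [0, h - 1]], dtype=float)
    tform = ProjectiveTransform.from_estimate(rect, quad)
    if not tform:
        raise ValueError("non-invertible homography for the given quad")
    warped = warp(crop.astype(float), inverse_map=tform, output_shape=(h, w), order=1, cval=0.0)
    if np.issubdtype(crop.dtype, np.integer):
        return np.clip(np.round(warped), 0, 255).astype(crop.dtype)
    return warped


class HomographyRectifier:
    """Default rectifier: fit_quad + perspective warp to a fixed size."""

    def __init__(self, out_size: tuple[int, int] = DEFAULT_OUT_SIZE):
        self.out_size = out_size

    def rectify(self, crop: np.ndarray, hull: np.ndarray) -> np.ndarray:
        return warp_frontal(crop, fit_quad(hull), self.out_size)


def rectify_instance(inst: AdInstance, rectifier: RectifierContract | None = None) -> np.ndarray:
    """Rectify one extracted instance, shifting its hull into crop coordinates."""
    if rectifier is None:
        rectifier = HomographyRectifier()
    r0, c0, _, _ = inst.bbox
    hull_local = inst.hull - np.array([c0, r0], dtype=float)
    return rectifier.rectify(inst.crop, hull_local)
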