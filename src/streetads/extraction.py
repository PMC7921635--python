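"""Advertisement instance extraction from semantic label maps.

Each connected component of advertisement pixels becomes a candidate
instance: a convex hull is drawn around the component and filled to obtain
a binary mask, instances whose filled hull covers fewer than 2000 pixels
are discarded (small advertisements are too low-resolution to categorise),
and the surviving instances carry a hull-masked tight crop plus the source
frame's geotag.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from skimage.measure import label as cc_label
from skimage.morphology import convex_hull_image

from .core import AD_IDS, AdInstance, LabelMap, PALETTE, StreetImage

#: Minimum filled-hull pixel area for an instance to be retained.
DEFAULT_MIN_AREA = 2000


def _category_mask(label_map: LabelMap, category_id) -> np.ndarray:
    ids = {category_id} if np.isscalar(category_id) else set(category_id)
    unknown = ids - set(PALETTE)
    if unknown:
        raise ValueError(f"unknown category ids {sorted(unknown)}")
    return np.isin(label_map.grid, sorted(ids))


def find_components(label_map: LabelMap, category_id, connectivity: int = 8) -> list[np.ndarray]:
    """Maximal connected sets of the category's pixels.

    ``category_id`` may be a single palette id or an iterable of ids (the
    usual call treats all advertisement ids as one "billboard" class).
    Returns one boolean mask per component.
    """
    if connectivity not in (4, 8):
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    mask = _category_mask(label_map, category_id)
    labelled = cc_label(mask, connectivity=1 if connectivity == 4 else 2)
    return [labelled == k for k in range(1, labelled.max() + 1)]


def hull_and_fill(component: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Convex hull of a pixel set, its filled mask, and the filled area.

    Returns ``(hull_vertices, filled_mask, filled_area_px)`` where the hull
    is a (K, 2) array of (x, y) vertices in counter-clockwise order on
    screen (y down). Degenerate components (single pixel, collinear) yield
    their pixel set unchanged with a minimal hull polygon.
    """
    component = np.asarray(component, dtype=bool)
    if not component.any():
        raise ValueError("component is empty")
    filled = convex_hull_image(component)
    rows, cols = np.nonzero(component)
    pts = np.column_stack([cols, rows]).astype(float)  # (x, y)
    try:
        hull = ConvexHull(pts)
        vertices = pts[hull.vertices]
    except QhullError:  # < 3 unique points or collinear
        lo = pts.min(axis=0)
        hi = pts.max(axis=0)
        vertices = np.unique(np.array([lo, [hi[0], lo[1]], hi, [lo[0], hi[1]]]), axis=0)
    return vertices, filled, int(filled.sum())


def extract_instances(
    label_map: LabelMap,
    image: StreetImage,
    min_area: int = DEFAULT_MIN_AREA,
    category_id=None,
    connectivity: int = 8,
) -> list[AdInstance]:
    """Extract one :class:`AdInstance` per sufficiently large component.

    A component is retained iff its *filled hull* covers at least
    ``min_area`` pixels (boundary kept: exactly 2000 passes the default).
    Crops are masked to the hull — pixels outside it are zero — and
    tight-cropped to the hull's bounding box. Instances inherit the source
    frame's lon/lat; this is the capture point, an approximation to the
    billboard's true position.
    """
    if label_map.shape != image.shape:
        raise ValueError(
            f"label map {label_map.shape} and image {image.shape} dimensions disagree"
        )
    if category_id is None:
        category_id = AD_IDS
    instances = []
    for k, component in enumerate(find_components(label_map, category_id, connectivity)):
        hull, filled, area = hull_and_fill(component)
        if area < min_area:
            continue
        rows, cols = np.nonzero(filled)
        r0, r1 = rows.min(), rows.max() + 1
        c0, c1 = cols.min(), cols.max() + 1
        masked = np.where(filled[..., None], image.pixels, 0)
        instances.append(
            AdInstance(
                instance_id=f"{image.image_id}_ad{k:02d}",
                image_id=image.image_id,
                hull=hull,
                filled_area_px=area,
                crop=masked[r0:r1, c0:c1],
                lon=image.lon,
                lat=image.lat,
                bbox=(int(r0), int(c0), int(r1), int(c1)),
            )
        )
    return instances


def extract_all(
    label_maps: dict[str, LabelMap],
    images: dict[str, StreetImage],
    min_area: int = DEFAULT_MIN_AREA,
    connectivity: int = 8,
) -> list[AdInstance]:
    """Extract instances from every frame of a survey, in frame order."""
    out: list[AdInstance] = []
    for image_id in sorted(images):
        if image_id not in label_maps:
            raise ValueError(f"no label map for image {image_id}")
        out.extend(
            extract_instances(
                label_maps[image_id], images[image_id], min_area=min_area, connectivity=connectivity
            )
        )
    return out
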