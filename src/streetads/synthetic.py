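"""Deterministic synthetic street-survey fixtures.

Generates everything a desk-scale run of the pipeline needs with no
download: straight-line cycling routes sampled at a fixed time interval,
street-scene frames with planted billboards re-observed across consecutive
frames, pixel-exact ground-truth label maps, labelled crop sets for
classifier training, and attribute-tagged zone polygons.

Design notes
------------
* Routes are straight lines at constant heading so inter-frame distances
  are analytic (real survey routes are irregular; straightness is a fixture
  simplification, not a pipeline assumption).
* Billboard textures are procedural: each content category has a distinct
  colour palette and base pattern, and each physical billboard additionally
  carries a seeded speckle field. The palette separates categories for a
  desk-scale classifier; the speckle makes keypoint descriptors distinctive
  per billboard so feature matching can tell physical billboards apart.
* Geographic placement uses a local equirectangular metre->degree
  conversion around the route origin, valid for the sub-kilometre fixtures
  generated here.
* All randomness flows through :func:`numpy.random.default_rng` seeded from
  explicit integer seeds, so equal seeds give bit-identical bundles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import polygon as draw_polygon
from skimage.transform import ProjectiveTransform, warp
from shapely.geometry import Polygon as ShapelyPolygon

from .core import CATEGORIES, CATEGORY_IDS, LabelMap, StreetImage
from .geo import offset_lonlat
from .zones import OAC_GROUPS, Zone

__all__ = [
    "RouteSpec",
    "PlantedBillboard",
    "FixtureBundle",
    "generate_route",
    "plant_billboards",
    "generate_zones",
    "billboard_texture",
    "rect_quad",
    "standard_plan",
    "labelled_crop_set",
]

_EPOCH = pd.Timestamp("2020-01-14T09:00:00+00:00")


@dataclass(frozen=True)
class RouteSpec:
    """A straight survey route sampled at a fixed time interval."""

    n_frames: int
    frame_interval_s: float = 0.5
    speed_mps: float = 10.0
    origin: tuple[float, float] = (-2.98, 53.40)  # lon, lat
    heading_deg: float = 90.0  # 0 = north, 90 = east
    seed: int = 0


@dataclass
class PlantedBillboard:
    """Ground truth for one physical billboard planted in the fixture.

    ``pixel_polygon_per_frame`` maps each visible frame index to a 4x2
    array of (x, y) quad corners, inclusive integer pixel convention: the
    rasterised polygon of corners (x0, y0)..(x0+w-1, y0+h-1) covers exactly
    w*h pixels.
    """

    billboard_id: str
    category: str
    visible_in: list[int]
    pixel_polygon_per_frame: dict[int, np.ndarray]
    texture_seed: int = 0

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}; expected one of {CATEGORIES}")
        if sorted(self.visible_in) != sorted(self.pixel_polygon_per_frame):
            raise ValueError("visible_in and pixel_polygon_per_frame frames disagree")
        for f, quad in self.pixel_polygon_per_frame.items():
            quad = np.asarray(quad, dtype=float)
            if quad.shape != (4, 2):
                raise ValueError(f"frame {f}: polygon must be a 4x2 quadrilateral")
            self.pixel_polygon_per_frame[f] = quad


@dataclass
class FixtureBundle:
    """A complete synthetic survey: frames, truth maps, manifest, zones."""

    images: dict[str, StreetImage]
    label_maps: dict[str, LabelMap]
    truth_manifest: list[PlantedBillboard]
    route: pd.DataFrame
    zones: list[Zone] = field(default_factory=list)

    def frame_id(self, index: int) -> str:
        return f"frame_{index:05d}"


def generate_route(spec: RouteSpec) -> pd.DataFrame:
    """Emit the ordered frame positions of a straight constant-speed route.

    Returns a DataFrame with columns ``frame_id, lon, lat, timestamp``;
    consecutive positions are exactly ``speed_mps * frame_interval_s``
    metres apart along the heading.
    """
    if spec.n_frames < 1:
        raise ValueError(f"n_frames must be >= 1, got {spec.n_frames}")
    if spec.speed_mps <= 0:
        raise ValueError(f"speed_mps must be positive, got {spec.speed_mps}")
    if spec.frame_interval_s <= 0:
        raise ValueError(f"frame_interval_s must be positive, got {spec.frame_interval_s}")

    step = spec.speed_mps * spec.frame_interval_s
    theta = np.radians(spec.heading_deg)
    rows = []
    for i in range(spec.n_frames):
        east = step * i * np.sin(theta)
        north = step * i * np.cos(theta)
        lon, lat = offset_lonlat(spec.origin[0], spec.origin[1], east, north)
        ts = _EPOCH + pd.Timedelta(seconds=i * spec.frame_interval_s)
        rows.append((f"frame_{i:05d}", lon, lat, ts.isoformat()))
    return pd.DataFrame(rows, columns=["frame_id", "lon", "lat", "timestamp"])


# ---------------------------------------------------------------------------
# Textures


_PALETTES = {
    # (colour_a, colour_b, pattern)
    "food": ((210, 40, 30), (250, 210, 60), "checker"),
    "alcohol": ((20, 40, 120), (230, 160, 40), "hstripe"),
    "gambling": ((20, 130, 60), (240, 240, 240), "dstripe"),
    "other": ((90, 90, 100), (190, 190, 200), "vstripe"),
}


def billboard_texture(category: str, texture_seed: int, size: tuple[int, int] = (96, 128)) -> np.ndarray:
    """Procedural frontal texture for one billboard.

    Category decides palette and base pattern; the seed adds a per-billboard
    speckle field so two billboards of the same category remain
    distinguishable to a keypoint matcher.
    """
    if category not in _PALETTES:
        raise ValueError(f"unknown category {category!r}")
    h, w = size
    ca, cb, pattern = _PALETTES[category]
    yy, xx = np.mgrid[0:h, 0:w]
    if pattern == "checker":
        sel = ((yy // 16) + (xx // 16)) % 2 == 0
    elif pattern == "hstripe":
        sel = (yy // 12) % 2 == 0
    elif pattern == "dstripe":
        sel = ((yy + xx) // 14) % 2 == 0
    else:
        sel = (xx // 12) % 2 == 0
    tex = np.where(sel[..., None], np.array(ca, dtype=float), np.array(cb, dtype=float))

    cat_key = CATEGORIES.index(category)
    rng = np.random.default_rng(np.random.SeedSequence([cat_key, texture_seed]))
    # coarse blobs + fine speckle give keypoint detectors distinctive,
    # non-repetitive structure unique to each physical billboard
    blobs = rng.normal(0.0, 1.0, (-(-h // 8), -(-w // 8)))
    blobs = np.kron(blobs, np.ones((8, 8)))[:h, :w] * 28.0
    speckle = rng.normal(0.0, 14.0, (h, w))
    tex += (blobs + speckle)[..., None]
    return np.clip(tex, 0, 255).astype(np.uint8)


def rect_quad(x0: int, y0: int, width: int, height: int) -> np.ndarray:
    """Axis-aligned quad in the inclusive-corner convention (w*h pixels)."""
    return np.array(
        [
            [x0, y0],
            [x0 + width - 1, y0],
            [x0 + width - 1, y0 + height - 1],
            [x0, y0 + height - 1],
        ],
        dtype=float,
    )


def _rasterise(quad: np.ndarray, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    return draw_polygon(quad[:, 1], quad[:, 0], shape=shape)


def plant_billboards(
    route: pd.DataFrame,
    plan: list[PlantedBillboard],
    image_size: tuple[int, int] = (300, 400),
    seed: int = 0,
) -> FixtureBundle:
    """Render frames and pixel-exact label maps for a billboard plan.

    Every frame of ``route`` gets an RGB image (textured background plus the
    billboards visible in it, perspective-warped to their quads) and a label
    map in which exactly the rasterised quad pixels carry the billboard's
    category id. The returned truth manifest is the plan itself.
    """
    h, w = image_size
    for pb in plan:
        for f, quad in pb.pixel_polygon_per_frame.items():
            if f < 0 or f >= len(route):
                raise ValueError(f"billboard {pb.billboard_id}: frame {f} outside route")
            if quad.min() < 0 or quad[:, 0].max() > w - 1 or quad[:, 1].max() > h - 1:
                raise ValueError(
                    f"billboard {pb.billboard_id}: polygon outside image bounds in frame {f}"
                )

    by_frame: dict[int, list[PlantedBillboard]] = {}
    for pb in plan:
        for f in pb.visible_in:
            by_frame.setdefault(f, []).append(pb)

    images: dict[str, StreetImage] = {}
    label_maps: dict[str, LabelMap] = {}
    for i, row in route.iterrows():
        rng = np.random.default_rng(np.random.SeedSequence([seed, int(i)]))
        # muted textured background, kept low-contrast relative to billboards
        bg = rng.normal(128.0, 6.0, (h, w, 1)) + rng.normal(0.0, 4.0, (h, w, 3))
        img = np.clip(bg, 0, 255)
        grid = np.zeros((h, w), dtype=np.uint8)
        for pb in sorted(by_frame.get(i, []), key=lambda b: b.billboard_id):
            quad = pb.pixel_polygon_per_frame[i]
            tex = billboard_texture(pb.category, pb.texture_seed)
            th, tw = tex.shape[:2]
            tform = ProjectiveTransform.from_estimate(
                quad, np.array([[0, 0], [tw - 1, 0], [tw - 1, th - 1], [0, th - 1]], dtype=float)
            )
            if not tform:
                raise ValueError(f"billboard {pb.billboard_id}: degenerate quad in frame {i}")
            warped = warp(tex.astype(float), inverse_map=tform, output_shape=(h, w), order=1, cval=0.0)
            rr, cc = _rasterise(quad, (h, w))
            img[rr, cc] = warped[rr, cc]
            grid[rr, cc] = CATEGORY_IDS[pb.category]
        fid = row["frame_id"]
        images[fid] = StreetImage(
            image_id=fid,
            pixels=img.astype(np.uint8),
            lon=float(row["lon"]),
            lat=float(row["lat"]),
            timestamp=str(row["timestamp"]),
        )
        label_maps[fid] = LabelMap(image_id=fid, grid=grid)

    return FixtureBundle(images=images, label_maps=label_maps, truth_manifest=list(plan), route=route)


# ---------------------------------------------------------------------------
# Zones


def generate_zones(
    bbox: tuple[float, float, float, float],
    n_cols: int,
    n_rows: int,
    attribute_seed: int = 0,
) -> list[Zone]:
    """Tile a lon/lat bbox with an attribute-tagged polygon grid.

    Each cell gets a deprivation decile (1..10, 1 = most deprived) and an
    output-area-classification group code, both drawn deterministically from
    ``attribute_seed``. Cells tile the bbox exactly and do not overlap.
    """
    minx, miny, maxx, maxy = bbox
    if not (maxx > minx and maxy > miny):
        raise ValueError(f"degenerate bbox {bbox}")
    if n_cols < 1 or n_rows < 1:
        raise ValueError("n_cols and n_rows must be >= 1")
    rng = np.random.default_rng(attribute_seed)
    xs = np.linspace(minx, maxx, n_cols + 1)
    ys = np.linspace(miny, maxy, n_rows + 1)
    zones = []
    k = 0
    for r in range(n_rows):
        for c in range(n_cols):
            poly = ShapelyPolygon(
                [(xs[c], ys[r]), (xs[c + 1], ys[r]), (xs[c + 1], ys[r + 1]), (xs[c], ys[r + 1])]
            )
            group = OAC_GROUPS[int(rng.integers(len(OAC_GROUPS)))]
            zones.append(
                Zone(
                    zone_id=k,
                    polygon=poly,
                    imd_decile=int(rng.integers(1, 11)),
                    oac_supergroup=int(group[0]),
                    oac_group=group,
                )
            )
            k += 1
    return zones


# ---------------------------------------------------------------------------
# Ready-made plans and crop sets


def standard_plan(
    route: pd.DataFrame,
    n_billboards: int = 12,
    frames_per_billboard: tuple[int, int] = (2, 4),
    gap_frames: int = 3,
    image_size: tuple[int, int] = (300, 400),
    base_size: tuple[int, int] = (120, 95),
    seed: int = 0,
) -> list[PlantedBillboard]:
    """Plan distinct billboards each re-observed in consecutive frames.

    Billboards occupy disjoint frame windows separated by ``gap_frames``
    frames, so observations of one billboard stay spatially close while
    distinct billboards are well separated along the route. The quad drifts
    and shrinks slightly from frame to frame, mimicking the changing
    viewpoint of a moving camera.
    """
    rng = np.random.default_rng(seed)
    h, w = image_size
    bw, bh = base_size
    plan = []
    frame = 0
    lo, hi = frames_per_billboard
    for b in range(n_billboards):
        k = int(rng.integers(lo, hi + 1))
        if frame + k > len(route):
            raise ValueError("route too short for the requested plan")
        category = CATEGORIES[b % len(CATEGORIES)]
        x0 = int(rng.integers(20, w - bw - 30))
        y0 = int(rng.integers(20, h - bh - 30))
        polys: dict[int, np.ndarray] = {}
        for j in range(k):
            quad = rect_quad(x0 + 6 * j, y0 + 2 * j, bw - 2 * j, bh - j)
            # small seeded corner perturbation: a mild perspective change
            quad = quad + rng.uniform(-1.5, 1.5, size=(4, 2))
            quad[:, 0] = np.clip(quad[:, 0], 0, w - 1)
            quad[:, 1] = np.clip(quad[:, 1], 0, h - 1)
            polys[frame + j] = quad
        plan.append(
            PlantedBillboard(
                billboard_id=f"bb_{b:03d}",
                category=category,
                visible_in=list(polys),
                pixel_polygon_per_frame=polys,
                texture_seed=1000 + b,
            )
        )
        frame += k + gap_frames
    return plan


def labelled_crop_set(
    n_per_category: int = 10,
    size: tuple[int, int] = (96, 128),
    seed: int = 0,
) -> tuple[list[np.ndarray], list[str]]:
    """Frontal billboard crops with labels, for classifier training/eval."""
    rng = np.random.default_rng(seed)
    crops, labels = [], []
    for category in CATEGORIES:
        for i in range(n_per_category):
            tex = billboard_texture(category, texture_seed=int(rng.integers(1 << 30)), size=size)
            noise = rng.normal(0.0, 5.0, tex.shape)
            crops.append(np.clip(tex.astype(float) + noise, 0, 255).astype(np.uint8))
            labels.append(category)
    return crops, labels
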