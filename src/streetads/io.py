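"""Readers and writers for the pipeline's on-disk formats.

Images and crops are RGB PNG; label maps are single-channel PNG with a
JSON sidecar palette; manifests are UTF-8 comma-separated CSV with header
rows; zones and joined advert points are RFC 7946 GeoJSON. Pixel polygons
in manifests are WKT in pixel coordinates (0-based, x right, y down).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from shapely import wkt as shapely_wkt
from shapely.geometry import Polygon as ShapelyPolygon, mapping, shape

from .core import AdInstance, LabelMap, PALETTE, StreetImage
from .zones import Zone

SCHEMA_VERSION = "1"


# --- images and label maps -------------------------------------------------

def write_image(path, pixels: np.ndarray) -> None:
    Image.fromarray(np.asarray(pixels, dtype=np.uint8)).save(path, format="PNG")


def read_image(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def write_label_map(path, label_map: LabelMap) -> None:
    Image.fromarray(label_map.grid.astype(np.uint8), mode="L").save(path, format="PNG")


def read_label_map(path, image_id: str) -> LabelMap:
    grid = np.asarray(Image.open(path).convert("L"))
    return LabelMap(image_id=image_id, grid=grid)


def write_palette(path) -> None:
    with open(path, "w") as fh:
        json.dump({"background": 0, **{name: i for i, name in PALETTE.items()}}, fh, indent=2)


# --- manifests -------------------------------------------------------------

def route_manifest(images: dict[str, StreetImage], image_dir: str = "images") -> pd.DataFrame:
    rows = [
        (im.image_id, f"{image_dir}/{im.image_id}.png", im.timestamp, im.lon, im.lat)
        for im in sorted(images.values(), key=lambda i: i.image_id)
    ]
    return pd.DataFrame(rows, columns=["frame_id", "path", "timestamp_iso8601", "lon", "lat"])


def billboard_manifest(truth_manifest) -> pd.DataFrame:
    rows = []
    for pb in truth_manifest:
        for f in sorted(pb.visible_in):
            quad = pb.pixel_polygon_per_frame[f]
            rows.append(
                (pb.billboard_id, pb.category, f"frame_{f:05d}", ShapelyPolygon(quad).wkt)
            )
    return pd.DataFrame(rows, columns=["billboard_id", "category", "frame_id", "polygon_wkt_pixels"])


def ad_manifest(instances: list[AdInstance], crop_dir: str = "crops") -> pd.DataFrame:
    rows = [
        (
            a.instance_id,
            a.image_id,
            a.lon,
            a.lat,
            a.filled_area_px,
            ShapelyPolygon(a.hull).wkt,
            f"{crop_dir}/{a.instance_id}.png",
            a.category or "",
        )
        for a in instances
    ]
    return pd.DataFrame(
        rows,
        columns=["ad_id", "image_id", "lon", "lat", "filled_area_px", "hull_wkt_pixels", "crop_path", "category"],
    )


def dedup_report(group_of: dict[str, int], retained_ids: set[str]) -> pd.DataFrame:
    sizes: dict[int, int] = {}
    for g in group_of.values():
        sizes[g] = sizes.get(g, 0) + 1
    rows = [
        (ad_id, g, int(ad_id in retained_ids), sizes[g]) for ad_id, g in sorted(group_of.items())
    ]
    return pd.DataFrame(rows, columns=["ad_id", "duplicate_group", "representative", "component_size"])


def write_csv(df: pd.DataFrame, path) -> None:
    df = df.copy()
    df.attrs["schema_version"] = SCHEMA_VERSION
    df.to_csv(path, index=False)


# --- GeoJSON ---------------------------------------------------------------

def write_zones_geojson(zones: list[Zone], path) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": mapping(z.polygon),
            "properties": {
                "zone_id": z.zone_id,
                "imd_decile": z.imd_decile,
                "oac_supergroup": z.oac_supergroup,
                "oac_group": z.oac_group,
            },
        }
        for z in zones
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_zones_geojson(path) -> list[Zone]:
    with open(path) as fh:
        data = json.load(fh)
    zones = []
    for feat in data["features"]:
        props = feat["properties"]
        zones.append(
            Zone(
                zone_id=int(props["zone_id"]),
                polygon=shape(feat["geometry"]),
                imd_decile=int(props["imd_decile"]),
                oac_supergroup=int(props["oac_supergroup"]),
                oac_group=str(props["oac_group"]),
            )
        )
    return zones


def write_ad_points_geojson(instances: list[AdInstance], zone_of: dict[str, object], path) -> None:
    """Advert points with their joined zone id as a GeoJSON point layer."""
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [a.lon, a.lat]},
            "properties": {
                "ad_id": a.instance_id,
                "category": a.category,
                "zone_id": zone_of.get(a.instance_id),
            },
        }
        for a in instances
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


# --- bundles ---------------------------------------------------------------

def write_bundle(bundle, out_dir) -> None:
    """Write a synthetic fixture bundle in the pipeline's input formats."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "labels").mkdir(parents=True, exist_ok=True)
    for im in bundle.images.values():
        write_image(out / "images" / f"{im.image_id}.png", im.pixels)
    for lm in bundle.label_maps.values():
        write_label_map(out / "labels" / f"{lm.image_id}.png", lm)
    write_palette(out / "palette.json")
    write_csv(route_manifest(bundle.images), out / "route.csv")
    write_csv(billboard_manifest(bundle.truth_manifest), out / "billboards.csv")
    if bundle.zones:
        write_zones_geojson(bundle.zones, out / "zones.geojson")


def read_bundle_inputs(in_dir) -> tuple[dict[str, StreetImage], dict[str, LabelMap], list[Zone] | None]:
    """Read images, label maps and (optionally) zones written by write_bundle."""
    root = Path(in_dir)
    route = pd.read_csv(root / "route.csv")
    images: dict[str, StreetImage] = {}
    label_maps: dict[str, LabelMap] = {}
    for _, row in route.iterrows():
        fid = row["frame_id"]
        images[fid] = StreetImage(
            image_id=fid,
            pixels=read_image(root / "images" / f"{fid}.png"),
            lon=float(row["lon"]),
            lat=float(row["lat"]),
            timestamp=str(row["timestamp_iso8601"]),
        )
        lpath = root / "labels" / f"{fid}.png"
        if lpath.exists():
            label_maps[fid] = read_label_map(lpath, fid)
    zones = None
    zpath = root / "zones.geojson"
    if zpath.exists():
        zones = read_zones_geojson(zpath)
    return images, label_maps, zones


def read_truth_manifest(path):
    """Planted-billboard records from a billboards.csv manifest."""
    from .synthetic import PlantedBillboard

    df = pd.read_csv(path)
    out = []
    for bid, sub in df.groupby("billboard_id", sort=True):
        polys = {}
        for _, row in sub.iterrows():
            frame = int(str(row["frame_id"]).split("_")[1])
            quad = np.asarray(shapely_wkt.loads(row["polygon_wkt_pixels"]).exterior.coords[:-1])
            polys[frame] = quad
        out.append(
            PlantedBillboard(
                billboard_id=str(bid),
                category=str(sub["category"].iloc[0]),
                visible_in=sorted(polys),
                pixel_polygon_per_frame=polys,
            )
        )
    return out
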