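"""Segmentation backend contract and billboard-category evaluation.

The heavy panoptic segmentation network that produces label maps is
deliberately outside this package: any backend satisfying
:class:`SegmentationBackend` can plug in. Two backends ship here — an
oracle that returns a fixture's ground-truth maps (for end-to-end testing)
and an adapter that reads label-map PNGs produced externally.

Evaluation follows the usual audit of a detector feeding an analysis
pipeline: pixel intersection-over-union for the billboard category, with an
optional minimum-pixel threshold excluding images whose ground truth
carries fewer billboard pixels, plus a detected / falsely-detected / missed
count over instances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Protocol, runtime_checkable

import numpy as np
from shapely.geometry import Polygon as ShapelyPolygon

from .core import AD_IDS, AdInstance, LabelMap, StreetImage


class UndefinedResultError(ValueError):
    """Raised when a metric has no defined value (e.g. empty considered set)."""


@runtime_checkable
class SegmentationBackend(Protocol):
    name: str

    def segment(self, image: StreetImage) -> LabelMap: ...


class OracleBackend:
    """Returns the fixture's ground-truth label map for each image."""

    name = "oracle"

    def __init__(self, truth: dict[str, LabelMap]):
        self._truth = truth

    def segment(self, image: StreetImage) -> LabelMap:
        try:
            return self._truth[image.image_id]
        except KeyError:
            raise KeyError(f"oracle has no label map for image {image.image_id!r}") from None


class PNGAdapterBackend:
    """Reads externally produced single-channel label-map PNGs from a directory."""

    name = "png-adapter"

    def __init__(self, directory):
        from pathlib import Path

        self.directory = Path(directory)

    def segment(self, image: StreetImage) -> LabelMap:
        from .io import read_label_map

        path = self.directory / f"{image.image_id}.png"
        if not path.exists():
            raise FileNotFoundError(f"no label map PNG for {image.image_id} at {path}")
        return read_label_map(path, image.image_id)


def _cat_mask(lm: LabelMap, category_id) -> np.ndarray:
    ids = {category_id} if np.isscalar(category_id) else set(category_id)
    return np.isin(lm.grid, sorted(ids))


def miou(
    pred: dict[str, LabelMap],
    truth: dict[str, LabelMap],
    category_id=None,
    min_pixels: int = 0,
    average: str = "micro",
) -> float:
    """Intersection-over-union for one category across aligned label maps.

    Images whose *truth* category pixel count is below ``min_pixels`` are
    excluded when ``min_pixels > 0``. ``average='micro'`` pools pixels over
    the considered images (single per-category value); ``'macro'`` averages
    per-image IoUs, skipping images where the union is empty.

    Raises :class:`UndefinedResultError` when no image is considered or the
    pooled union is empty.
    """
    if category_id is None:
        category_id = AD_IDS
    if average not in ("micro", "macro"):
        raise ValueError(f"unknown average {average!r}")
    missing = set(truth) - set(pred)
    if missing:
        raise ValueError(f"predictions missing for images: {sorted(missing)[:5]}")

    inter = union = 0
    per_image = []
    considered = 0
    for image_id, t in truth.items():
        p = pred[image_id]
        if p.shape != t.shape:
            raise ValueError(f"{image_id}: pred {p.shape} vs truth {t.shape} dimension mismatch")
        tm = _cat_mask(t, category_id)
        if min_pixels > 0 and tm.sum() < min_pixels:
            continue
        considered += 1
        pm = _cat_mask(p, category_id)
        i = int((tm & pm).sum())
        u = int((tm | pm).sum())
        inter += i
        union += u
        if u > 0:
            per_image.append(i / u)
    if considered == 0:
        raise UndefinedResultError("no image meets the min_pixels threshold")
    if average == "micro":
        if union == 0:
            raise UndefinedResultError("category absent from both prediction and truth")
        return inter / union
    if not per_image:
        raise UndefinedResultError("category absent from every considered image")
    return float(np.mean(per_image))


@dataclass(frozen=True)
class TruthPolygon:
    """Ground-truth billboard footprint in one frame, in pixel coordinates."""

    truth_id: str
    image_id: str
    polygon: ShapelyPolygon
    area_px: int


@dataclass(frozen=True)
class DetectionAudit:
    n_truth: int
    n_detected: int
    n_false: int

    @property
    def n_missed(self) -> int:
        return self.n_truth - self.n_detected

    def as_dict(self) -> dict[str, int]:
        return {
            "n_truth": self.n_truth,
            "n_detected": self.n_detected,
            "n_false": self.n_false,
            "n_missed": self.n_missed,
        }


def _hull_polygon(inst: AdInstance) -> ShapelyPolygon:
    # buffer(0.5) restores the half-pixel border lost by taking pixel centres
    return ShapelyPolygon(inst.hull).buffer(0.5, join_style="mitre")


def detection_audit(
    extracted: Iterable[AdInstance],
    truth: Iterable[TruthPolygon],
    iou_match_threshold: float = 0.5,
) -> DetectionAudit:
    """Greedy one-to-one matching of extractions to ground-truth billboards.

    Candidate pairs (same image) are ranked by descending polygon IoU, ties
    broken by lower instance id then lower truth id; pairs at or above the
    threshold count as detected. Unmatched extractions are false positives;
    unmatched truths are misses.
    """
    if iou_match_threshold < 0:
        raise ValueError("iou_match_threshold must be non-negative")
    extracted = sorted(extracted, key=lambda e: e.instance_id)
    truth = sorted(truth, key=lambda t: (t.truth_id, t.image_id))
    pairs = []
    for e in extracted:
        ep = _hull_polygon(e)
        for t in truth:
            if t.image_id != e.image_id:
                continue
            u = ep.union(t.polygon).area
            if u == 0:
                continue
            iou = ep.intersection(t.polygon).area / u
            if iou >= iou_match_threshold:
                pairs.append((-iou, e.instance_id, t.truth_id, t.image_id))
    pairs.sort()
    matched_e: set[str] = set()
    matched_t: set[tuple[str, str]] = set()
    for _, eid, tid, img in pairs:
        if eid in matched_e or (tid, img) in matched_t:
            continue
        matched_e.add(eid)
        matched_t.add((tid, img))
    n_truth = len(truth)
    n_detected = len(matched_t)
    return DetectionAudit(n_truth=n_truth, n_detected=n_detected, n_false=len(extracted) - len(matched_e))


def truth_polygons(bundle, min_area: int = 2000) -> list[TruthPolygon]:
    """Per-frame truth footprints from a fixture manifest, area-filtered.

    The area is the rasterised pixel count of the planted quad, matching the
    extraction filter's semantics; footprints under ``min_area`` pixels are
    excluded from the audit's ground truth.
    """
    from skimage.draw import polygon as draw_polygon

    out = []
    for pb in bundle.truth_manifest:
        for f, quad in pb.pixel_polygon_per_frame.items():
            image_id = bundle.frame_id(f)
            shape = bundle.label_maps[image_id].shape
            rr, _ = draw_polygon(quad[:, 1], quad[:, 0], shape=shape)
            area = len(rr)
            if area < min_area:
                continue
            # +0.5 pixel buffer: quad corners are inclusive pixel indices
            poly = ShapelyPolygon(quad).buffer(0.5, join_style="mitre")
            out.append(TruthPolygon(truth_id=pb.billboard_id, image_id=image_id, polygon=poly, area_px=area))
    return out
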