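"""End-to-end orchestration: segment, extract, dedup, rectify, classify, analyze.

The pipeline is a thin composition of the stage modules with reproducible
configuration: every run records per-stage counts and a hash of the
effective configuration, and identical configs and seeds give identical
outputs. Stages degrade gracefully — a missing zones layer skips the
analysis stage with a logged reason but keeps earlier outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import classify as _classify
from . import dedup as _dedup
from . import exposure as _exposure
from . import extraction as _extraction
from . import io as _io
from . import rectify as _rectify
from .core import AdInstance, LabelMap, StreetImage
from .segmentation import OracleBackend, PNGAdapterBackend, SegmentationBackend
from .zones import Zone

log = logging.getLogger("streetads")


@dataclass
class PipelineConfig:
    """Reproducible knob set; defaults are the workflow's operating point."""

    min_area_px: int = 2000
    tau: float = 60
    d_metres: float = 10.0
    connectivity: int = 8
    crop_size: int = 224
    ratio_test: float = 0.75
    iou_match_threshold: float = 0.5
    seed: int = 0
    matcher: str = "sift"  # or "oracle" (exact-texture test matcher)
    input_dir: str | None = None
    output_dir: str | None = None
    train_dir: str | None = None

    def __post_init__(self) -> None:
        for name in ("min_area_px", "tau", "d_metres", "crop_size", "ratio_test", "iou_match_threshold"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunResult:
    config: PipelineConfig
    instances: list[AdInstance]
    retained: list[AdInstance]
    group_of: dict[str, int]
    rectified: dict[str, np.ndarray]
    report: object | None  # inequality report DataFrame, or None if skipped
    summary: dict = field(default_factory=dict)


def _make_matcher(config: PipelineConfig) -> _dedup.FeatureMatcherContract:
    if config.matcher == "sift":
        return _dedup.SIFTMatcher(ratio=config.ratio_test)
    if config.matcher == "oracle":
        return _dedup.ExactTextureMatcher()
    raise ValueError(f"unknown matcher {config.matcher!r}")


def run_pipeline(
    images: dict[str, StreetImage],
    backend: SegmentationBackend,
    config: PipelineConfig | None = None,
    classifier: _classify.ClassifierContract | None = None,
    train_set: _classify.LabelledCropSet | None = None,
    train_config: _classify.TrainConfig | None = None,
    zones: list[Zone] | None = None,
    out_dir: str | None = None,
) -> RunResult:
    """Run every stage over the given frames.

    ``backend`` supplies label maps (the oracle backend replays fixture
    ground truth; the PNG adapter reads an external network's maps). The
    classifier is fitted on ``train_set`` when provided unfitted. When
    ``zones`` is None the analysis stage is skipped with a logged reason.
    Outputs (manifests, reports, summary JSON) are written when ``out_dir``
    is given.
    """
    config = config or PipelineConfig()
    summary: dict = {"config_hash": config.config_hash(), "stages": {}}

    log.info("segment: %d frames via backend %s", len(images), backend.name)
    label_maps: dict[str, LabelMap] = {i: backend.segment(im) for i, im in sorted(images.items())}
    summary["stages"]["segment"] = {"n_frames": len(label_maps)}

    instances = _extraction.extract_all(
        label_maps, images, min_area=config.min_area_px, connectivity=config.connectivity
    )
    log.info("extract: %d instances of >= %d px", len(instances), config.min_area_px)
    summary["stages"]["extract"] = {"n_instances": len(instances)}

    result = _dedup.deduplicate(instances, _make_matcher(config), config.d_metres, config.tau)
    log.info("dedup: %d instances -> %d representatives", len(instances), len(result.retained))
    summary["stages"]["dedup"] = {
        "n_in": len(instances),
        "n_retained": len(result.retained),
        "n_groups": len(set(result.group_of.values())),
    }

    rectifier = _rectify.HomographyRectifier(out_size=(config.crop_size, config.crop_size))
    rectified = {a.instance_id: _rectify.rectify_instance(a, rectifier) for a in result.retained}
    summary["stages"]["rectify"] = {"n_rectified": len(rectified), "out_size": config.crop_size}

    if classifier is None:
        classifier = _classify.DeskClassifier()
    if train_set is not None:
        classifier.fit(train_set, train_config or _classify.TrainConfig(seed=config.seed))
    n_classified = 0
    for a in result.retained:
        a.category, _ = classifier.predict(rectified[a.instance_id])
        n_classified += 1
    log.info("classify: %d representatives labelled", n_classified)
    counts: dict[str, int] = {}
    for a in result.retained:
        counts[a.category] = counts.get(a.category, 0) + 1
    summary["stages"]["classify"] = {"n_classified": n_classified, "category_counts": counts}

    report = None
    if zones:
        report = _exposure.inequality_report(list(images.values()), result.retained, zones)
        summary["stages"]["analyze"] = {"n_tests": int(len(report))}
    else:
        log.info("analyze: skipped — no zones provided")
        summary["stages"]["analyze"] = {"skipped": "no zones provided"}

    run = RunResult(
        config=config,
        instances=instances,
        retained=result.retained,
        group_of=result.group_of,
        rectified=rectified,
        report=report,
        summary=summary,
    )
    if out_dir is not None:
        _write_outputs(run, zones, Path(out_dir))
    return run


def _write_outputs(run: RunResult, zones: list[Zone] | None, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    crops = out / "crops"
    crops.mkdir(exist_ok=True)
    for a in run.retained:
        _io.write_image(crops / f"{a.instance_id}.png", run.rectified[a.instance_id])
    _io.write_csv(_io.ad_manifest(run.instances), out / "ads.csv")
    retained_ids = {a.instance_id for a in run.retained}
    _io.write_csv(_io.dedup_report(run.group_of, retained_ids), out / "dedup.csv")
    _io.write_csv(_io.ad_manifest(run.retained), out / "representatives.csv")
    if run.report is not None:
        _io.write_csv(run.report, out / "inequality_report.csv")
        if zones:
            zone_of = {
                a.instance_id: _exposure.assign_zone(a.lon, a.lat, zones) for a in run.retained
            }
            _io.write_ad_points_geojson(run.retained, zone_of, out / "ad_points.geojson")
    with open(out / "run_summary.json", "w") as fh:
        json.dump(run.summary, fh, indent=2, sort_keys=True)


def run_from_directory(config: PipelineConfig) -> RunResult:
    """Disk-based entry point: read a bundle directory, run, write outputs."""
    if not config.input_dir:
        raise ValueError("config.input_dir is required")
    images, label_maps, zones = _io.read_bundle_inputs(config.input_dir)
    backend: SegmentationBackend
    if label_maps and len(label_maps) == len(images):
        backend = OracleBackend(label_maps)
    else:
        backend = PNGAdapterBackend(Path(config.input_dir) / "labels")
    train_set = None
    if config.train_dir:
        train_set = load_training_directory(config.train_dir)
    else:
        from .synthetic import labelled_crop_set

        crops, labels = labelled_crop_set(seed=config.seed)
        train_set = _classify.LabelledCropSet(crops, labels)
    return run_pipeline(
        images, backend, config=config, train_set=train_set, zones=zones, out_dir=config.output_dir
    )


def load_training_directory(train_dir) -> _classify.LabelledCropSet:
    """Directory-per-category PNG layout -> labelled crop set."""
    root = Path(train_dir)
    crops, labels = [], []
    for cat_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        for png in sorted(cat_dir.glob("*.png")):
            crops.append(_io.read_image(png))
            labels.append(cat_dir.name)
    if not crops:
        raise ValueError(f"no training crops under {train_dir}")
    return _classify.LabelledCropSet(crops, labels)
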