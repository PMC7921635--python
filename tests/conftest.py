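"""Shared fixtures: synthetic survey bundles generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from streetads.classify import DeskClassifier, LabelledCropSet, TrainConfig
from streetads.extraction import extract_all
from streetads.synthetic import (
    RouteSpec,
    generate_route,
    labelled_crop_set,
    plant_billboards,
    standard_plan,
)

#: seed for every deterministic fixture in the suite
SEED = 1


@pytest.fixture(scope="session")
def survey_bundle():
    """12 distinct billboards, each observed in 2-4 consecutive frames."""
    route = generate_route(RouteSpec(n_frames=88, seed=SEED))
    plan = standard_plan(route, n_billboards=12, seed=SEED)
    return plant_billboards(route, plan, seed=SEED)


@pytest.fixture(scope="session")
def survey_instances(survey_bundle):
    return extract_all(survey_bundle.label_maps, survey_bundle.images)


@pytest.fixture(scope="session")
def billboard_of(survey_bundle):
    """image_id -> planted billboard for the survey bundle (one per frame)."""
    return {
        f"frame_{f:05d}": pb
        for pb in survey_bundle.truth_manifest
        for f in pb.visible_in
    }


@pytest.fixture(scope="session")
def quick_classifier():
    """Desk classifier trained with a light schedule on the 40-crop set."""
    crops, labels = labelled_crop_set(n_per_category=10, seed=SEED)
    clf = DeskClassifier()
    clf.fit(
        LabelledCropSet(crops, labels),
        TrainConfig(epochs=1, steps_per_epoch=20, batch_size=16, seed=SEED),
    )
    return clf


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)
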