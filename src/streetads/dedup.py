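"""Duplicate suppression for re-observed advertisements.

Frames captured every 0.5 s re-record the same physical billboard many
times, biasing any downstream exposure count. The suppression algorithm:

1. candidate pairs — instances whose capture points lie within ``d`` metres
   (geodesic; at d = 10 m indistinguishable from planar Euclidean);
2. feature matching — count keypoint matches between the two crops;
3. graph — add an edge when the match count strictly exceeds ``tau``;
4. each connected component is one physical advertisement; keep only the
   member closest to the component's coordinate centroid.

Defaults ``d = 10`` m and ``tau = 60``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Protocol, runtime_checkable

import networkx as nx
import numpy as np
from skimage.color import rgb2gray
from skimage.feature import SIFT, match_descriptors
from skimage.transform import resize

from .core import AdInstance
from .geo import haversine_m, pairwise_distances_m

DEFAULT_D_METRES = 10.0
DEFAULT_TAU = 60
DEFAULT_RATIO = 0.75


@runtime_checkable
class FeatureMatcherContract(Protocol):
    """Symmetric, deterministic count of matching features between crops."""

    def match_count(self, a: np.ndarray, b: np.ndarray) -> int: ...


class SIFTMatcher:
    """Scale-invariant keypoint matcher with Lowe's ratio test.

    Descriptors are extracted once per crop (cached by object identity) and
    matched nearest-neighbour with cross-checking and a max-ratio test.
    """

    def __init__(self, ratio: float = DEFAULT_RATIO, upsampling: int = 2):
        if not 0 < ratio <= 1:
            raise ValueError("ratio must be in (0, 1]")
        self.ratio = ratio
        self.upsampling = upsampling
        self._cache: dict[int, np.ndarray | None] = {}
        self._keepalive: list[np.ndarray] = []

    def _descriptors(self, img: np.ndarray) -> np.ndarray | None:
        key = id(img)
        if key not in self._cache:
            gray = rgb2gray(img) if img.ndim == 3 else img.astype(float)
            sift = SIFT(upsampling=self.upsampling)
            try:
                sift.detect_and_extract(gray)
                desc = sift.descriptors
            except RuntimeError:  # no keypoints found
                desc = None
            self._cache[key] = desc
            self._keepalive.append(img)
        return self._cache[key]

    def match_count(self, a: np.ndarray, b: np.ndarray) -> int:
        da, db = self._descriptors(a), self._descriptors(b)
        if da is None or db is None or len(da) == 0 or len(db) == 0:
            return 0
        # the ratio test is direction-dependent; canonicalise the order by a
        # content digest so the count is symmetric in its arguments
        if a.tobytes() > b.tobytes():
            da, db = db, da
        matches = match_descriptors(da, db, cross_check=True, max_ratio=self.ratio)
        return int(len(matches))


class ExactTextureMatcher:
    """Test oracle: a large fixed count for near-identical textures, else 0.

    Crops are resized to a small common grid and compared by Pearson
    correlation; crops of the same rendered texture correlate near 1 while
    distinct procedural textures do not. Deterministic and symmetric.
    """

    MATCH = 1000

    def __init__(self, threshold: float = 0.8, grid: int = 32):
        self.threshold = threshold
        self.grid = grid

    def _signature(self, img: np.ndarray) -> np.ndarray:
        small = resize(img.astype(float), (self.grid, self.grid), anti_aliasing=True)
        v = small.ravel()
        v = v - v.mean()
        n = np.linalg.norm(v)
        return v / n if n > 0 else v

    def match_count(self, a: np.ndarray, b: np.ndarray) -> int:
        corr = float(self._signature(a) @ self._signature(b))
        return self.MATCH if corr >= self.threshold else 0


@dataclass
class MatchGraph:
    """Similarity graph over instances; components are physical adverts."""

    graph: nx.Graph
    d_metres: float
    tau: float

    def components(self) -> list[list[str]]:
        comps = [sorted(c) for c in nx.connected_components(self.graph)]
        return sorted(comps, key=lambda c: c[0])


@dataclass
class DedupResult:
    retained: list[AdInstance]
    group_of: dict[str, int] = field(default_factory=dict)  # instance id -> component index
    graph: MatchGraph | None = None


def candidate_pairs(instances: list[AdInstance], d_metres: float = DEFAULT_D_METRES) -> set[tuple[str, str]]:
    """Unordered id pairs whose capture points are within d metres (inclusive)."""
    if d_metres < 0:
        raise ValueError("d_metres must be non-negative")
    if len(instances) < 2:
        return set()
    lons = np.array([i.lon for i in instances])
    lats = np.array([i.lat for i in instances])
    dist = pairwise_distances_m(lons, lats)
    ids = [i.instance_id for i in instances]
    out = set()
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            if dist[a, b] <= d_metres:
                out.add(tuple(sorted((ids[a], ids[b]))))
    return out


def build_graph(
    instances: list[AdInstance],
    matcher: FeatureMatcherContract,
    d_metres: float = DEFAULT_D_METRES,
    tau: float = DEFAULT_TAU,
) -> MatchGraph:
    """Edges exactly where a candidate pair's match count strictly exceeds tau."""
    by_id = {i.instance_id: i for i in instances}
    if len(by_id) != len(instances):
        raise ValueError("duplicate instance ids")
    g = nx.Graph()
    g.add_nodes_from(sorted(by_id))
    for a, b in sorted(candidate_pairs(instances, d_metres)):
        count = matcher.match_count(by_id[a].crop, by_id[b].crop)
        if count > tau:
            g.add_edge(a, b, match_count=count)
    return MatchGraph(graph=g, d_metres=d_metres, tau=tau)


def select_representatives(
    graph: MatchGraph, instances: list[AdInstance]
) -> tuple[list[AdInstance], dict[str, int]]:
    """One retained instance per connected component.

    For multi-member components the member geodesically nearest the
    arithmetic centroid of member coordinates is kept (ties to the smallest
    instance id); singletons are kept as-is. Every instance gets a
    component label, so the labels partition the input.
    """
    by_id = {i.instance_id: i for i in instances}
    unknown = set(graph.graph.nodes) - set(by_id)
    if unknown:
        raise ValueError(f"graph nodes missing from instances: {sorted(unknown)[:5]}")
    retained = []
    group_of: dict[str, int] = {}
    for gi, comp in enumerate(graph.components()):
        members = [by_id[i] for i in comp]
        for m in members:
            group_of[m.instance_id] = gi
        if len(members) == 1:
            retained.append(members[0])
            continue
        c_lon = float(np.mean([m.lon for m in members]))
        c_lat = float(np.mean([m.lat for m in members]))
        # micrometre rounding so exact geometric ties resolve by id
        best = min(
            members,
            key=lambda m: (round(haversine_m(m.lon, m.lat, c_lon, c_lat), 6), m.instance_id),
        )
        retained.append(best)
    return retained, group_of


def deduplicate(
    instances: list[AdInstance],
    matcher: FeatureMatcherContract,
    d_metres: float = DEFAULT_D_METRES,
    tau: float = DEFAULT_TAU,
) -> DedupResult:
    """Full duplicate suppression; idempotent for a deterministic matcher."""
    if not instances:
        return DedupResult(retained=[], group_of={}, graph=None)
    graph = build_graph(instances, matcher, d_metres, tau)
    retained, group_of = select_representatives(graph, instances)
    return DedupResult(retained=retained, group_of=group_of, graph=graph)
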