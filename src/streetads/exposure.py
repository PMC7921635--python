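"""Exposure-inequality analysis of classified advertisements.

Survey frames and their deduplicated, classified advertisements are joined
to attribute-tagged zone polygons (deprivation decile; output-area
classification). For each group of zones the analysis reports how many
frames fall in the group and what percentage of them contain at least one
advertisement of each category — the exposure percentage — and tests
whether with/without-advert frame counts are independent of the grouping
with Pearson's chi-squared.

No multiple-testing correction is applied across categories or groupings;
the report notes this.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import Point

from .core import CATEGORIES
from .zones import Zone

UNASSIGNED = "UNASSIGNED"

GROUPINGS = ("decile", "oac_supergroup", "oac_group")


def _group_key(zone: Zone, grouping: str):
    if grouping == "decile":
        return zone.imd_decile
    if grouping == "oac_supergroup":
        return zone.oac_supergroup
    if grouping == "oac_group":
        return zone.oac_group
    raise ValueError(f"unknown grouping {grouping!r}; expected one of {GROUPINGS}")


def validate_zones(zones: list[Zone]) -> None:
    """Warn when zone interiors overlap (boundary sharing is expected)."""
    for i in range(len(zones)):
        for j in range(i + 1, len(zones)):
            inter = zones[i].polygon.intersection(zones[j].polygon)
            if inter.area > 1e-12 * max(zones[i].polygon.area, zones[j].polygon.area):
                warnings.warn(
                    f"zones {zones[i].zone_id} and {zones[j].zone_id} overlap", stacklevel=2
                )
                return


def assign_zone(lon: float, lat: float, zones: list[Zone]):
    """Zone id containing the point, or :data:`UNASSIGNED`.

    Boundary points go to the lowest zone id whose closed polygon covers
    them, making the assignment deterministic on shared edges.
    """
    pt = Point(lon, lat)
    for z in sorted(zones, key=lambda z: z.zone_id):
        if z.polygon.covers(pt):
            return z.zone_id
    return UNASSIGNED


@dataclass
class ExposureTable:
    """Per-group frame counts and exposure percentages.

    ``table`` has one row per group with columns ``group, n_images`` and,
    per category, ``n_with_<cat>`` and ``pct_<cat>`` (0..100, rounded to 2
    decimals for reporting). ``n_unassigned`` counts frames outside every
    zone; they are excluded from the groups.
    """

    grouping: str
    table: pd.DataFrame
    n_unassigned: int


def _frames_df(images) -> pd.DataFrame:
    if isinstance(images, pd.DataFrame):
        df = images[["image_id", "lon", "lat"]].copy() if "image_id" in images else images.copy()
    else:
        df = pd.DataFrame(
            [(im.image_id, im.lon, im.lat) for im in images], columns=["image_id", "lon", "lat"]
        )
    if df["image_id"].duplicated().any():
        raise ValueError("duplicate image ids")
    return df


def exposure_table(images, ads, zones: list[Zone], grouping: str = "decile") -> ExposureTable:
    """Join frames to zones and count per-group category exposure.

    ``images`` is an iterable of frames (or a DataFrame with image_id, lon,
    lat); ``ads`` an iterable of classified instances referencing those
    frames. A frame counts as exposed to a category when at least one of
    its advertisements carries that category.
    """
    if grouping not in GROUPINGS:
        raise ValueError(f"unknown grouping {grouping!r}; expected one of {GROUPINGS}")
    frames = _frames_df(images)
    known = set(frames["image_id"])
    zone_by_id = {z.zone_id: z for z in zones}
    cats_in_frame: dict[str, set[str]] = {}
    for ad in ads:
        if ad.image_id not in known:
            raise ValueError(f"ad {ad.instance_id} references unknown image {ad.image_id}")
        if ad.category is None:
            raise ValueError(f"ad {ad.instance_id} has no category")
        cats_in_frame.setdefault(ad.image_id, set()).add(ad.category)

    rows = []
    n_unassigned = 0
    for _, fr in frames.iterrows():
        zid = assign_zone(fr["lon"], fr["lat"], zones)
        if zid == UNASSIGNED:
            n_unassigned += 1
            continue
        rows.append((_group_key(zone_by_id[zid], grouping), fr["image_id"]))
    assigned = pd.DataFrame(rows, columns=["group", "image_id"])

    records = []
    for group, sub in assigned.groupby("group"):
        rec: dict = {"group": group, "n_images": len(sub)}
        for cat in CATEGORIES:
            n_with = int(sum(cat in cats_in_frame.get(i, ()) for i in sub["image_id"]))
            rec[f"n_with_{cat}"] = n_with
            rec[f"pct_{cat}"] = round(100.0 * n_with / len(sub), 2)
        records.append(rec)
    table = pd.DataFrame(records)
    if len(table):
        table = table.sort_values("group", key=lambda s: s.astype(str)).reset_index(drop=True)
    return ExposureTable(grouping=grouping, table=table, n_unassigned=n_unassigned)


def chi_squared(table) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence on an r x k count table.

    Returns ``(statistic, df, p_value)`` with expected counts from the
    row/column marginals and the p-value from the distribution's upper
    tail. Cells with expected count below 5 trigger a warning; a zero row
    or column marginal is rejected.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2:
        raise ValueError("contingency table must be 2-D")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    if (obs.sum(axis=0) <= 0).any() or (obs.sum(axis=1) <= 0).any():
        raise ValueError("zero row or column marginal")
    res = stats.chi2_contingency(obs, correction=False)
    if (res.expected_freq < 5).any():
        warnings.warn(
            f"{int((res.expected_freq < 5).sum())} cells have expected count < 5", stacklevel=2
        )
    return float(res.statistic), int(res.dof), float(res.pvalue)


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def inequality_report(images, ads, zones: list[Zone], groupings=("decile", "oac_group")) -> pd.DataFrame:
    """Exposure tables plus chi-squared tests per category and grouping.

    For each category the contingency is 2 x k: frames with vs without at
    least one advertisement of the category, across the groups. Groups and
    categories where the test is undefined (no exposed frame anywhere, or a
    single group) are reported with the reason instead of a statistic.
    """
    ads = list(ads)
    rows = []
    for grouping in groupings:
        et = exposure_table(images, ads, zones, grouping)
        for cat in CATEGORIES:
            base = {"grouping": grouping, "category": cat}
            if len(et.table) < 2:
                rows.append({**base, "chi2": np.nan, "df": 0, "p": np.nan,
                             "stars": "", "skipped": "fewer than two groups"})
                continue
            with_c = et.table[f"n_with_{cat}"].to_numpy()
            without_c = et.table["n_images"].to_numpy() - with_c
            if with_c.sum() == 0 or without_c.sum() == 0:
                rows.append({**base, "chi2": np.nan, "df": 0, "p": np.nan,
                             "stars": "", "skipped": "degenerate contingency (all-with or all-without)"})
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                stat, df, p = chi_squared(np.vstack([with_c, without_c]))
            rows.append({**base, "chi2": round(stat, 2), "df": df, "p": p,
                         "stars": significance_stars(p), "skipped": ""})
    return pd.DataFrame(rows)


def simulate_decile_pvalue(
    n_frames_per_decile,
    exposure_rates,
    seed: int = 0,
) -> float:
    """One synthetic with/without-by-decile test under known exposure rates.

    Draws, per decile, a binomial count of frames containing an
    advertisement and returns the chi-squared p-value — the building block
    for null-calibration and power checks of the inequality test.
    """
    n = np.asarray(n_frames_per_decile, dtype=int)
    p = np.asarray(exposure_rates, dtype=float)
    if n.shape != p.shape:
        raise ValueError("frame counts and rates must align")
    rng = np.random.default_rng(seed)
    with_c = rng.binomial(n, p)
    without_c = n - with_c
    _, _, pval = chi_squared(np.vstack([with_c, without_c]))
    return pval
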