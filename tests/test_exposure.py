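"""Zone joining, exposure percentages, chi-squared independence tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from shapely.geometry import Polygon

from streetads.core import AdInstance
from streetads.exposure import (
    UNASSIGNED,
    assign_zone,
    chi_squared,
    exposure_table,
    inequality_report,
    significance_stars,
    simulate_decile_pvalue,
)
from streetads.zones import Zone


def _zone(zid, x0, y0, x1, y1, decile=5, group="2a"):
    return Zone(
        zone_id=zid,
        polygon=Polygon([(x0, y0), (x1, y0), (x1, y1), (x0, y1)]),
        imd_decile=decile,
        oac_supergroup=int(group[0]),
        oac_group=group,
    )


def _frames(n, lon=0.5, lat=0.5):
    return pd.DataFrame(
        {"image_id": [f"f{i}" for i in range(n)], "lon": [lon] * n, "lat": [lat] * n}
    )


def _ad(aid, image_id, category, lon=0.5, lat=0.5):
    return AdInstance(
        instance_id=aid,
        image_id=image_id,
        hull=np.array([[0, 0], [9, 0], [9, 9], [0, 9]], float),
        filled_area_px=100,
        crop=np.zeros((4, 4, 3), np.uint8),
        lon=lon,
        lat=lat,
        category=category,
    )


class TestAssignZone:
    def test_zone_centre_assigned(self):
        zones = [_zone(1, 0, 0, 1, 1), _zone(2, 1, 0, 2, 1)]
        assert assign_zone(0.5, 0.5, zones) == 1
        assert assign_zone(1.5, 0.5, zones) == 2

    def test_outside_all_zones_unassigned(self):
        assert assign_zone(5.0, 5.0, [_zone(1, 0, 0, 1, 1)]) == UNASSIGNED

    def test_shared_edge_goes_to_lowest_zone_id(self):
        zones = [_zone(2, 1, 0, 2, 1), _zone(1, 0, 0, 1, 1)]
        assert assign_zone(1.0, 0.5, zones) == 1


class TestExposureTable:
    def test_worked_example_14_images_2_with_alcohol(self):
        # 2 of 14 frames in one zone contain an alcohol advert -> 14.29%
        zones = [_zone(1, 0, 0, 1, 1, group="8c")]
        ads = [_ad("a1", "f0", "alcohol"), _ad("a2", "f1", "alcohol")]
        et = exposure_table(_frames(14), ads, zones, grouping="oac_group")
        row = et.table.iloc[0]
        assert row["n_images"] == 14
        assert row["n_with_alcohol"] == 2
        assert row["pct_alcohol"] == 14.29

    def test_worked_example_6_images_1_with_food(self):
        zones = [_zone(1, 0, 0, 1, 1, group="4c")]
        et = exposure_table(_frames(6), [_ad("a1", "f0", "food")], zones, "oac_group")
        assert et.table.iloc[0]["pct_food"] == 16.67

    def test_no_ads_gives_zero_percentages(self):
        zones = [_zone(1, 0, 0, 1, 1)]
        et = exposure_table(_frames(9), [], zones, "decile")
        row = et.table.iloc[0]
        assert all(row[f"pct_{c}"] == 0.0 for c in ("food", "alcohol", "gambling", "other"))

    def test_group_marginals_and_unassigned_accounting(self):
        zones = [_zone(1, 0, 0, 1, 1, decile=1), _zone(2, 1, 0, 2, 1, decile=9)]
        frames = pd.DataFrame(
            {
                "image_id": ["a", "b", "c", "d"],
                "lon": [0.5, 0.5, 1.5, 9.0],
                "lat": [0.5, 0.5, 0.5, 9.0],
            }
        )
        et = exposure_table(frames, [], zones, "decile")
        assert et.table["n_images"].sum() == 3
        assert et.n_unassigned == 1

    def test_pct_recomputable_from_counts(self):
        zones = [_zone(1, 0, 0, 1, 1)]
        ads = [_ad("x", "f0", "food"), _ad("y", "f3", "food"), _ad("z", "f3", "other")]
        et = exposure_table(_frames(7), ads, zones, "decile")
        row = et.table.iloc[0]
        for c in ("food", "alcohol", "gambling", "other"):
            assert row[f"pct_{c}"] == round(100.0 * row[f"n_with_{c}"] / row["n_images"], 2)

    def test_unknown_grouping_rejected(self):
        with pytest.raises(ValueError, match="grouping"):
            exposure_table(_frames(1), [], [_zone(1, 0, 0, 1, 1)], "postcode")

    def test_uncategorised_ad_rejected(self):
        with pytest.raises(ValueError, match="category"):
            exposure_table(_frames(2), [_ad("a", "f0", None)], [_zone(1, 0, 0, 1, 1)], "decile")


def _brute_chi2(table: np.ndarray) -> tuple[float, int]:
    """Independent textbook implementation of Pearson's statistic."""
    table = np.asarray(table, float)
    total = table.sum()
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    stat = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            e = rows[i] * cols[j] / total
            stat += (table[i, j] - e) ** 2 / e
    return stat, (table.shape[0] - 1) * (table.shape[1] - 1)


class TestChiSquared:
    def test_textbook_2x2_case(self):
        stat, df, p = chi_squared([[10, 20], [20, 10]])
        assert stat == pytest.approx(20 / 3, abs=1e-9)  # 6.667 by hand
        assert df == 1
        assert p == pytest.approx(stats.chi2.sf(20 / 3, 1))

    def test_proportional_rows_give_exact_zero(self):
        stat, _, p = chi_squared([[3, 6, 9], [6, 12, 18]])
        assert stat == 0.0
        assert p == 1.0

    def test_equal_columns_2x10(self):
        stat, df, _ = chi_squared(np.tile([[4], [7]], (1, 10)))
        assert stat == 0.0
        assert df == 9

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_squared([[0, 0], [1, 2]])

    def test_low_expected_counts_warn(self):
        with pytest.warns(UserWarning, match="expected count"):
            chi_squared([[1, 2], [2, 1]])

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        st.integers(2, 4),
        st.integers(2, 6),
        st.integers(0, 2**31 - 1),
    )
    def test_agrees_with_brute_force_oracle(self, r, k, seed):
        rng = np.random.default_rng(seed)
        table = rng.integers(1, 50, size=(r, k))
        stat, df, _ = chi_squared(table)
        b_stat, b_df = _brute_chi2(table)
        assert df == b_df
        assert stat == pytest.approx(b_stat, rel=1e-9)


class TestStars:
    @pytest.mark.parametrize(
        "p,expected", [(0.2, ""), (0.04, "*"), (0.004, "**"), (0.0004, "***")]
    )
    def test_thresholds(self, p, expected):
        assert significance_stars(p) == expected


class TestInequalityReport:
    def test_empty_ad_set_reports_skips_with_reason(self):
        zones = [_zone(1, 0, 0, 1, 1, decile=1), _zone(2, 1, 0, 2, 1, decile=8)]
        frames = pd.DataFrame(
            {"image_id": ["a", "b"], "lon": [0.5, 1.5], "lat": [0.5, 0.5]}
        )
        rep = inequality_report(frames, [], zones, groupings=("decile",))
        assert (rep["skipped"] != "").all()
        assert rep["chi2"].isna().all()

    def test_imbalanced_rates_flagged_significant(self):
        zones = [
            _zone(1, 0, 0, 1, 1, decile=1, group="2a"),
            _zone(2, 1, 0, 2, 1, decile=9, group="8c"),
        ]
        rng = np.random.default_rng(0)
        rows, ads = [], []
        for i in range(400):
            lon = 0.5 if i < 200 else 1.5
            rows.append((f"f{i}", lon, 0.5))
            rate = 0.45 if i < 200 else 0.05
            if rng.random() < rate:
                ads.append(_ad(f"ad{i}", f"f{i}", "food", lon=lon))
        frames = pd.DataFrame(rows, columns=["image_id", "lon", "lat"])
        rep = inequality_report(frames, ads, zones, groupings=("decile",))
        food = rep[rep["category"] == "food"].iloc[0]
        assert food["stars"] == "***"

    def test_null_simulation_rarely_rejects(self):
        # equal planted rates across deciles: rejection should sit near alpha
        pvals = [
            simulate_decile_pvalue([50] * 10, [0.2] * 10, seed=s) for s in range(60)
        ]
        rate = np.mean([p < 0.05 for p in pvals])
        assert rate <= 0.15
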