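"""Attribute-tagged zone polygons.

Zones emulate the two English area-level datasets the exposure analysis
joins against: Lower Super Output Areas carrying a deprivation decile
(1 = most deprived) and Output Areas carrying the 2011 Output Area
Classification, with 8 Supergroups and 26 Groups.
"""

from __future__ import annotations

from dataclasses import dataclass

from shapely.geometry import Polygon

#: The 26 Output Area Classification group codes (8 supergroups).
OAC_GROUPS: tuple[str, ...] = (
    "1a", "1b", "1c",
    "2a", "2b", "2c", "2d",
    "3a", "3b", "3c", "3d",
    "4a", "4b", "4c",
    "5a", "5b",
    "6a", "6b",
    "7a", "7b", "7c", "7d",
    "8a", "8b", "8c", "8d",
)

OAC_SUPERGROUP_NAMES: dict[int, str] = {
    1: "rural residents",
    2: "cosmopolitans",
    3: "ethnicity central",
    4: "multicultural metropolitans",
    5: "urbanites",
    6: "suburbanites",
    7: "constrained city dwellers",
    8: "hard-pressed living",
}


@dataclass
class Zone:
    """One attribute-tagged polygon in WGS84 lon/lat."""

    zone_id: int
    polygon: Polygon
    imd_decile: int
    oac_supergroup: int
    oac_group: str

    def __post_init__(self) -> None:
        if not self.polygon.is_valid or self.polygon.area == 0:
            raise ValueError(f"zone {self.zone_id}: invalid polygon")
        if not 1 <= self.imd_decile <= 10:
            raise ValueError(f"zone {self.zone_id}: imd_decile must be 1..10")
        if self.oac_group not in OAC_GROUPS:
            raise ValueError(f"zone {self.zone_id}: unknown OAC group {self.oac_group!r}")
        if self.oac_supergroup != int(self.oac_group[0]):
            raise ValueError(f"zone {self.zone_id}: supergroup/group mismatch")
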