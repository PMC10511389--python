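"""Tissue-region sets: labelled partitions of the vessel-wall cross section.

Labels follow the histological differentiation of dissecting-aneurysm walls:
A1 intact elastin without thrombus attachment, A2 intact elastin with
thrombus attachment, A3 fragmented elastin, A4 thrombus with red blood
cells, A5 thrombus without red blood cells.  ``outer_excluded`` marks the
adventitia/surrounding tissue outside the analyzed wall, which never
contributes strain samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contours import Contour

REGION_LABELS = ("A1", "A2", "A3", "A4", "A5")
REGION_DESCRIPTIONS = {
    "A1": "elastin_no_thrombus",
    "A2": "elastin_with_thrombus",
    "A3": "fragmented_elastin",
    "A4": "thrombus_with_RBC",
    "A5": "thrombus_without_RBC",
    "outer_excluded": "adventitia_and_surroundings",
}
ELASTIN_LABELS = ("A1", "A2", "A3")


@dataclass
class TissueRegionSet:
    """Lumen and outer wall contours plus labelled region contours tiling the wall.

    ``sector_intervals`` optionally records the angular extent (theta_a,
    theta_b) of each region about ``center`` for cross sections whose regions
    are sector-like; the mesh generator requires it.
    """

    lumen: Contour
    outer: Contour
    regions: dict[str, Contour]
    center: np.ndarray = field(default_factory=lambda: np.zeros(2))
    sector_intervals: dict[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        for label in self.regions:
            if label not in REGION_DESCRIPTIONS:
                raise ValueError(f"unknown region label {label!r}")

    @property
    def labels(self) -> list[str]:
        return sorted(self.regions)

    def wall_area(self) -> float:
        return abs(self.outer.area) - abs(self.lumen.area)
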