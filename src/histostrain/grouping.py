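"""Isolation of strain values by mapped tissue-region contours.

After the finite-element mapping, each tissue region's deformed contour is
superimposed on the in vivo strain field and the strain values whose voxel
centres fall inside the contour are isolated and grouped per region.  The
``outer_excluded`` region and voxels outside every contour are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from matplotlib.path import Path

from .regions import TissueRegionSet
from .strain import StrainField


class GroupingError(ValueError):
    """Raised when the field and regions do not intersect (frame mismatch)."""


@dataclass
class RegionStrains:
    """Per-region strain samples with provenance."""

    samples: dict[str, np.ndarray]
    case_id: str = ""
    position: str = ""

    @property
    def counts(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.samples.items()}

    def total_count(self) -> int:
        return int(sum(len(v) for v in self.samples.values()))

    def medians(self) -> dict[str, float]:
        return {k: float(np.median(v)) for k, v in self.samples.items() if len(v)}


def group_strains(
    strain_field: StrainField,
    regions: TissueRegionSet,
    case_id: str = "",
    position: str = "",
) -> RegionStrains:
    """Group defined strain voxels by the region whose contour contains them.

    A voxel joins region ``r`` iff its centre lies inside r's contour under
    the even-odd rule; centres claimed by several contours go to the smallest
    region label (boundary tie-break); ``outer_excluded`` never collects
    samples.  Field and regions must share the deformed coordinate frame.
    """
    x, y = strain_field.centers_2d()
    xx, yy = np.meshgrid(x, y)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    defined = strain_field.mask.ravel()
    values = strain_field.values.ravel()

    taken = np.zeros(len(pts), dtype=bool)
    samples: dict[str, np.ndarray] = {}
    for label in sorted(regions.regions):
        if label == "outer_excluded":
            continue
        poly = regions.regions[label].points
        path = Path(np.vstack([poly, poly[:1]]), closed=True)
        inside = path.contains_points(pts, radius=1e-9)
        sel = inside & defined & ~taken
        taken |= inside
        samples[label] = values[sel].copy()

    if not any(len(v) for v in samples.values()):
        raise GroupingError(
            "no strain voxel falls inside any region contour; "
            "field and regions may be in different frames"
        )
    return RegionStrains(samples=samples, case_id=case_id, position=position)
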