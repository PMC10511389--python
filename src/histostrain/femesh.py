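"""Conforming multi-region triangulation of annular vessel cross sections.

The wall domain between the lumen and outer contours is meshed region by
region with linear triangles.  Regions are the sector-like tissue areas of a
segmented cross section; the mesher builds radial node columns (shared
columns on inter-region interfaces, so the mesh conforms) and stitches
neighbouring columns into triangle strips.  Per-region target edge lengths
control the column spacing; elastin regions are customarily meshed about
twice as finely as thrombus regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .contours import Contour, polyline_radius_interpolant
from .regions import TissueRegionSet

# Realized mean edge length of a right-triangle strip mesh with spacing h is
# (h + h + sqrt(2) h) / 3; divide targets by this factor to hit them on average.
_EDGE_FACTOR = (2.0 + np.sqrt(2.0)) / 3.0

DEFAULT_EDGE_LENGTHS: dict[str, float] = {
    "A1": 4.0,
    "A2": 4.0,
    "A3": 4.0,
    "A4": 8.6,
    "A5": 8.6,
}


class MeshError(ValueError):
    """Raised for un-meshable region sets."""


@dataclass
class Mesh:
    """Multi-region 2D triangle mesh in micrometres.

    ``boundary_nodes`` maps 'lumen' and 'outer' to node ids ordered by angle,
    so the boundary polylines can be read off directly.
    """

    nodes: np.ndarray
    elements: np.ndarray
    element_labels: np.ndarray
    boundary_nodes: dict[str, np.ndarray]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def signed_areas(self, nodes: np.ndarray | None = None) -> np.ndarray:
        xy = self.nodes if nodes is None else nodes
        a, b, c = (xy[self.elements[:, i]] for i in range(3))
        return 0.5 * ((b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - (c[:, 0] - a[:, 0]) * (b[:, 1] - a[:, 1]))

    def region_edge_lengths(self, label: str) -> np.ndarray:
        """Lengths of the unique element edges inside one region."""
        els = self.elements[self.element_labels == label]
        edges = np.sort(
            np.vstack([els[:, [0, 1]], els[:, [1, 2]], els[:, [2, 0]]]), axis=1
        )
        edges = np.unique(edges, axis=0)
        return np.linalg.norm(self.nodes[edges[:, 0]] - self.nodes[edges[:, 1]], axis=1)

    def total_area(self) -> float:
        return float(self.signed_areas().sum())


def _radius_interpolant(contour: Contour, center: np.ndarray):
    # chordal interpolation keeps boundary nodes exactly on the input polyline
    return polyline_radius_interpolant(contour.points, center)


def _stitch(col_a: np.ndarray, sa: np.ndarray, col_b: np.ndarray, sb: np.ndarray) -> list[tuple[int, int, int]]:
    """Triangulate the strip between two radial node columns (monotone in s)."""
    tris = []
    i = j = 0
    while i < len(col_a) - 1 or j < len(col_b) - 1:
        if j == len(col_b) - 1 or (i < len(col_a) - 1 and sa[i + 1] <= sb[j + 1]):
            tris.append((col_a[i], col_a[i + 1], col_b[j]))
            i += 1
        else:
            tris.append((col_a[i], col_b[j], col_b[j + 1]))
            j += 1
    return tris


def mesh_cross_section(
    regions: TissueRegionSet,
    edge_lengths: Mapping[str, float] | float | None = None,
) -> Mesh:
    """Mesh the wall annulus with region-conforming linear triangles.

    Requires a sector-structured region set (``sector_intervals`` present):
    every region spans an angular interval of the wall between the lumen and
    outer contours, which matches segmented aneurysm cross sections.  Region
    interfaces are traced by shared element edges; realized mean edge lengths
    land within about 15 % of the per-region targets.
    """
    if regions.sector_intervals is None:
        raise MeshError("mesh_cross_section requires a sector-structured TissueRegionSet")
    if edge_lengths is None:
        edge_lengths = DEFAULT_EDGE_LENGTHS
    if np.isscalar(edge_lengths):
        edge_lengths = {label: float(edge_lengths) for label in regions.regions}
    missing = [l for l in regions.regions if l not in edge_lengths]
    if missing:
        raise MeshError(f"no target edge length for regions {missing}")

    order = sorted(regions.sector_intervals.items(), key=lambda kv: kv[1][0])
    labels = [kv[0] for kv in order]
    intervals = [kv[1] for kv in order]
    for (la, ia), (lb, ib) in zip(zip(labels, intervals), zip(labels[1:], intervals[1:])):
        if abs(ia[1] - ib[0]) > 1e-9:
            raise MeshError(f"regions {la} and {lb} do not share an interface (gap or overlap)")
    span = intervals[-1][1] - intervals[0][0]
    if abs(span - 2.0 * np.pi) > 1e-9:
        raise MeshError("region sectors do not tile the full wall annulus")

    center = regions.center
    r_lumen = _radius_interpolant(regions.lumen, center)
    r_outer = _radius_interpolant(regions.outer, center)
    h_eff = {l: float(edge_lengths[l]) / _EDGE_FACTOR for l in labels}

    nodes: list[np.ndarray] = []
    lumen_ids: list[int] = []
    outer_ids: list[int] = []

    def make_column(theta: float, m: int) -> tuple[np.ndarray, np.ndarray]:
        s = np.linspace(0.0, 1.0, m + 1)
        rl, ro = float(r_lumen(theta)), float(r_outer(theta))
        rr = rl + s * (ro - rl)
        pts = center + np.column_stack([rr * np.cos(theta), rr * np.sin(theta)])
        ids = np.arange(len(nodes), len(nodes) + len(pts))
        nodes.extend(pts)
        lumen_ids.append(ids[0])
        outer_ids.append(ids[-1])
        return ids, s

    def radial_divisions(theta: float, h: float) -> int:
        thickness = float(r_outer(theta) - r_lumen(theta))
        return max(1, int(round(thickness / h)))

    # interface columns are shared by the two adjacent regions and use the
    # finer of their radial spacings
    n_regions = len(labels)
    interface_cols = []
    for i in range(n_regions):
        theta_i = intervals[i][0]
        left = labels[i - 1]
        right = labels[i]
        m = max(radial_divisions(theta_i, h_eff[left]), radial_divisions(theta_i, h_eff[right]))
        interface_cols.append((theta_i, m))

    elements: list[tuple[int, int, int]] = []
    el_labels: list[str] = []
    first_iface: tuple[np.ndarray, np.ndarray] | None = None
    prev_iface: tuple[np.ndarray, np.ndarray] | None = None

    for i, label in enumerate(labels):
        theta_a, theta_b = intervals[i]
        if prev_iface is None:
            prev_iface = make_column(*interface_cols[i])
            first_iface = prev_iface
        cols = [prev_iface]
        r_mid = 0.5 * (
            float(r_lumen(0.5 * (theta_a + theta_b))) + float(r_outer(0.5 * (theta_a + theta_b)))
        )
        n_cols = max(1, int(round((theta_b - theta_a) * r_mid / h_eff[label])))
        m_int = radial_divisions(0.5 * (theta_a + theta_b), h_eff[label])
        for theta in np.linspace(theta_a, theta_b, n_cols + 1)[1:-1]:
            cols.append(make_column(theta, m_int))
        if i == n_regions - 1:
            next_iface = first_iface
        else:
            next_iface = make_column(*interface_cols[i + 1])
        cols.append(next_iface)
        for (ids_a, sa), (ids_b, sb) in zip(cols, cols[1:]):
            tris = _stitch(ids_a, sa, ids_b, sb)
            elements.extend(tris)
            el_labels.extend([label] * len(tris))
        prev_iface = next_iface

    node_arr = np.array(nodes)
    el_arr = np.array(elements, dtype=int)
    # normalize element orientation to positive signed area
    a, b, c = (node_arr[el_arr[:, k]] for k in range(3))
    areas = 0.5 * ((b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - (c[:, 0] - a[:, 0]) * (b[:, 1] - a[:, 1]))
    flip = areas < 0
    el_arr[flip] = el_arr[flip][:, [0, 2, 1]]

    # boundary ids were appended once per column in theta order, but interface
    # columns for region i are created before region i's interior columns, so
    # order is already monotone in theta; drop duplicates defensively.
    lumen_order = np.array(lumen_ids, dtype=int)
    outer_order = np.array(outer_ids, dtype=int)

    mesh = Mesh(
        nodes=node_arr,
        elements=el_arr,
        element_labels=np.array(el_labels, dtype=object),
        boundary_nodes={"lumen": lumen_order, "outer": outer_order},
    )
    if np.any(mesh.signed_areas() <= 0):
        raise MeshError("mesher produced degenerate or inverted elements")
    return mesh
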