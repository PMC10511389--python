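"""File formats: contour CSV, TIFF volumes/fields with JSON sidecars, VTK meshes.

Contours travel as CSV with columns (role, region_label, point_index, x_um,
y_um).  Volumes and strain fields are TIFF stacks with a JSON sidecar holding
the voxel size (and origin for fields).  Meshes use legacy ASCII VTK with a
cell-data field ``region_label``.  Warp parameter sets are CSV with twelve
columns p1..p12, one row per fitting window.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .contours import Contour
from .femesh import Mesh

from .strain import StrainField, VolumePair


def write_contours_csv(path, contours: list[Contour]) -> None:
    rows = []
    for c in contours:
        for i, (x, y) in enumerate(c.points):
            rows.append(
                {
                    "role": c.role,
                    "region_label": c.region_label or "",
                    "point_index": i,
                    "x_um": x,
                    "y_um": y,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_contours_csv(path) -> list[Contour]:
    df = pd.read_csv(path, keep_default_na=False)
    contours = []
    for (role, label), g in df.groupby(["role", "region_label"], sort=False):
        g = g.sort_values("point_index")
        contours.append(
            Contour(
                g[["x_um", "y_um"]].to_numpy(float),
                role=role,
                region_label=label or None,
            )
        )
    return contours


def write_strain_field(path, field: StrainField) -> None:
    path = Path(path)
    data = np.where(field.mask, field.values, np.nan).astype(np.float32)
    tifffile.imwrite(path, data)
    sidecar = {
        "voxel_size_um": field.voxel_size_um,
        "origin_um": field.origin_um.tolist(),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_strain_field(path) -> StrainField:
    path = Path(path)
    data = tifffile.imread(path).astype(float)
    meta = json.loads(path.with_suffix(".json").read_text())
    mask = np.isfinite(data)
    return StrainField(
        values=np.where(mask, data, 0.0),
        voxel_size_um=float(meta["voxel_size_um"]),
        origin_um=np.asarray(meta["origin_um"], dtype=float),
        mask=mask,
    )


def write_volume_pair(directory, pair: VolumePair, stem: str = "volume") -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(directory / f"{stem}_reference.tif", pair.reference.astype(np.float32))
    tifffile.imwrite(directory / f"{stem}_target.tif", pair.target.astype(np.float32))
    (directory / f"{stem}.json").write_text(
        json.dumps({"voxel_size_um": pair.voxel_size_um}, indent=1)
    )


def read_volume_pair(directory, stem: str = "volume") -> VolumePair:
    directory = Path(directory)
    meta = json.loads((directory / f"{stem}.json").read_text())
    return VolumePair(
        reference=tifffile.imread(directory / f"{stem}_reference.tif").astype(float),
        target=tifffile.imread(directory / f"{stem}_target.tif").astype(float),
        voxel_size_um=float(meta["voxel_size_um"]),
    )


def write_warps_csv(path, warps: np.ndarray) -> None:
    """Warp parameter rows (n_windows, 12) as CSV with columns p1..p12."""
    arr = np.atleast_2d(np.asarray(warps, dtype=float))
    pd.DataFrame(arr, columns=[f"p{i}" for i in range(1, 13)]).to_csv(path, index=False)


def read_warps_csv(path) -> np.ndarray:
    return pd.read_csv(path).to_numpy(float)


def write_mesh_vtk(path, mesh: Mesh) -> None:
    labels = sorted(set(mesh.element_labels.tolist()))
    code = {l: i for i, l in enumerate(labels)}
    lines = [
        "# vtk DataFile Version 2.0",
        "histostrain cross-section mesh; region codes: "
        + ", ".join(f"{code[l]}={l}" for l in labels),
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} double",
    ]
    lines += [f"{x:.9g} {y:.9g} 0" for x, y in mesh.nodes]
    m = len(mesh.elements)
    lines.append(f"CELLS {m} {4 * m}")
    lines += [f"3 {a} {b} {c}" for a, b, c in mesh.elements]
    lines.append(f"CELL_TYPES {m}")
    lines += ["5"] * m
    lines += [f"CELL_DATA {m}", "SCALARS region_label int 1", "LOOKUP_TABLE default"]
    lines += [str(code[l]) for l in mesh.element_labels]
    Path(path).write_text("\n".join(lines) + "\n")


def read_mesh_vtk(path) -> Mesh:
    text = Path(path).read_text().splitlines()
    code_map = {}
    for part in text[1].split("region codes: ")[-1].split(", "):
        if "=" in part:
            k, v = part.split("=")
            code_map[int(k)] = v
    i = text.index(next(l for l in text if l.startswith("POINTS")))
    n = int(text[i].split()[1])
    nodes = np.array([list(map(float, text[i + 1 + k].split()))[:2] for k in range(n)])
    j = i + 1 + n
    m = int(text[j].split()[1])
    elements = np.array([list(map(int, text[j + 1 + k].split()))[1:] for k in range(m)])
    k0 = text.index("LOOKUP_TABLE default") + 1
    labels = np.array([code_map[int(text[k0 + k])] for k in range(m)], dtype=object)
    # boundary node sets are not stored in VTK; recover nothing here
    return Mesh(nodes=nodes, elements=elements, element_labels=labels, boundary_nodes={})


def write_boundary_displacements_csv(path, node_ids, displacements) -> None:
    pd.DataFrame(
        {
            "node_id": np.asarray(node_ids, dtype=int),
            "ux_um": np.asarray(displacements)[:, 0],
            "uy_um": np.asarray(displacements)[:, 1],
        }
    ).to_csv(path, index=False)


def write_region_strains_csv(path, region_strains) -> None:
    rows = []
    for label, vals in sorted(region_strains.samples.items()):
        for v in vals:
            rows.append(
                {
                    "case": region_strains.case_id,
                    "position": region_strains.position,
                    "region_label": label,
                    "E1": v,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_manifest(path, manifest: dict) -> None:
    Path(path).write_text(yaml.safe_dump(manifest, sort_keys=False))


def read_manifest(path) -> dict:
    return yaml.safe_load(Path(path).read_text())
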