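"""Displacement-driven hyperelastic finite elements (zero surface tractions).

The registration of histological onto in vivo contours prescribes the full
motion of the lumen and outer wall boundaries.  With no applied tractions the
interior deformation follows from static equilibrium alone, and for this
"displacement - zero traction" problem class the computed displacements are
nearly independent of the constitutive law, which is what the material
sensitivity analysis quantifies.

The body is a compressible Neo-Hookean solid in plane stress.  With in-plane
deformation gradient F (J = det F) the strain energy density is

    W = mu/2 (tr(F^T F) - 2) - mu ln J + lam/2 (ln J)^2

where ``lam`` is the plane-stress-condensed Lame parameter, so the
out-of-plane stress is zero by construction.  mu = 2 C10.  Because boundary
displacements are prescribed everywhere, scaling the stiffness of a
homogeneous body leaves the solution unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from .contours import Contour
from .femesh import Mesh
from .regions import TissueRegionSet


class SolverError(RuntimeError):
    """Newton iteration failed to converge."""


@dataclass
class MaterialSpec:
    """Per-region (or uniform) Neo-Hookean stiffness.

    ``c10_kpa`` may be a scalar for a homogeneous body or a mapping from
    region label to C10 in kPa.  ``poisson`` is the Poisson-like ratio of the
    compressible stand-in for the incompressible reference material; values
    near 0.5 recover near-incompressibility without volumetric locking of the
    linear triangles.
    """

    c10_kpa: float | Mapping[str, float] = 1.0e6  # 1 GPa
    poisson: float = 0.45

    def mu_for(self, labels: np.ndarray) -> np.ndarray:
        if np.isscalar(self.c10_kpa):
            return np.full(len(labels), 2.0 * float(self.c10_kpa))
        table = dict(self.c10_kpa)
        missing = sorted({l for l in labels if l not in table})
        if missing:
            raise ValueError(f"no C10 for regions {missing}")
        mu = np.array([2.0 * table[l] for l in labels], dtype=float)
        if np.any(mu <= 0):
            raise ValueError("C10 must be positive")
        return mu


@dataclass
class BoundaryDisplacement:
    """Prescribed displacement on every lumen and outer boundary node."""

    node_ids: np.ndarray
    displacements: np.ndarray  # (n, 2) in µm

    def __post_init__(self) -> None:
        self.node_ids = np.asarray(self.node_ids, dtype=int)
        self.displacements = np.asarray(self.displacements, dtype=float)
        if self.displacements.shape != (len(self.node_ids), 2):
            raise ValueError("displacements must be (n, 2) matching node_ids")

    @classmethod
    def from_field(cls, mesh: Mesh, field_fn) -> "BoundaryDisplacement":
        """Evaluate a displacement field on the mesh boundary nodes."""
        ids = np.concatenate([mesh.boundary_nodes["lumen"], mesh.boundary_nodes["outer"]])
        return cls(ids, np.asarray(field_fn(mesh.nodes[ids]), dtype=float))


@dataclass
class SolveResult:
    deformed_mesh: Mesh
    displacement: np.ndarray
    increments: int
    newton_iterations: int
    residual_norms: list[float]


def _element_gradients(nodes: np.ndarray, elements: np.ndarray):
    a, b, c = (nodes[elements[:, k]] for k in range(3))
    J = np.stack([b - a, c - a], axis=2)  # (M, 2, 2), columns are edges
    detJ = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
    area = 0.5 * detJ
    inv = np.empty_like(J)
    inv[:, 0, 0] = J[:, 1, 1] / detJ
    inv[:, 0, 1] = -J[:, 0, 1] / detJ
    inv[:, 1, 0] = -J[:, 1, 0] / detJ
    inv[:, 1, 1] = J[:, 0, 0] / detJ
    # shape gradients: rows of inv give d(xi)/dx; N = [1-xi-eta, xi, eta]
    g = np.empty((len(elements), 3, 2))
    g[:, 1, :] = inv[:, 0, :]
    g[:, 2, :] = inv[:, 1, :]
    g[:, 0, :] = -g[:, 1, :] - g[:, 2, :]
    return g, area


def _stress_tangent(F: np.ndarray, mu: np.ndarray, lam: np.ndarray):
    J = F[:, 0, 0] * F[:, 1, 1] - F[:, 0, 1] * F[:, 1, 0]
    if np.any(J <= 0):
        return None, None, None
    FinvT = np.empty_like(F)
    FinvT[:, 0, 0] = F[:, 1, 1] / J
    FinvT[:, 0, 1] = -F[:, 1, 0] / J
    FinvT[:, 1, 0] = -F[:, 0, 1] / J
    FinvT[:, 1, 1] = F[:, 0, 0] / J
    lnJ = np.log(J)
    P = mu[:, None, None] * (F - FinvT) + (lam * lnJ)[:, None, None] * FinvT
    # magnitude of the terms that cancel inside P: sets the roundoff floor
    Pscale = mu[:, None, None] * (np.abs(F) + np.abs(FinvT)) + np.abs(lam * lnJ)[
        :, None, None
    ] * np.abs(FinvT)
    # A_iJkL = mu d_ik d_JL + (mu - lam lnJ) FinvT_iL FinvT_kJ + lam FinvT_iJ FinvT_kL
    eye = np.eye(2)
    A = mu[:, None, None, None, None] * np.einsum("ik,JL->iJkL", eye, eye)[None]
    A = A + (mu - lam * lnJ)[:, None, None, None, None] * np.einsum(
        "miL,mkJ->miJkL", FinvT, FinvT
    )
    A = A + lam[:, None, None, None, None] * np.einsum("miJ,mkL->miJkL", FinvT, FinvT)
    return P, A, Pscale


class _Assembler:
    def __init__(self, mesh: Mesh, material: MaterialSpec):
        self.mesh = mesh
        self.g, self.area = _element_gradients(mesh.nodes, mesh.elements)
        mu = material.mu_for(mesh.element_labels)
        nu = material.poisson
        lam3d = 2.0 * mu * nu / (1.0 - 2.0 * nu)
        self.lam = 2.0 * lam3d * mu / (lam3d + 2.0 * mu)  # plane-stress condensation
        self.mu = mu
        conn = mesh.elements
        dof = np.stack([2 * conn, 2 * conn + 1], axis=2).reshape(len(conn), 6)
        self.rows = np.repeat(dof, 6, axis=1).ravel()
        self.cols = np.tile(dof, (1, 6)).ravel()
        self.dof = dof
        self.ndof = 2 * mesh.n_nodes

    def forces_and_stiffness(self, u: np.ndarray, need_stiffness: bool = True):
        conn = self.mesh.elements
        ue = u.reshape(-1, 2)[conn]  # (M, 3, 2)
        F = np.eye(2)[None] + np.einsum("mai,maJ->miJ", ue, self.g)
        P, A, Pscale = _stress_tangent(F, self.mu, self.lam)
        if P is None:
            return None, None, 0.0
        fe = self.area[:, None, None] * np.einsum("miJ,maJ->mai", P, self.g)
        f = np.zeros(self.ndof)
        np.add.at(f, self.dof.ravel(), fe.reshape(-1))
        # pre-cancellation force magnitude: the assembly roundoff floor
        gross = float(
            np.linalg.norm(
                self.area[:, None, None] * np.einsum("miJ,maJ->mai", Pscale, np.abs(self.g))
            )
        )
        if not need_stiffness:
            return f, None, gross
        Ke = self.area[:, None, None, None, None] * np.einsum(
            "miJkL,maJ,mbL->maibk", A, self.g, self.g
        )
        Ke = Ke.reshape(len(conn), 6, 6)
        K = sp.coo_matrix(
            (Ke.ravel(), (self.rows, self.cols)), shape=(self.ndof, self.ndof)
        ).tocsr()
        return f, K, gross


def solve_zero_traction(
    mesh: Mesh,
    bc: BoundaryDisplacement,
    material: MaterialSpec | None = None,
    n_increments: int = 10,
    tol: float = 1e-8,
    max_newton: int = 25,
    max_halvings: int = 6,
) -> SolveResult:
    """Static equilibrium under prescribed boundary displacements, no tractions.

    The boundary motion is applied in equal increments; each increment is
    solved with Newton's method (automatic increment halving on divergence or
    element inversion).  Convergence requires the free-node residual norm to
    fall below ``tol`` times the reaction force norm.  Boundary nodes land
    exactly on their prescribed positions.
    """
    material = material or MaterialSpec()
    boundary_all = set(np.concatenate([mesh.boundary_nodes["lumen"], mesh.boundary_nodes["outer"]]))
    if set(bc.node_ids) != boundary_all:
        raise ValueError("boundary displacement must cover exactly the lumen and outer nodes")

    asm = _Assembler(mesh, material)
    ndof = asm.ndof
    fixed = np.zeros(ndof, dtype=bool)
    fixed[2 * bc.node_ids] = True
    fixed[2 * bc.node_ids + 1] = True
    free = ~fixed
    u_bc_full = np.zeros(ndof)
    u_bc_full[2 * bc.node_ids] = bc.displacements[:, 0]
    u_bc_full[2 * bc.node_ids + 1] = bc.displacements[:, 1]

    u = np.zeros(ndof)
    lam_done = 0.0
    step = 1.0 / n_increments
    min_step = step / 2**max_halvings
    increments = 0
    newton_total = 0
    res_norms: list[float] = []

    while lam_done < 1.0 - 1e-12:
        lam_try = min(1.0, lam_done + step)
        u_try = u.copy()
        u_try[fixed] = lam_try * u_bc_full[fixed]
        ok = False
        for it in range(max_newton):
            f, K, gross = asm.forces_and_stiffness(u_try)
            if f is None:  # element inversion
                break
            r = f[free]
            reactions = np.linalg.norm(f[fixed])
            rnorm = np.linalg.norm(r)
            # converged when small against the reactions, or at the assembly
            # roundoff floor (stress-free motions have zero reactions)
            if rnorm <= tol * max(reactions, 1e-30) or rnorm <= 1e-12 * gross:
                ok = True
                res_norms.append(rnorm)
                newton_total += it
                break
            du = spsolve(K[free][:, free].tocsc(), -r)
            # backtracking on residual increase or inversion
            scale = 1.0
            for _ in range(8):
                u_new = u_try.copy()
                u_new[free] += scale * du
                f_new, _, _ = asm.forces_and_stiffness(u_new, need_stiffness=False)
                if f_new is not None and (
                    np.linalg.norm(f_new[free]) < rnorm or scale < 1e-3
                ):
                    break
                scale *= 0.5
            else:
                break
            if f_new is None:
                break
            u_try = u_new
        if ok:
            u = u_try
            lam_done = lam_try
            increments += 1
        else:
            step *= 0.5
            if step < min_step:
                raise SolverError(
                    f"Newton diverged at load fraction {lam_done:.3f}; "
                    f"residual history {res_norms[-5:]}"
                )

    deformed = Mesh(
        nodes=mesh.nodes + u.reshape(-1, 2),
        elements=mesh.elements,
        element_labels=mesh.element_labels,
        boundary_nodes=mesh.boundary_nodes,
    )
    return SolveResult(deformed, u.reshape(-1, 2), increments, newton_total, res_norms)


def _region_boundary_loop(mesh: Mesh, label: str) -> np.ndarray:
    els = mesh.elements[mesh.element_labels == label]
    if not len(els):
        raise ValueError(f"region {label!r} has no elements")
    edges = np.vstack([els[:, [0, 1]], els[:, [1, 2]], els[:, [2, 0]]])
    key = np.sort(edges, axis=1)
    _, idx, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
    boundary = edges[idx[counts == 1]]
    nxt = dict(zip(boundary[:, 0].tolist(), boundary[:, 1].tolist()))
    if len(nxt) != len(boundary):
        raise ValueError(f"broken boundary chain for region {label!r}")
    start = boundary[0, 0]
    loop = [start]
    node = nxt[start]
    while node != start:
        loop.append(node)
        if node not in nxt or len(loop) > len(boundary):
            raise ValueError(f"broken boundary chain for region {label!r}")
        node = nxt[node]
    return np.array(loop, dtype=int)


def extract_deformed_region_contours(deformed: Mesh) -> TissueRegionSet:
    """Trace region, lumen and outer contours of a (deformed) mesh.

    Only nodal positions are used: strains and stresses of the mapping solve
    are artefacts of the arbitrary constitutive choice and are discarded.
    Every returned contour is closed with counterclockwise orientation.
    """
    regions = {}
    for label in sorted(set(deformed.element_labels.tolist())):
        loop = _region_boundary_loop(deformed, label)
        regions[label] = Contour(
            deformed.nodes[loop], role="region_boundary", region_label=label
        )
    lumen = Contour(deformed.nodes[deformed.boundary_nodes["lumen"]], role="lumen")
    outer = Contour(deformed.nodes[deformed.boundary_nodes["outer"]], role="outer")
    return TissueRegionSet(
        lumen=lumen,
        outer=outer,
        regions=regions,
        center=lumen.centroid,
    )
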