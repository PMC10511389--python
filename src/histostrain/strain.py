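"""Direct deformation estimation (DDE) and Green-Lagrange strain.

Strain is estimated by fitting a 12-parameter affine warp directly to voxel
intensities of an image pair.  The warp acts on homogeneous coordinates as

    W(x; p) = [[1+p1, p4,   p7,   p10],
               [p2,   1+p5, p8,   p11],
               [p3,   p6,   1+p9, p12]] @ [x, y, z, 1]^T

so the deformation gradient F is read off the first nine parameters without
an intermediate displacement field.  The first principal Green-Lagrange
strain E1 is the largest eigenvalue of E = (F^T F - I) / 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates


class NonPhysicalWarpError(ValueError):
    """Deformation gradient with non-positive determinant."""


class FlatTextureError(ValueError):
    """Fitting window has too little intensity variation to constrain a warp."""


@dataclass
class WarpParameters:
    """The 12-vector p of the affine warp; p1-p9 dimensionless, p10-p12 voxels."""

    p: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float).reshape(-1)
        if p.size != 12:
            raise ValueError("warp parameters must have 12 entries")
        self.p = p

    @classmethod
    def zeros(cls) -> "WarpParameters":
        return cls(np.zeros(12))

    @property
    def translation(self) -> np.ndarray:
        return self.p[9:12]

    def matrix(self) -> np.ndarray:
        """3x4 affine matrix [F | t]."""
        return np.column_stack([warp_to_deformation_gradient(self), self.translation])


def warp_to_deformation_gradient(p: WarpParameters | np.ndarray) -> np.ndarray:
    """Deformation gradient from the first nine warp parameters.

    The parameters fill F - I column-wise:
    row 1 is (1+p1, p4, p7), row 2 is (p2, 1+p5, p8), row 3 is (p3, p6, 1+p9).
    """
    v = p.p if isinstance(p, WarpParameters) else np.asarray(p, dtype=float).reshape(-1)
    F = np.eye(3) + v[:9].reshape(3, 3, order="F")
    return F


def is_physical(F: np.ndarray) -> bool:
    return float(np.linalg.det(F)) > 0.0


def green_lagrange(F: np.ndarray) -> np.ndarray:
    """Green-Lagrange strain tensor E = (F^T F - I)/2 (2x2 or 3x3)."""
    F = np.asarray(F, dtype=float)
    return 0.5 * (F.T @ F - np.eye(F.shape[0]))


def green_lagrange_principal(F: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """First principal Green-Lagrange strain of a deformation gradient.

    Returns ``(E1, direction, eigenvalues)`` where ``direction`` is the unit
    eigenvector of the largest eigenvalue and ``eigenvalues`` are sorted
    descending.  Directions of the symmetric eigenproblem are orthonormal.
    """
    F = np.asarray(F, dtype=float)
    if np.linalg.det(F) <= 0.0:
        raise NonPhysicalWarpError("det F <= 0")
    E = green_lagrange(F)
    w, v = np.linalg.eigh(E)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    return float(w[0]), v[:, 0], w


@dataclass
class VolumePair:
    """Reference and target intensity volumes on the same isotropic grid."""

    reference: np.ndarray
    target: np.ndarray
    voxel_size_um: float = 40.0

    def __post_init__(self) -> None:
        self.reference = np.asarray(self.reference, dtype=float)
        self.target = np.asarray(self.target, dtype=float)
        if self.reference.shape != self.target.shape:
            raise ValueError("reference and target must share a shape")
        if self.voxel_size_um <= 0:
            raise ValueError("voxel size must be positive")


@dataclass
class StrainField:
    """Gridded first-principal strain values with a missing-value mask.

    ``values[iy, ix]`` (or ``[iz, iy, ix]``) is E1 at the voxel whose centre
    sits at ``origin_um + (index + 0.5) * voxel_size_um`` with index order
    reversed to (x, y[, z]).  ``mask`` is True where E1 is defined.
    """

    values: np.ndarray
    voxel_size_um: float
    origin_um: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.origin_um = np.asarray(self.origin_um, dtype=float)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask must be congruent")
        defined = self.values[self.mask]
        if defined.size and np.nanmin(defined) < -0.5 - 1e-12:
            raise ValueError("E1 below the physical lower bound of -0.5")

    def centers_2d(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) voxel-centre coordinate arrays for a 2D field, in µm."""
        ny, nx = self.values.shape
        x = self.origin_um[0] + (np.arange(nx) + 0.5) * self.voxel_size_um
        y = self.origin_um[1] + (np.arange(ny) + 0.5) * self.voxel_size_um
        return x, y


def sample_affine_warp(volume: np.ndarray, p: WarpParameters, origin: np.ndarray | None = None) -> np.ndarray:
    """Sample ``volume`` at warped grid coordinates with trilinear interpolation.

    Output voxel at index ``x`` takes the value ``volume[W(x - origin) + origin]``;
    ``origin`` defaults to the volume centre so p10-p12 translate about it.
    """
    shape = volume.shape
    if origin is None:
        origin = (np.array(shape, dtype=float) - 1.0) / 2.0
    grid = np.stack(np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij"), axis=0)
    rel = grid.reshape(3, -1) - origin[:, None]
    A = p.matrix()
    warped = A[:, :3] @ rel + A[:, 3:4] + origin[:, None]
    out = map_coordinates(volume, warped, order=1, mode="nearest")
    return out.reshape(shape)


@dataclass
class WarpEstimate:
    parameters: WarpParameters
    residual: float
    converged: bool
    iterations: int
    residual_history: np.ndarray = field(default_factory=lambda: np.empty(0))


def _window_slices(window) -> tuple[slice, slice, slice]:
    return tuple(slice(int(a), int(b)) for a, b in window)


def estimate_warp(
    pair: VolumePair,
    window,
    init: WarpParameters | None = None,
    tol: float = 1e-8,
    max_iter: int = 200,
    min_variance: float = 1e-8,
) -> WarpEstimate:
    """Gauss-Newton fit of the affine warp on one window of a volume pair.

    Minimizes the sum of squared differences between the reference window and
    the target sampled at warped coordinates (trilinear interpolation); the
    warp origin is the window centre.  ``window`` is a per-axis sequence of
    (start, stop) voxel bounds; each side must be at least 8 voxels and the
    window must be interior to the volumes.  Deterministic given its inputs.
    """
    window = np.asarray(window, dtype=int)
    if window.shape != (3, 2):
        raise ValueError("window must be three (start, stop) pairs")
    sides = window[:, 1] - window[:, 0]
    if np.any(sides < 8):
        raise ValueError("window side must be at least 8 voxels")
    if np.any(window[:, 0] < 0) or np.any(window[:, 1] > np.array(pair.reference.shape)):
        raise ValueError("window must be interior to the volumes")

    sl = _window_slices(window)
    ref = pair.reference[sl]
    if float(ref.var()) < min_variance:
        raise FlatTextureError("window intensity variance below threshold")

    center = (window[:, 0] + window[:, 1] - 1) / 2.0
    grid = np.stack(
        np.meshgrid(*[np.arange(a, b, dtype=float) for a, b in window], indexing="ij"), axis=0
    ).reshape(3, -1)
    rel = grid - center[:, None]  # window-centred coordinates
    grads = np.gradient(pair.target)

    p = np.zeros(12) if init is None else np.array(init.p, dtype=float)
    r_ref = ref.reshape(-1)

    def residual(pv: np.ndarray) -> np.ndarray:
        A = WarpParameters(pv).matrix()
        coords = A[:, :3] @ rel + A[:, 3:4] + center[:, None]
        vals = map_coordinates(pair.target, coords, order=1, mode="nearest")
        return vals - r_ref, coords

    r, coords = residual(p)
    history = [float(np.sqrt(np.mean(r**2)))]
    converged = False
    for it in range(max_iter):
        g = np.stack([map_coordinates(gax, coords, order=1, mode="nearest") for gax in grads])
        # d(coords_i)/dp: linear part columns are rel components, translation is 1
        J = np.empty((r.size, 12))
        for j in range(9):
            i, col = j % 3, j // 3  # p(1+j) perturbs F[i, col]
            J[:, j] = g[i] * rel[col]
        for i in range(3):
            J[:, 9 + i] = g[i]
        step, *_ = np.linalg.lstsq(J, -r, rcond=None)
        rms_prev = history[-1]
        scale = 1.0
        for _ in range(12):
            trial = p + scale * step
            r_try, coords_try = residual(trial)
            rms_try = float(np.sqrt(np.mean(r_try**2)))
            if rms_try <= rms_prev or scale < 1e-6:
                break
            scale *= 0.5
        p, r, coords = trial, r_try, coords_try
        history.append(rms_try)
        if abs(rms_prev - rms_try) <= tol * max(rms_prev, 1e-30) or rms_try < 1e-14:
            converged = True
            break
    return WarpEstimate(
        WarpParameters(p), history[-1], converged, len(history) - 1, np.array(history)
    )


def strain_field_from_volumes(
    pair: VolumePair,
    window_size: int = 16,
    overlap: float = 0.5,
    mask: np.ndarray | None = None,
    planar: bool = False,
    **fit_kwargs,
) -> StrainField:
    """Tile a volume pair with fitting windows and map E1 at window centres.

    Windows of ``window_size`` voxels per side are tiled with the given
    fractional overlap over the (optional) foreground mask; each window gets
    an independent warp fit, and E1 of the resulting deformation gradient is
    assigned to the window centre.  Failed or flat windows are masked out.
    With ``planar=True`` E1 is computed from the in-plane 2x2 sub-block of F.
    """
    shape = np.array(pair.reference.shape)
    stride = max(1, int(round(window_size * (1.0 - overlap))))
    starts = [np.arange(0, s - window_size + 1, stride) for s in shape]
    values = np.full([len(s) for s in starts], np.nan)
    ok = np.zeros_like(values, dtype=bool)
    for ii, si in enumerate(starts[0]):
        for jj, sj in enumerate(starts[1]):
            for kk, sk in enumerate(starts[2]):
                win = [(si, si + window_size), (sj, sj + window_size), (sk, sk + window_size)]
                if mask is not None:
                    sl = _window_slices(np.asarray(win))
                    if not mask[sl].any():
                        continue
                try:
                    est = estimate_warp(pair, win, **fit_kwargs)
                except (FlatTextureError, ValueError):
                    continue
                if not est.converged:
                    continue
                F = warp_to_deformation_gradient(est.parameters)
                if not is_physical(F):
                    continue
                if planar:
                    F = F[:2, :2]
                e1, _, _ = green_lagrange_principal(F)
                values[ii, jj, kk] = e1
                ok[ii, jj, kk] = True
    if not ok.any():
        raise ValueError("all fitting windows failed; empty strain field")
    # window centres: (start + (window_size - 1)/2) voxels along each axis
    origin = (
        np.array([s[0] for s in starts], dtype=float) + (window_size - 1) / 2.0 - stride / 2.0
    ) * pair.voxel_size_um
    return StrainField(
        values=values,
        voxel_size_um=stride * pair.voxel_size_um,
        origin_um=origin,
        mask=ok,
    )
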