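import warnings

import numpy as np
import pytest

import histostrain as hs
from histostrain.contours import Contour
from histostrain.fesolve import BoundaryDisplacement, solve_zero_traction
from histostrain.femesh import mesh_cross_section

warnings.filterwarnings("ignore", message=".*Input data has range zero.*")
warnings.filterwarnings("ignore", message=".*Precision loss occurred.*")

# coarse per-region target edge lengths (µm) keeping unit-test solves fast
COARSE_EDGES = {"A1": 12.0, "A2": 12.0, "A3": 12.0, "A4": 24.0, "A5": 24.0}


@pytest.fixture(scope="session")
def phantom_ref():
    """Reference cross-section phantom (study-like geometry, seed 1)."""
    return hs.generate_cross_section_phantom(seed=1)


@pytest.fixture(scope="session")
def mesh_ref(phantom_ref):
    return mesh_cross_section(phantom_ref.undeformed_regions, COARSE_EDGES)


@pytest.fixture(scope="session")
def solved_ref(phantom_ref, mesh_ref):
    bc = BoundaryDisplacement.from_field(mesh_ref, phantom_ref.ground_truth_displacement)
    return solve_zero_traction(mesh_ref, bc)


def circle_contour(radius=500.0, n=200, role="lumen", center=(0.0, 0.0)):
    th = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    pts = np.column_stack(
        [center[0] + radius * np.cos(th), center[1] + radius * np.sin(th)]
    )
    return Contour(pts, role=role)


def perturbed_circle_contour(radius=500.0, n=10000, amplitudes=((2, 0.05), (3, 0.03)), role="lumen"):
    th = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    r = radius * (1.0 + sum(a * np.cos(k * th) for k, a in amplitudes))
    return Contour(np.column_stack([r * np.cos(th), r * np.sin(th)]), role=role)
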