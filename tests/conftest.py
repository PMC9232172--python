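import math

import numpy as np
import pytest

from epivertex import theory
from epivertex.cell_cycle import CellCycleParams
from epivertex.mechanics import MechanicalParams
from epivertex.mesh_core import ABNORMAL, build_hexagonal_tissue

SOLID = (0.12, 0.04)  # wing-disc-like, low fluidity
FLUID = (0.01, 0.025)  # high fluidity


@pytest.fixture(scope="session")
def solid_ground():
    return theory.ground_state(*SOLID)


@pytest.fixture(scope="session")
def fluid_ground():
    return theory.ground_state(*FLUID)


@pytest.fixture
def solid_params():
    return MechanicalParams(
        lambda_normal=SOLID[0],
        lambda_abnormal=SOLID[0],
        gamma_normal=SOLID[1],
        gamma_abnormal=SOLID[1],
    )


@pytest.fixture
def fluid_params():
    return MechanicalParams(
        lambda_normal=FLUID[0],
        lambda_abnormal=FLUID[0],
        gamma_normal=FLUID[1],
        gamma_abnormal=FLUID[1],
    )


@pytest.fixture
def cycle_frozen():
    return CellCycleParams(tau_abnormal=math.inf, tau_normal=math.inf)


@pytest.fixture
def rosette7(solid_ground):
    return build_hexagonal_tissue(7, solid_ground.l_g)


@pytest.fixture
def patch19(solid_ground):
    return build_hexagonal_tissue(19, solid_ground.l_g)


@pytest.fixture
def perturbed19(solid_ground):
    mesh = build_hexagonal_tissue(19, solid_ground.l_g)
    rng = np.random.default_rng(7)
    mesh.vertices += 0.02 * solid_ground.l_g * rng.standard_normal(mesh.vertices.shape)
    return mesh


def mark_central(mesh, n):
    center = np.mean([mesh.cell_centroid(c) for c in mesh.cell_ids()], axis=0)
    ids = sorted(mesh.cell_ids(), key=lambda c: float(np.linalg.norm(mesh.cell_centroid(c) - center)))
    for c in ids[:n]:
        mesh.cells[c].cell_type = ABNORMAL
    return ids[:n]
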