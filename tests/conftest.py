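import numpy as np
import pytest

from ampelqtl.morphometrics import LandmarkSet
from ampelqtl.simulate import SimulationConfig, simulate_genotypes

# Hand-laid-out reference leaf: margin landmarks 14-21 sweep the
# digitised half, the three vein polygons are thin branched quads
# inside it.  Lengths were chosen to come out round (L1=8, L2=L3=L4=5)
# and the polygon areas were frozen from exact rational shoelace
# arithmetic and checked against an independent polygon library.
LEAF_A_POINTS = np.array(
    [
        [-0.5, 0.0],     # 1
        [-0.3, 0.0],     # 2
        [-0.1, 0.0],     # 3
        [0.1, 0.0],      # 4
        [-1.681, 0.322], # 5
        [-1.451, 0.254], # 6
        [-1.538, 0.384], # 7
        [-1.988, 2.284], # 8
        [-1.808, 2.044], # 9
        [-1.802, 2.236], # 10
        [-0.1, 6.2],     # 11
        [-0.1, 5.8],     # 12
        [0.1, 5.8],      # 13
        [0.6, -2.2],     # 14
        [-5.2, 1.4],     # 15
        [-3.2, 1.6],     # 16
        [-4.3, 3.0],     # 17
        [-3.2, 4.0],     # 18
        [-1.5, 4.0],     # 19
        [-0.6, 7.0],     # 20
        [0.0, 8.0],      # 21
    ]
)

# frozen oracle values for leaf_A (exact rational shoelace / sqrt)
LEAF_A_EXPECTED = {
    "L1": 8.0,
    "L2": 5.0,
    "L3": 5.0,
    "L4": 5.0,
    "L5": 3.1982365453480766,  # sqrt(10.228717)
    "total_area": 24.63,
    "mid_vein_area": 1.5,
    "dist_vein_area": 0.736,
    "prox_vein_area": 0.4998,
    "vein_area": 2.7358,
    "blade_area": 21.8942,
    "veins_to_blade": -2.0797978638902457,
    "prox_to_dist": 1.0,
    "prox_to_mid": 0.625,
    "dist_to_mid": 0.625,
    "xvii_to_mid": 0.625,
    "petiolar_sinus_to_area": 0.12985126046886222,
}


def make_leaf(points, leaf_id="leaf", **meta):
    defaults = dict(
        genotype_id="G1",
        presentation="own_rooted",
        position="middle",
        daylength_h=14,
        year=2021,
    )
    defaults.update(meta)
    return LandmarkSet(leaf_id=leaf_id, points=np.asarray(points, dtype=float), **defaults)


@pytest.fixture
def leaf_a():
    return make_leaf(LEAF_A_POINTS, leaf_id="leaf_A")


@pytest.fixture(scope="session")
def small_cross():
    """135 F1 individuals over 19 LGs x 10 markers (seeded)."""
    cfg = SimulationConfig(n_genotypes=135, n_lgs=19, markers_per_lg=10, seed=20240901)
    return simulate_genotypes(cfg)


@pytest.fixture(scope="session")
def tiny_cross():
    """Small, fast cross for permutation-heavy tests."""
    cfg = SimulationConfig(n_genotypes=100, n_lgs=5, markers_per_lg=8, seed=42)
    return simulate_genotypes(cfg)
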