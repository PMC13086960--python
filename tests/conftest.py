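import numpy as np
import pytest

from waxpore import (LatticeSpec, PoreRegion, PoreSpec, build_crystal_slab,
                     carve_pore)


@pytest.fixture(scope="session")
def default_lattice():
    return LatticeSpec()


@pytest.fixture(scope="session")
def flat_slab():
    """6 x 6 nm single-layer slab: 192 C30 chains, 5760 carbons."""
    return build_crystal_slab((6.0, 6.0), LatticeSpec())


@pytest.fixture(scope="session")
def pore_slab():
    """4-layer slab with the default 14-chain, 15 nm pore carved."""
    slab = build_crystal_slab((6.0, 6.0), LatticeSpec(layer_count=4))
    carved, per_layer = carve_pore(slab, PoreSpec())
    return carved, per_layer


@pytest.fixture
def pore_region(flat_slab):
    return PoreRegion(axis=(flat_slab.box[0] / 2, flat_slab.box[1] / 2),
                      radius=0.975, z_top=0.0, z_bottom=-15.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
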