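import numpy as np
import pytest

from memsteer import electrostatics as es
from memsteer import synthetic_systems as ss
from memsteer.protein_model import ProteinModel


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_patch():
    """60 x 60 Å patch: 58 sites per leaflet, quick to grid."""
    return ss.build_patch((60.0, 60.0), 62.0, 40.0, -7.0)


@pytest.fixture
def full_patch():
    return ss.build_patch()


@pytest.fixture
def single_bead_protein():
    return ProteinModel(np.zeros((1, 3)), np.array([1.0]), ["Q1"])


def make_zero_grid(half_extent=150.0, spacing=10.0, z_lo=0.0, z_hi=500.0):
    """Uniform zero potential covering a generous box."""
    nx = int(2 * half_extent / spacing) + 1
    nz = int((z_hi - z_lo) / spacing) + 1
    return es.PotentialGrid((-half_extent, -half_extent, z_lo), spacing,
                            np.zeros((nx, nx, nz)))


def make_linear_grid(coeff=1.0, half_extent=150.0, spacing=5.0,
                     z_lo=0.0, z_hi=400.0):
    """Potential Phi = coeff * z (exactly linear, so trilinear is exact)."""
    nx = int(2 * half_extent / spacing) + 1
    nz = int((z_hi - z_lo) / spacing) + 1
    zs = z_lo + spacing * np.arange(nz)
    values = np.broadcast_to(coeff * zs, (nx, nx, nz)).copy()
    return es.PotentialGrid((-half_extent, -half_extent, z_lo), spacing, values)
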