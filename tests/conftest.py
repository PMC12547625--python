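import numpy as np
import pytest

from csfdyn.io_core import GradientTable, MaskVolume, Series4D
from csfdyn.phantom import DwiPhantomSpec, gen_dwi_phantom


@pytest.fixture
def identity_affine():
    return np.eye(4)


@pytest.fixture
def small_dwi():
    """Tiny noiseless isotropic DWI phantom (7 volumes: 1 b0 + 6 directions)."""
    spec = DwiPhantomSpec(shape=(8, 8, 8), seed=1)
    return gen_dwi_phantom(spec)


def make_series(data, affine=None, tr=None):
    if affine is None:
        affine = np.eye(4)
    return Series4D(data=np.asarray(data, dtype=float), affine=affine, t_spacing=tr)


def make_mask(data, affine=None):
    if affine is None:
        affine = np.eye(4)
    return MaskVolume(data=np.asarray(data), affine=affine)
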