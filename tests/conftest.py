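"""Shared fixtures: the 5-shell protocol and a noiseless phantom pipeline.

Session-scoped because the noiseless phantom and its voxelwise DKI fit are
reused by the metric, geometry and acceptance tests.
"""

import numpy as np
import pytest

from cardiodki import build_protocol, fit_image
from cardiodki.phantom import (PhantomSpec, build_ground_truth,
                               synthesize_series)
from cardiodki.preprocessing import phase_correct_real


@pytest.fixture(scope="session")
def protocol():
    """The full in-vivo protocol: 5 shells, 30 directions x 6 repeats
    (3 x 12 at b=100), 756 measurements."""
    return build_protocol(30, 6, seed=1)


@pytest.fixture(scope="session")
def noiseless_spec():
    return PhantomSpec(snr_at_b100=None)


@pytest.fixture(scope="session")
def noiseless_truth(noiseless_spec):
    return build_ground_truth(noiseless_spec)


@pytest.fixture(scope="session")
def noiseless_real(noiseless_truth, noiseless_spec, protocol):
    """Phase-corrected real-valued noiseless series."""
    series = synthesize_series(noiseless_truth, protocol, noiseless_spec)
    return phase_correct_real(series)


@pytest.fixture(scope="session")
def noiseless_dki_fit(noiseless_real, protocol):
    """Voxelwise DKI WLS fit of the noiseless phantom."""
    return fit_image(noiseless_real.data, protocol, noiseless_real.mask,
                     model="dki")


@pytest.fixture(scope="session")
def truth_voxel(noiseless_truth):
    """Ground-truth (D, w15) of one myocardial voxel."""
    idx = tuple(np.argwhere(noiseless_truth.mask)[40])
    return noiseless_truth.D[idx], noiseless_truth.w15[idx]
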