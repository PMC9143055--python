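import numpy as np
import pytest

from msitma import MassAxis, PeakList, SpectralMatrix


def make_matrix(intensities, mz=None, run_id="run", slide_id="slide", coords=None):
    intensities = np.asarray(intensities, dtype=float)
    m, n = intensities.shape
    if mz is None:
        mz = 100.0 + 10.0 * np.arange(n)
    if coords is None:
        side = int(np.ceil(np.sqrt(m)))
        xs, ys = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
        coords = np.column_stack([xs.ravel(), ys.ravel()])[:m]
    return SpectralMatrix(run_id, slide_id, coords, intensities, MassAxis(np.asarray(mz, float)))


def make_peaklist(mz, intensity=None):
    mz = np.asarray(mz, dtype=float)
    if intensity is None:
        intensity = np.ones_like(mz)
    return PeakList(mz, np.asarray(intensity, float), np.zeros_like(mz))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
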