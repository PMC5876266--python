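import numpy as np
import pytest

from mpcpr import phantom


@pytest.fixture(scope="session")
def tube():
    """Noiseless straight tube, radius 4 mm, 1 mm isotropic."""
    spec = phantom.straight_tube_spec(radius=4.0, shape=(48, 48, 80), noise_sd=0.0)
    vol, truth = phantom.generate_phantom(spec)
    return spec, vol, truth


@pytest.fixture(scope="session")
def two_leg():
    """Noiseless lesion-free two-leg phantom with ground truth."""
    spec = phantom.PhantomSpec(noise_sd=0.0)
    vol, truth = phantom.generate_phantom(spec)
    return spec, vol, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def brute_trilinear(voxels, spacing, origin, point):
    """Independent trilinear sampler (textbook 8-corner formula)."""
    voxels = np.asarray(voxels, dtype=float)
    f = (np.asarray(point, float) - np.asarray(origin)) / np.asarray(spacing)
    out_of_range = -1024.0
    i = np.floor(f).astype(int)
    t = f - i
    acc = 0.0
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = ((t[0] if dx else 1 - t[0])
                     * (t[1] if dy else 1 - t[1])
                     * (t[2] if dz else 1 - t[2]))
                ii = i + np.array([dx, dy, dz])
                if np.all(ii >= 0) and np.all(ii < voxels.shape):
                    v = voxels[tuple(ii)]
                else:
                    v = out_of_range
                acc += w * v
    return acc
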