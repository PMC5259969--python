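import numpy as np
import pytest

from shrewid import synthetic_imaging as syn


def random_connected_mask(rng: np.random.Generator, size: int = 20) -> np.ndarray:
    """A random single-component 8-connected mask inside a size x size grid.

    Grown by repeated random dilation steps from a seed pixel, then the
    largest component of a random thinning — guaranteed non-empty and
    connected.
    """
    from scipy import ndimage

    mask = np.zeros((size, size), dtype=bool)
    r0, c0 = rng.integers(3, size - 3, size=2)
    mask[r0, c0] = True
    for _ in range(rng.integers(2, 8)):
        grow = ndimage.binary_dilation(mask, np.ones((3, 3), dtype=bool))
        keep = rng.random(mask.shape) < 0.7
        mask = mask | (grow & keep)
    mask[0, :] = mask[-1, :] = mask[:, 0] = mask[:, -1] = False
    labels, n = ndimage.label(mask, np.ones((3, 3), dtype=bool))
    if n == 0:
        mask[r0, c0] = True
        return mask
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    return labels == (int(np.argmax(sizes)) + 1)


@pytest.fixture
def rng():
    return np.random.default_rng(20160101)


@pytest.fixture(scope="session")
def noiseless_scene():
    """One clean dorsal scene whose truth mask thresholding recovers exactly."""
    params = syn.ShapeParams(view="dorsal", klass="NM", semi_axis_a=80,
                             semi_axis_b=48, roughness_amp=1.5)
    spec = syn.SceneSpec(seed=42, noise_sd=0.0, n_clutter=0)
    return syn.render_silhouette(params, spec)


@pytest.fixture(scope="session")
def separable_table():
    """Well-separated descriptor table: 30 per class, 4 SD separation."""
    return syn.generate_feature_table(
        30, syn.offsets_for_separation(4.0), syn.SceneSpec(seed=1)
    )
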