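import numpy as np
import pytest

from bovw3d.rihog3d import Patch, compute_gradients, rihog_descriptor
from bovw3d.volume_io import Volume


def descriptor_of_array(arr, n_theta=4, n_phi=8):
    """Compute the relative-orientation descriptor of a full cubic array."""
    arr = np.ascontiguousarray(arr, dtype=np.float64)
    e = arr.shape[0]
    v = Volume(arr)
    grad = compute_gradients(v)
    patch = Patch(
        center=(e // 2,) * 3, edge_len=e, intensities=arr,
        in_mask_fraction=1.0, slices=(slice(0, e),) * 3, mask=None,
    )
    return rihog_descriptor(patch, grad, n_theta=n_theta, n_phi=n_phi).bins


def grid_rotations_24(a):
    """The 24 orientation-preserving axis-aligned rotations of a cubic array."""
    from itertools import permutations

    out = []
    for perm in permutations(range(3)):
        for flips in range(8):
            P = np.zeros((3, 3))
            for i, j in enumerate(perm):
                P[i, j] = 1
            signs = [-1 if flips & (1 << i) else 1 for i in range(3)]
            if np.linalg.det(np.diag(signs) @ P) <= 0:
                continue
            b = np.transpose(a, perm)
            for i, s in enumerate(signs):
                if s < 0:
                    b = np.flip(b, axis=i)
            out.append(np.ascontiguousarray(b))
    return out


@pytest.fixture(scope="session")
def smooth_patch():
    """A smooth, mildly anisotropic synthetic patch (blob + low-frequency field)."""
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(7)
    e = 11
    zz, yy, xx = np.mgrid[:e, :e, :e] - e // 2
    base = np.exp(-(zz ** 2 / (2 * 2.0 ** 2) + yy ** 2 / (2 * 3.0 ** 2) + xx ** 2 / (2 * 2.5 ** 2)))
    base = base + 0.3 * gaussian_filter(rng.normal(size=(e, e, e)), 2.5)
    return base - base.min()


@pytest.fixture(scope="session")
def small_fit_results():
    """One small end-to-end fit shared by the pipeline-level tests."""
    from bovw3d.pipeline import PipelineConfig, run_pipeline
    from bovw3d.synthetic_fixtures import FixtureSpec, make_dataset

    records, manifest = make_dataset(FixtureSpec(n_per_class=5, seed=3))
    cfg = PipelineConfig(n_words=32, seed=3, n_folds=3)
    return records, manifest, run_pipeline(cfg, records=records)
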