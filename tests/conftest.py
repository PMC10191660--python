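import numpy as np
import pytest
from scipy import ndimage

from livoct import Alveolus, CLASS_LABELS, PhantomSpec


def uniform_class_maps(rho: float = 0.0, mu: float = 1.0):
    """Class dictionaries giving every label the same dynamics/intensity."""
    return ({k: mu for k in CLASS_LABELS}, {k: rho for k in CLASS_LABELS})


@pytest.fixture
def smooth_image():
    """A smooth positive test image (sum of Gaussian blobs on a ramp):
    band-limited, so spline shifting is accurate and invertible."""
    zz, xx = np.mgrid[0:96, 0:96].astype(float)
    img = 1.0 + 0.002 * zz + 0.001 * xx
    rng = np.random.default_rng(17)
    for _ in range(12):
        cz, cx = rng.uniform(10, 86, 2)
        img += rng.uniform(0.5, 2.0) * np.exp(
            -((zz - cz) ** 2 + (xx - cx) ** 2) / (2 * 6.0 ** 2))
    return img


@pytest.fixture
def speckle_frame_db():
    """One dB-scaled speckle frame with realistic grain and noise floor."""
    intensities, corrs = uniform_class_maps(rho=1.0)
    spec = PhantomSpec(grid_shape=(128, 128, 1), class_intensity=intensities,
                       class_correlation=corrs, seed=23)
    from livoct import build_label_map, simulate_timeseries
    from livoct.liv import to_db
    stack = simulate_timeseries(build_label_map(spec), spec, n_frames=2,
                                seed=23)[0]
    return to_db(stack.data[0], spec.noise_floor_mean)


def static_organoid_spec(seed: int = 3, shape=(96, 96, 1)) -> PhantomSpec:
    """A frozen (rho = 1 everywhere) organoid scene: the bulk-motion test
    bed, where any temporal LIV beyond the noise floor is an artifact."""
    intensities = {"background": 0.05, "lumen": 0.3, "epithelium_high": 1.0,
                   "epithelium_low": 1.0, "fibroblast": 0.5, "inclusion": 2.0}
    corrs = {k: 1.0 for k in CLASS_LABELS}
    cz, cx = shape[0] // 2, shape[1] // 2
    return PhantomSpec(grid_shape=shape, class_intensity=intensities,
                       class_correlation=corrs,
                       alveoli=[Alveolus((cz, cx, 0), 20, 6)],
                       noise_floor_mean=0.01, seed=seed)
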