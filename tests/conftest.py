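import numpy as np
import pytest

from mggdreg.mggd import MGGDComponent, PointCloud


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def iso2d():
    """Isotropic 2-D component with a sharp peak (beta = 0.5)."""
    return MGGDComponent(mean=[0.0, 0.0], scatter=np.eye(2), shape=0.5, scale=1.0)


@pytest.fixture
def gauss2d():
    """beta = 1 component: a plain bivariate Gaussian with covariance 2*Sigma."""
    return MGGDComponent(
        mean=[1.0, -2.0],
        scatter=np.array([[2.0, 0.6], [0.6, 1.0]]),
        shape=1.0,
        scale=2.0,
    )


@pytest.fixture
def blob_cloud(rng):
    """One Gaussian blob plus one far outlier."""
    pts = rng.normal(0.0, 1.0, size=(100, 2))
    pts = np.vstack([pts, [[25.0, 25.0]]])
    return PointCloud(points=pts)
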