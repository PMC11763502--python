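import numpy as np
import pytest

from flimupscale import FLIMFrame, IntensityImage, LifetimeImage, PhantomSpec, make_fixture_pair
from flimupscale.pipeline import reconstruct_frame


def make_frame(intensity, lifetime, valid=None, threshold=0.0):
    intensity = np.asarray(intensity, dtype=float)
    lifetime = np.asarray(lifetime, dtype=float)
    if valid is None:
        valid = np.ones(lifetime.shape, dtype=bool)
    return FLIMFrame(
        intensity=IntensityImage(intensity),
        lifetime=LifetimeImage(np.where(valid, lifetime, 0.0), valid),
        photon_threshold=threshold,
    )


@pytest.fixture(scope="session")
def microsphere_pair():
    """Seeded 512x512 microsphere ground truth with its 256x256 decimated input."""
    spec = PhantomSpec(scene="microspheres", image_size=512, seed=1)
    lr, hr = make_fixture_pair(spec, factor=2, mode="decimate")
    return lr, hr


@pytest.fixture(scope="session")
def microsphere_reconstructions(microsphere_pair):
    """Bicubic and EPIM reconstructions of the shared microsphere fixture."""
    lr, hr = microsphere_pair
    return {
        "bicubic": reconstruct_frame(lr, 2, "bicubic"),
        "epim": reconstruct_frame(lr, 2, "epim"),
    }
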