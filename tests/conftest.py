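import numpy as np
import pytest

from lipograin import InstanceSet


def ellipse_mask(shape, cy, cx, a, b, phi=0.0):
    """Boolean mask of pixel centers inside a rotated ellipse (a = semi-x)."""
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    dy, dx = yy - cy, xx - cx
    u = dx * np.cos(phi) + dy * np.sin(phi)
    v = -dx * np.sin(phi) + dy * np.cos(phi)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def disc_mask(shape, cy, cx, r):
    return ellipse_mask(shape, cy, cx, r, r)


def random_disc_set(rng, shape=(256, 256), n=8, r_range=(4, 9), margin=12):
    """Non-deterministic placement helper for oracle comparisons."""
    masks = []
    for _ in range(n):
        r = rng.integers(*r_range)
        cy = rng.integers(margin, shape[0] - margin)
        cx = rng.integers(margin, shape[1] - margin)
        masks.append(disc_mask(shape, cy, cx, r))
    return InstanceSet(masks, shape=shape)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
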