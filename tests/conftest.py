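import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from gammaqa import DoseGrid


def smooth_random_pair(rng, n=15, spacing=2.0, noise_pct=1.0, smooth_sigma=3.0):
    """A smooth random reference field and a noisy evaluated copy.

    The reference is low-pass-filtered noise rescaled to [10, 100] dose
    units (so the default 5% threshold keeps every point); the evaluated
    grid adds Gaussian dose noise expressed as percent of the maximum.
    """
    base = gaussian_filter(rng.normal(size=(n, n)), smooth_sigma)
    base -= base.min()
    peak = base.max()
    if peak == 0:
        base[:] = 1.0
        peak = 1.0
    ref_vals = 100.0 * (0.1 + 0.9 * base / peak)
    ev_vals = np.clip(
        ref_vals + rng.normal(0.0, noise_pct, size=(n, n)), 0.0, None
    )
    half = (n - 1) * spacing / 2.0
    geom = dict(spacing=(spacing, spacing), origin=(-half, -half))
    return DoseGrid(ref_vals, **geom), DoseGrid(ev_vals, **geom)


def uniform_grid(value=100.0, n=10, spacing=1.0):
    return DoseGrid(np.full((n, n), float(value)), (spacing, spacing), (0.0, 0.0))


@pytest.fixture
def rng():
    return np.random.default_rng(20190707)
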