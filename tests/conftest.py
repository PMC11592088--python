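import numpy as np
import pytest

from usradiomics.prep import DiscretizedROI


def make_droi(levels, mask=None, n_bins=None) -> DiscretizedROI:
    """Wrap a small integer grid (levels >= 1) as a DiscretizedROI."""
    levels = np.asarray(levels, dtype=np.int64)
    if mask is None:
        mask = levels > 0
    else:
        mask = np.asarray(mask, dtype=bool)
    n_bins = n_bins or int(levels.max())
    lv = np.where(mask, levels, 0)
    return DiscretizedROI(
        levels=lv, mask=mask, n_bins=n_bins,
        roi_min=float(lv[mask].min()), roi_max=float(lv[mask].max()),
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240)


def random_grid(rng, max_side=8, max_levels=6):
    """Random small level grid with a random (non-empty) mask."""
    h = int(rng.integers(2, max_side + 1))
    w = int(rng.integers(2, max_side + 1))
    levels = rng.integers(1, max_levels + 1, size=(h, w))
    mask = rng.random((h, w)) < 0.8
    if not mask.any():
        mask[h // 2, w // 2] = True
    return make_droi(np.where(mask, levels, 0), mask, n_bins=max_levels)
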