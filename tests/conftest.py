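import numpy as np
import pytest

from texagg.image import DiscretizedVOI
from texagg.phantom import FIXTURE_NAMES, fixture_grid


def random_voi(seed: int, shape=(4, 6, 6), n_bins: int = 4) -> DiscretizedVOI:
    """A seeded random VOI: ~70% occupancy mask, grey levels 1..n_bins."""
    rng = np.random.default_rng(seed)
    mask = rng.random(shape) < 0.7
    if not mask.any():
        mask[tuple(s // 2 for s in shape)] = True
    grey = np.zeros(shape, dtype=np.int32)
    grey[mask] = rng.integers(1, n_bins + 1, size=int(mask.sum()))
    return DiscretizedVOI(grey, mask, n_bins, 0.0, 1.0)


RANDOM_SEEDS = tuple(range(20))


@pytest.fixture(params=RANDOM_SEEDS, ids=[f"rand{s}" for s in RANDOM_SEEDS])
def rand_voi(request):
    return random_voi(request.param)


@pytest.fixture(params=FIXTURE_NAMES)
def fixture_voi(request):
    voi, _ = fixture_grid(request.param)
    return voi


@pytest.fixture()
def all_vois():
    """Every catalogue fixture plus the 20 seeded random VOIs."""
    vois = [fixture_grid(n)[0] for n in FIXTURE_NAMES]
    vois += [random_voi(s) for s in RANDOM_SEEDS]
    return vois
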