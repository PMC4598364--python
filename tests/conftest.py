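import numpy as np
import pytest

import floravision as fv
from floravision.spectra import STANDARD_GRID


@pytest.fixture
def flat(request):
    """Constant reflectance spectrum on the standard grid."""

    def make(level=0.5, accession="flat"):
        return fv.Spectrum(STANDARD_GRID.copy(), np.full(STANDARD_GRID.size, level),
                           accession_id=accession)

    return make


@pytest.fixture(scope="session")
def leaf_background():
    """Smoothed synthetic average-leaf spectrum (the adapting background)."""
    return fv.smooth(fv.make_leaf_background())


@pytest.fixture(scope="session")
def bee_system(leaf_background):
    return fv.bee_visual_system(leaf_background)


@pytest.fixture(scope="session")
def bird_system(leaf_background):
    return fv.hummingbird_visual_system(leaf_background)


def random_distance_matrix(rng, n, dims=3, labels=None):
    """Euclidean distance matrix of random points (valid metric, no ties a.s.)."""
    from floravision.categories import euclidean_distances

    pts = rng.random((n, dims))
    labels = labels or [f"s{i}" for i in range(n)]
    return euclidean_distances(pts, labels=labels)
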