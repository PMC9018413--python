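import numpy as np
import pytest

import hemastate as hs
from hemastate.synthetic import gen_reference_cells, random_atlas_spec


@pytest.fixture(scope="session")
def atlas3():
    """Small 3-type atlas with shared background (for atlas/deconvolution)."""
    spec = random_atlas_spec(n_types=3, n_genes=400, cells_per_type=100, seed=1)
    return spec, gen_reference_cells(spec)


@pytest.fixture(scope="session")
def profiles3(atlas3):
    spec, cells = atlas3
    kept = hs.qc_filter(cells)
    return hs.build_profiles(kept, spec.lineage_tags)


@pytest.fixture(scope="session")
def atlas6():
    """Six-type atlas used for matcher training (well-separated programs)."""
    spec = random_atlas_spec(n_types=6, n_genes=400, cells_per_type=100,
                             seed=5)
    cells = gen_reference_cells(spec)
    norm = hs.normalize_log1p(hs.qc_filter(cells))
    return spec, norm


@pytest.fixture(scope="session")
def matcher6(atlas6):
    """Matcher trained on 70% of the 6-type atlas plus its held-out cells.

    Session-scoped: elastic-net CV is the most expensive fit in the suite.
    """
    _spec, norm = atlas6
    rng = np.random.default_rng(5)
    hold = rng.random(norm.n_cells) < 0.3
    train = norm.subset_cells(~hold)
    test = norm.subset_cells(hold)
    model = hs.train_matcher(train, folds=5, n_lambdas=10, seed=5)
    return model, train, test
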