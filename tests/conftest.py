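import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def sort_spec():
    """Default sorted-pool scenario: 3,000 scaffolds, 12% X-linked,
    10% impurity in pool 0 — the regime in which the P0 distribution is
    clearly bimodal with modes near 0.1 and 0.5."""
    from fasterx.synth import SortSpec

    return SortSpec(
        n_scaffolds=3000,
        frac_x=0.12,
        impurity0=0.10,
        impurityX=0.02,
        depth_per_pool=1_000_000.0,
        seed=101,
    )
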