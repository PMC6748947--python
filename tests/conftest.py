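import numpy as np
import pytest

from loopfit.io_contacts import BinAnnotation, BinnedContactMap
from loopfit.simulate import FixtureSpec, make_fixture


@pytest.fixture(scope="session")
def small_fixture():
    """Well-specified fixture with 20 implanted 8x loops (seed 1)."""
    return make_fixture(FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def null_fixture():
    """Same generator with no implants."""
    return make_fixture(FixtureSpec(seed=1, n_loops=0))


@pytest.fixture(scope="session")
def enriched_fixture():
    """Fixture whose peak bins carry a 3x coverage multiplier (PP enrichment)."""
    return make_fixture(FixtureSpec(seed=2, peak_multiplier=3.0))


@pytest.fixture()
def tiny_map():
    """Hand-built two-chromosome map at 5 kb."""
    cmap = BinnedContactMap(binsize=5000)
    cmap.add("chr1", 4, 10, 2)
    cmap.add("chr1", 4, 12, 1)
    cmap.add("chr2", 0, 8, 3)
    return cmap


@pytest.fixture()
def tiny_ann():
    ann = BinAnnotation(binsize=5000, n_bins={"chr1": 20, "chr2": 10})
    ann.peak_flags["chr1"][4] = True
    ann.peak_flags["chr1"][10] = True
    return ann
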