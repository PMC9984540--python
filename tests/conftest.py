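import dataclasses

import pytest

from pgti import BootstrapSpec, load_preset
from pgti.physics import Slab

# fixed once, before any outcome was inspected at this seed
SEED = 20251002


@pytest.fixture(scope="session")
def medicyc():
    return load_preset("medicyc_63mev")


@pytest.fixture(scope="session")
def s2c2():
    return load_preset("s2c2_148mev")


@pytest.fixture(scope="session")
def s2c2_with_gap(s2c2):
    """S2C2 beam/detectors on a thin target + air gap + thick target stack."""
    return dataclasses.replace(
        s2c2,
        slabs=[Slab("PMMA", 1.0), Slab("air", 0.5), Slab("PMMA", 23.0)],
        gap_index=1)


@pytest.fixture
def fast_bootstrap():
    """Reduced toy count for unit tests (full spec runs in acceptance)."""
    return BootstrapSpec(n_toys=400, subsample_sizes=(30, 60, 90, 120),
                         target_n=600)
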