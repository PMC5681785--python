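import numpy as np
import pytest

from chromoquant import (
    FociParams,
    SegmentationParams,
    SimConfig,
    generate_field,
    max_project,
    segment_foci,
    segment_nuclei,
)


@pytest.fixture(scope="session")
def small_field():
    """A small synthetic field shared across read-only tests: 12 nuclei
    with foci, fixed seed."""
    cfg = SimConfig(
        field_shape=(256, 256), n_nuclei=12, n_z=12, seed=42,
    )
    stack, truth = generate_field(cfg)
    return cfg, stack, truth


@pytest.fixture(scope="session")
def segmented_field(small_field):
    """The shared field taken through projection + both segmentations."""
    cfg, stack, truth = small_field
    dapi = max_project(stack, "dapi")
    mark = max_project(stack, "mark")
    nuclei = segment_nuclei(dapi, SegmentationParams())
    foci = segment_foci(mark, nuclei, FociParams())
    return cfg, stack, truth, dapi, mark, nuclei, foci


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
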