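"""Shared fixtures: a hand-built toy genome and a desk-scale synthetic atlas."""

import numpy as np
import pytest

from cfmeth.genome import GenomeCpGIndex
from cfmeth.pipeline import ReferencePipeline
from cfmeth.synthetic import AtlasSpec, SyntheticAtlas


@pytest.fixture(scope="session")
def toy_genome() -> GenomeCpGIndex:
    """Two chromosomes, 12 + 8 CpGs at hand-picked positions."""
    return GenomeCpGIndex(
        ("chr1", "chr2"),
        (
            np.array([10, 15, 22, 30, 41, 55, 70, 88, 100, 120, 150, 170]),
            np.array([5, 9, 14, 40, 60, 100, 140, 200]),
        ),
    )


@pytest.fixture(scope="session")
def small_spec() -> AtlasSpec:
    """Scaled-down atlas: 600 blocks, 50 private hypomethylated per type."""
    return AtlasSpec(n_blocks=600, n_private_per_type=50)


@pytest.fixture(scope="session")
def small_atlas(small_spec) -> SyntheticAtlas:
    return SyntheticAtlas(small_spec)


@pytest.fixture(scope="session")
def small_pipeline(small_atlas) -> ReferencePipeline:
    """Reference cohort at 20x with min-3-CpG segmentation."""
    return ReferencePipeline.build(small_atlas, coverage=20.0, min_cpgs=(3,), seed=5)
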