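"""Shared fixtures: small synthetic cohorts generated at test time."""

import numpy as np
import pytest

from atroseq.synthetic_cohort import CohortConfig, RegionSpec, generate_cohort


def small_regions():
    """Three disjoint 4x4x4 blocks on an 18x18x6 grid, staggered onsets."""
    return (
        RegionSpec("regA", onset=5.0, width=4.0, box=((2, 6), (2, 6), (1, 5))),
        RegionSpec("regB", onset=9.0, width=4.0, box=((12, 16), (2, 6), (1, 5))),
        RegionSpec("regC", onset=13.0, width=4.0, box=((7, 11), (11, 15), (1, 5))),
    )


@pytest.fixture(scope="session")
def small_cfg():
    return CohortConfig(
        n_patients=60, n_controls=40, grid_shape=(18, 18, 6),
        regions=small_regions(), noise_sd=0.02, rng_seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    """(records, maps, truth) for the small 3-region cohort."""
    return generate_cohort(small_cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
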