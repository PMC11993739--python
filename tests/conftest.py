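"""Shared fixtures: small synthetic datasets sized for fast unit tests."""

from __future__ import annotations

import numpy as np
import pytest

from virtualhic.coords import GenomicRegion
from virtualhic.io_formats import ContactMap
from virtualhic.synthetic import (
    SimulationConfig,
    chrom_region,
    simulate_contact_map,
    simulate_tracks_and_states,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cfg():
    """A 3-Mb single-chromosome genome: 600 bins of 5 kb."""
    return SimulationConfig(
        seed=7,
        chrom_lengths={"chr1": 3_000_000},
        n_tracks=6,
        track_resolution=25,
    )


@pytest.fixture(scope="session")
def small_map(small_cfg):
    return simulate_contact_map(small_cfg, chrom_region(small_cfg, "chr1"))


@pytest.fixture(scope="session")
def small_tracks_states(small_cfg, small_map):
    return simulate_tracks_and_states(
        small_cfg, chrom_region(small_cfg, "chr1"), small_map
    )


def random_symmetric_map(rng, n=30, chrom="chrT", bin_size=5000) -> ContactMap:
    m = rng.normal(size=(n, n))
    m = 0.5 * (m + m.T)
    region = GenomicRegion(chrom, 0, n * bin_size)
    return ContactMap(region, bin_size, m, np.ones((n, n), dtype=bool))


@pytest.fixture
def symmetric_map(rng):
    return random_symmetric_map(rng)
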