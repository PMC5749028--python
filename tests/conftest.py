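import numpy as np
import pytest

import triadgen as tg


@pytest.fixture(scope="session")
def tiny_source():
    """Small block-LD triad panel shared across tests (no rare SNPs)."""
    rng = np.random.default_rng(20240915)
    chroms = tg.make_chromosomes(
        n_chromosomes=2, n_snps_per_chrom=40, block_size=10,
        rare_fraction=0.0, rng=rng,
    )
    ds = tg.generate_source(120, chroms, rng)
    return ds


@pytest.fixture(scope="session")
def tiny_pool(tiny_source):
    triads = tg.build_triads(tiny_source.samples)
    pool, report = tg.build_pool(
        tiny_source.marker_map, tiny_source.samples, tiny_source.genotypes, triads
    )
    return pool, report


@pytest.fixture(scope="session")
def tiny_track(tiny_source):
    return tg.hotspots_to_boundaries(tiny_source.hotspots, tiny_source.marker_map)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
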