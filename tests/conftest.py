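import numpy as np
import pytest

from atacsim import (
    FragmentSet,
    GenomeLayout,
    ParentConfig,
    PeakSet,
    generate_parent_sample,
    make_bins,
)


@pytest.fixture
def small_layout():
    return GenomeLayout(("chr1", "chr2"), (100_000, 50_000))


@pytest.fixture
def toy_config():
    """Small genome for plumbing and conservation tests (fast to generate)."""
    return ParentConfig(
        chromosome_lengths=(10_000_000, 10_000_000),
        n_peaks=500,
        library_size=200_000,
        target_frip=0.50,
        inaccessible_block_fraction=0.06,
        inaccessible_block_width=120_000,
        peak_intensity_dispersion=2.0,
        seed=7,
    )


@pytest.fixture
def toy_parent(toy_config):
    return generate_parent_sample(toy_config)


@pytest.fixture(scope="session")
def default_parent():
    """One parent at the default (realistic-regime) configuration."""
    return generate_parent_sample(ParentConfig(seed=11))


def make_fragments(layout, records):
    """records: list of (chrom, start, end)."""
    chrom = np.array([layout.index(c) for c, _, _ in records], dtype=np.int32)
    start = np.array([s for _, s, _ in records], dtype=np.int64)
    end = np.array([e for _, _, e in records], dtype=np.int64)
    return FragmentSet(layout, chrom, start, end)


def make_peaks(layout, records):
    chrom = np.array([layout.index(c) for c, _, _ in records], dtype=np.int32)
    start = np.array([s for _, s, _ in records], dtype=np.int64)
    end = np.array([e for _, _, e in records], dtype=np.int64)
    return PeakSet(layout, chrom, start, end)
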