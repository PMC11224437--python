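import pytest

from tephrimark.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """6-taxon, 12-locus seeded simulation shared by read-only tests."""
    cfg = SimConfig(
        n_taxa=6,
        n_loci=12,
        background_length=25_000,
        locus_length_mean=500,
        locus_length_sd=80,
        seed=11,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def clean_dataset():
    """No dropout, shallow divergence: every locus present in every taxon."""
    cfg = SimConfig(
        n_taxa=6,
        n_loci=10,
        dropout_prob=0.0,
        tree_depth=0.05,
        background_length=25_000,
        locus_length_mean=500,
        locus_length_sd=50,
        seed=23,
    )
    return simulate_dataset(cfg)
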