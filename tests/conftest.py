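import numpy as np
import pytest

from panelseq.fixtures import FixtureConfig, generate_study


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def small_config(seed: int = 11, **overrides) -> FixtureConfig:
    """A ~270-kb study that generates in well under a second."""
    defaults = dict(
        chrom_lengths={
            "chr1": 74_800,
            "chr2": 59_300,
            "chr3": 59_900,
            "chr4": 48_600,
            "chr5": 28_400,
        },
        accession_density={f"acc{i}": 60.0 for i in range(1, 9)},
        shared_snp_per_100kb=25.0,
        panel_targets={"chr1": 4, "chr2": 3, "chr3": 3, "chr4": 2, "chr5": 2},
        amplicon_total_reads=40_000,
    )
    defaults.update(overrides)
    return FixtureConfig(seed=seed, **defaults)


@pytest.fixture(scope="session")
def small_bundle():
    return generate_study(small_config())


@pytest.fixture(scope="session")
def default_bundle():
    """The full default synthetic study (1/100-scale genome)."""
    return generate_study(FixtureConfig(seed=7))
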