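import numpy as np
import pytest

from cswitch.coverage import normalize_rpm
from cswitch.synthetic_data import SyntheticConfig, simulate


@pytest.fixture(scope="session")
def default_dataset():
    """The standard study conditions: 200 SMAD sites, half co-bound,
    delta=1, rho=0.5, 3 replicates at 1e6 reads."""
    return simulate(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def null_dataset():
    """No planted binding effect (delta=0, rho=0) over 500 sites, for
    type-I calibration."""
    return simulate(
        SyntheticConfig(
            seed=12,
            dependence_effect_delta=0.0,
            relocation_fraction_rho=0.0,
            n_smad_sites=500,
            n_genes=60,
            repressed_set_sizes=(10, 10, 4),
        )
    )


@pytest.fixture(scope="session")
def small_dataset():
    """A fast miniature dataset for plumbing-level tests."""
    return simulate(
        SyntheticConfig(
            seed=13,
            n_smad_sites=24,
            n_genes=40,
            repressed_set_sizes=(8, 8, 4),
        )
    )


@pytest.fixture(scope="session")
def norm_tracks(default_dataset):
    """RPM-normalized SMAD tracks of the default dataset, per genotype."""
    n = default_dataset.config.n_replicates
    return {
        geno: [
            normalize_rpm(default_dataset.tracks[("smad", geno, r)])
            for r in range(n)
        ]
        for geno in ("wt", "ko")
    }


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
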