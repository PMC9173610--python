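import numpy as np
import pytest

from trophicmix._sampler import MCMCSettings
from trophicmix.dataset import CommunityDataset, IsotopeSample


@pytest.fixture(scope="session")
def tiny_mcmc() -> MCMCSettings:
    """Short chains for unit tests of sampler-backed operations."""
    return MCMCSettings(chains=3, adapt=1500, iterations=6000,
                        burn_in=1500, thin=5)


@pytest.fixture(scope="session")
def recovery_mcmc() -> MCMCSettings:
    """Mid-length chains for parameter-recovery suites."""
    return MCMCSettings(chains=3, adapt=2000, iterations=8000,
                        burn_in=2000, thin=6)


@pytest.fixture
def toy_dataset() -> CommunityDataset:
    samples = [
        IsotopeSample("Aaa", "Taxon A", "Actinopterygii", -17.4, 12.6, 45.0, 12.0),
        IsotopeSample("Aaa", "Taxon A", "Actinopterygii", -17.2, 12.8, 44.0, 12.5),
        IsotopeSample("Bbb", "Taxon B", "Decapoda", -16.0, 13.5, 40.0, 11.0),
    ]
    return CommunityDataset.from_samples(samples)


@pytest.fixture(scope="session")
def study_pair():
    """Scallop + retro-calculated pelagic baseline pair (seeded)."""
    from trophicmix.study import build_study_baselines

    return build_study_baselines(seed=1)


@pytest.fixture(scope="session")
def flat_baselines():
    """Well-separated baselines with modest spread, for synthetic fits."""
    rng = np.random.default_rng(42)
    ben = [IsotopeSample("BEN", "benthic", "Baseline", float(c), float(n))
           for c, n in zip(rng.normal(-17.9, 0.2, 21), rng.normal(10.1, 0.4, 21))]
    pel = [IsotopeSample("PEL", "pelagic", "Baseline", float(c), float(n))
           for c, n in zip(rng.normal(-20.4, 0.3, 50), rng.normal(8.6, 0.3, 50))]
    from trophicmix.baselines import build_baseline_pair

    return build_baseline_pair(ben, pel, 2.0)
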