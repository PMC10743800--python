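import numpy as np
import pytest

from projage.harness import ChannelDataset, make_splits
from projage.phantom import PhantomConfig, generate_cohort
from projage.volume_io import GreyMatterVolume, SubjectRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_volume(rng, shape, sparsity=0.3):
    """Random likelihood volume with a sprinkling of exact zeros, so support
    hulls and slice ranks are nontrivial."""
    values = rng.random(shape)
    values[rng.random(shape) < sparsity] = 0.0
    return GreyMatterVolume(values)


@pytest.fixture(scope="session")
def phantom_cohort():
    """The desk-scale study cohort: 200 phantoms at default conditions."""
    return generate_cohort(200, PhantomConfig(seed=7))


@pytest.fixture(scope="session")
def phantom_dataset(phantom_cohort):
    records = [SubjectRecord(s.subject_id, s.recorded_age, "in-memory") for s in phantom_cohort]
    volumes = {s.subject_id: s.volume for s in phantom_cohort}
    dataset = ChannelDataset(records, volumes=volumes)
    plan = make_splits([s.subject_id for s in phantom_cohort], seed=7)
    return dataset, plan
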