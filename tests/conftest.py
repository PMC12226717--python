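import numpy as np
import pytest

from multiglau.core.types import ClinicalRecord, Dataset, ImageBundle
from multiglau.synthetic import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort() -> Dataset:
    """Mixed healthy/glaucoma cohort with images, shared across tests."""
    return generate_cohort(CohortSpec(n=60, healthy_fraction=0.5, seed=7,
                                      image_size=32))


@pytest.fixture(scope="session")
def staged_cohort() -> Dataset:
    """Glaucoma-only cohort (all samples carry stage labels and images)."""
    return generate_cohort(CohortSpec(n=80, healthy_fraction=0.0, seed=11,
                                      image_size=32))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(123)


def make_record(i: int = 0, **kw) -> ClinicalRecord:
    defaults = dict(sample_id=f"r{i}", age=60.0, gender="female", bcva=0.8,
                    iop=18.0, cdr=0.5)
    defaults.update(kw)
    return ClinicalRecord(**defaults)
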