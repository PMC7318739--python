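"""Shared fixtures.

The full-cohort study (21 animals, all stages) is expensive (~1 min), so it
is generated once per session and shared by the pipeline and acceptance
tests. The seed is the package's canonical example seed.
"""

import pytest
from hypothesis import settings

from brainfluid.pipeline import run_study

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from brainfluid.synthetic import PhantomSpec, make_study

STUDY_SEED = 1


@pytest.fixture(scope="session")
def study_spec() -> PhantomSpec:
    return PhantomSpec(seed=STUDY_SEED)


@pytest.fixture(scope="session")
def study_dataset(study_spec):
    return make_study(study_spec)


@pytest.fixture(scope="session")
def study_report(study_dataset):
    return run_study(study_dataset)
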