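import dataclasses

import pytest

from ogttphen.simulate import GeneratorParams, generate_cohort, generate_fixture


@pytest.fixture(scope="session")
def tiny_fixture():
    return generate_fixture("tiny")


@pytest.fixture(scope="session")
def tiny_cohort(tiny_fixture):
    return tiny_fixture.cohort


@pytest.fixture(scope="session")
def paper_like_fixture():
    return generate_fixture("paper_like")


@pytest.fixture(scope="session")
def paper_like_cohort(paper_like_fixture):
    return paper_like_fixture.cohort


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(GeneratorParams(n=138, seed=0))


@pytest.fixture(scope="session")
def large_cohort():
    return generate_cohort(dataclasses.replace(GeneratorParams(), n=2000, seed=42))
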