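import pytest

from mcda import fixtures


@pytest.fixture(scope="session")
def criteria():
    return fixtures.study_criteria()


@pytest.fixture(scope="session")
def values():
    return fixtures.study_values()


# function-scoped: several tests mutate assignments in place
@pytest.fixture
def matrix_unweighted():
    return fixtures.study_matrix("unweighted")


@pytest.fixture
def matrix_weighted():
    return fixtures.study_matrix("weighted")
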