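import pytest
from hypothesis import settings

from flscea import default_parameters

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def base_params():
    """The published base case (treat as read-only; copy before mutating)."""
    return default_parameters()


@pytest.fixture()
def params(base_params):
    """A private deep copy safe to mutate."""
    return base_params.model_copy(deep=True)
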