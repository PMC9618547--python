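import pytest
from hypothesis import settings

from smacea import base_case_spec, compare_all

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def base_spec():
    return base_case_spec()


@pytest.fixture(scope="session")
def base_result(base_spec):
    """Deterministic base-case run shared across tests (read-only)."""
    return compare_all(base_spec)


@pytest.fixture()
def spec():
    """A fresh, mutable copy of the base-case specification."""
    return base_case_spec()
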