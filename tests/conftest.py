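import warnings

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture()
def compound1():
    from ligandconf.shiftlist import load_compound

    return load_compound(1)


@pytest.fixture()
def compound2():
    from ligandconf.shiftlist import load_compound

    return load_compound(2)


@pytest.fixture()
def compound3():
    from ligandconf.shiftlist import load_compound

    return load_compound(3)


@pytest.fixture()
def quiet_rotamer_warnings():
    """The compound-2 list legitimately warns about its printed tag typos."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield
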