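import pytest

from circuitbo import build_model


@pytest.fixture(scope="session")
def toy_model():
    return build_model("toy")


@pytest.fixture(scope="session")
def glucaric_model():
    return build_model("glucaric_acid")


@pytest.fixture(scope="session")
def fatty_model():
    return build_model("fatty_acid")


@pytest.fixture(scope="session")
def pas_model():
    return build_model("p_aminostyrene")
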