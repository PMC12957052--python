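import pytest

from mptfoils import (
    build_recognition_model,
    build_source_model,
    run_experiment1,
    run_experiment2,
)


@pytest.fixture(scope="session")
def recognition():
    return build_recognition_model()


@pytest.fixture(scope="session")
def source():
    return build_source_model()


@pytest.fixture(scope="session")
def exp1_report():
    return run_experiment1(starts=20, seed=1)


@pytest.fixture(scope="session")
def exp2_report():
    return run_experiment2(starts=20, seed=1)
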