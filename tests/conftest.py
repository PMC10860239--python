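import pytest

from stroke_cea import load_model_config


@pytest.fixture(scope="session")
def params():
    """The packaged base-case parameter set."""
    return load_model_config()


@pytest.fixture(scope="session")
def arm_results(params):
    """Base-case two-arm model results (computed once)."""
    from stroke_cea import run_arm

    return {
        "intervention": run_arm("intervention", params),
        "comparator": run_arm("comparator", params),
    }
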