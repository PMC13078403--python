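import pytest

from relapsehta import fixture_aud, fixture_oud


@pytest.fixture(scope="session")
def aud_inputs():
    return fixture_aud()


@pytest.fixture(scope="session")
def oud_inputs():
    return fixture_oud()


@pytest.fixture(scope="session")
def model_inputs(aud_inputs, oud_inputs):
    return {"aud": aud_inputs, "oud": oud_inputs}


def assert_close_published(actual, printed, rel=0.10, abs_small=15.0,
                           small_cutoff=200.0):
    """Reproduction band for published model outputs.

    Unprinted modelling conventions (baseline mortality level, cycle
    accrual points, charging rule) limit agreement to about +/-10 percent
    relative, or +/-15 GBP absolute for money values under 200 GBP.
    """
    tol = max(rel * abs(printed),
              abs_small if abs(printed) < small_cutoff else 0.0)
    assert abs(actual - printed) <= tol, (
        f"{actual!r} not within {tol:g} of published {printed!r}")
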