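import pytest

from phytosynergy import load_fixtures, load_response_table, ResponseSurfaceModel


@pytest.fixture(scope="session")
def bundle():
    return load_fixtures()


@pytest.fixture(scope="session")
def ethanol_fits():
    """Fitted full-quadratic surfaces for the three ethanol responses."""
    return {
        response: ResponseSurfaceModel.from_response_table(
            load_response_table("ethanol", response)
        ).fit()
        for response in ("yield", "phenolic", "flavonoid")
    }
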