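import logging

import pytest

from catifunnel import (
    ExpressionSimSpec,
    RunConfig,
    VariantSimSpec,
    simulate_expression,
    simulate_variant_callsets,
)

logging.getLogger("catifunnel").setLevel(logging.WARNING)


@pytest.fixture()
def config():
    return RunConfig()


@pytest.fixture(scope="session")
def expression_bundle():
    """Default synthetic two-strain expression experiment with truth."""
    return simulate_expression(ExpressionSimSpec())


@pytest.fixture(scope="session")
def variant_bundle():
    """Default synthetic paired-assembly call sets with panel and truth."""
    spec = VariantSimSpec()
    case_a, case_b, panel, truth = simulate_variant_callsets(spec)
    return spec, case_a, case_b, panel, truth
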