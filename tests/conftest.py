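import pytest
from hypothesis import settings

import wptaxsim as w

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def egypt() -> w.Market:
    return w.egypt_market()


@pytest.fixture(scope="session")
def egypt_mort() -> w.MortalityAssumptions:
    return w.egypt_mortality()


@pytest.fixture()
def toy_market() -> w.Market:
    """Two hand-sized segments with easy arithmetic."""
    return w.Market(
        segments=(
            w.MarketSegment(name="cheap", share=0.6, base_price=1.0,
                            elasticity=-0.5, cif=0.2, advalorem_rate=1.0),
            w.MarketSegment(name="premium", share=0.4, base_price=4.0,
                            elasticity=-0.8, cif=0.5, duty_rate=0.1,
                            advalorem_rate=2.0),
        ),
        base_quantity=1e6,
        name="toy",
    )
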