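import pandas as pd
import pytest

from musselskill import GeneratorConfig, SiteConfig


@pytest.fixture
def site():
    """A mid-latitude Pacific shore site with three loggers."""
    return SiteConfig(site_id="testsite", latitude=38.3, longitude=-123.07, utc_offset=-8)


@pytest.fixture
def short_config():
    """Two synthetic weeks at 10-min cadence — enough tides for pairing tests."""
    return GeneratorConfig(seed=7, start="2007-07-01", end="2007-07-15")


@pytest.fixture
def hourly_index():
    return pd.date_range("2007-07-01", periods=24 * 7, freq="1h")
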