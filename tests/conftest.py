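import pytest

from fermsplit import STRAIN_PRESETS, build_model, table2_fixtures


@pytest.fixture(scope="session")
def glucose_model():
    return build_model(STRAIN_PRESETS["SH9*_ZG"], "glucose")


@pytest.fixture(scope="session")
def gluconate_model():
    return build_model(STRAIN_PRESETS["SH9*"], "gluconate")


@pytest.fixture(scope="session")
def panel():
    """Strain-panel fixtures keyed by sample id."""
    return {m.sample_id: m for m in table2_fixtures()}
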