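import pytest
from hypothesis import settings

from tbinhale import pipeline

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def dose_report():
    """One full dose-translation run (three PBPK simulations), shared across
    tests to keep the suite fast."""
    return pipeline.run_dose_translation()


@pytest.fixture(scope="session")
def api_contexts():
    """Per-API (profile, physiology, rescaled params) from the default chain."""
    from tbinhale.compounds import APIS, load_compound
    from tbinhale.physiology import study_subject

    out = {}
    for api in APIS:
        out[api] = pipeline.simulate_api(load_compound(api), study_subject(api))
    return out
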