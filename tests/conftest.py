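import pytest

import strokesim as ss


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic input bundle used across the suite."""
    return ss.generate_bundle(seed=1)


@pytest.fixture(scope="session")
def effects():
    return ss.load_effects()


@pytest.fixture(scope="session")
def incidence_table(bundle):
    return ss.estimate_from_bundle(bundle)


@pytest.fixture(scope="session")
def baseline_tts(bundle, incidence_table):
    return ss.build_transition_tables(
        bundle.mortality, incidence_table, bundle.case_fatality
    )


@pytest.fixture(scope="session")
def baseline_run(bundle, incidence_table):
    return ss.run_scenario(bundle, "baseline", 10, incidence_table=incidence_table)
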