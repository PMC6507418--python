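import pytest

from coligoseq import EndProfile, LibraryPrepConfig, load_catalog


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


@pytest.fixture(scope="session")
def dcr3(catalog):
    return catalog.template("Dcr3")


@pytest.fixture(scope="session")
def coligo122(catalog):
    return catalog.template("122")


@pytest.fixture()
def clean_config():
    """Deterministic-path config: everything efficient, no errors."""
    return LibraryPrepConfig(
        seed=11,
        adapter3_ligation_efficiency=1.0,
        circularization_efficiency=1.0,
        substitution_error_rate=0.0,
        nontemplated_first_base_rate=0.0,
    )


@pytest.fixture(scope="session")
def dcr3_profile():
    """Start/stop sites whose every combination yields a 60-69 nt monomer."""
    return EndProfile(
        start_dist={30: 0.9, 28: 0.1},
        stop_dist={51: 0.25, 49: 0.20, 48: 0.25, 46: 0.20, 44: 0.10},
    )
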