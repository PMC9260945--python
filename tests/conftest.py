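import pandas as pd
import pytest

from ipscreen import datasets, docking, library, reactivity


@pytest.fixture(scope="session")
def compounds():
    return library.read_compound_table(datasets.fixture_path("compounds"))


@pytest.fixture(scope="session")
def compounds_by_id(compounds):
    return {c.id: c for c in compounds}


@pytest.fixture(scope="session")
def physchem_reference():
    return pd.read_csv(
        datasets.fixture_path("physchem_reference"), sep="\t", comment="#"
    )


@pytest.fixture(scope="session")
def frontier_energies():
    return reactivity.read_frontier_energies(datasets.fixture_path("frontier_energies"))


@pytest.fixture(scope="session")
def reactivity_reference():
    return pd.read_csv(
        datasets.fixture_path("reactivity_reference"), sep="\t", comment="#"
    )


@pytest.fixture(scope="session")
def dock_scores():
    return pd.concat(
        [
            docking.read_dock_scores(datasets.fixture_path("fdps_dock_scores")),
            docking.read_dock_scores(datasets.fixture_path("pde3b_dock_scores")),
        ],
        ignore_index=True,
    )


@pytest.fixture(scope="session")
def fdps_contacts():
    return docking.read_hbond_contacts(datasets.fixture_path("fdps_hbond_contacts"))
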