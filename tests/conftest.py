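from importlib import resources
from pathlib import Path

import pytest

from oligodsd.panel import load_panel
from oligodsd.network import load_interaction_fixture
from oligodsd.variant_io import load_cohort_fixture


def data_path(name: str) -> Path:
    return Path(str(resources.files("oligodsd").joinpath(f"data/{name}")))


@pytest.fixture(scope="session")
def cohort():
    """The packaged eight-patient MAMLD1-carrier cohort."""
    return load_cohort_fixture()


@pytest.fixture(scope="session")
def panel41():
    """The 41-gene panel restricted to genes with candidate variants."""
    return load_panel(data_path("panel_41_cohort.tsv"))


@pytest.fixture(scope="session")
def interaction_graph():
    return load_interaction_fixture()


@pytest.fixture(scope="session")
def cohort_genes(cohort):
    return {v.gene for p in cohort for v in p.variants}
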