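import pytest

from cultev import IsolateCategory, TaxonProfile


@pytest.fixture
def iiia_category() -> IsolateCategory:
    """A low-probability, high-value isolate: i = 500,000, cP = 1.46%."""
    return IsolateCategory("SAR11_IIIa", 500_000, 0.0146, 1)


@pytest.fixture
def himb11_category() -> IsolateCategory:
    """A moderate-probability, lower-value isolate: i = 50,000, cP = 28.2%."""
    return IsolateCategory("HIMB11", 50_000, 0.282, 1)


@pytest.fixture
def two_isolate_project(iiia_category, himb11_category):
    return [iiia_category, himb11_category]


@pytest.fixture
def community_tsv(tmp_path):
    path = tmp_path / "community.tsv"
    path.write_text(
        "# synthetic two-taxon community\n"
        "taxon_id\trelative_abundance\n"
        "SAR11_IIIa\t0.20\n"
        "HIMB11\t0.05\n"
    )
    return str(path)


@pytest.fixture
def catalog_tsv(tmp_path):
    path = tmp_path / "catalog.tsv"
    path.write_text(
        "taxon_id\ti_value\tcp\n"
        "SAR11_IIIa\t500000\t0.0146\n"
        "HIMB11\t50000\t0.282\n"
    )
    return str(path)


@pytest.fixture
def scenario_tsv(tmp_path):
    path = tmp_path / "scenario.tsv"
    path.write_text(
        "label\ti_value\tcp\tcount\n"
        "SAR11_IIIa\t500000\t0.0146\t1\n"
        "HIMB11\t50000\t0.282\t1\n"
    )
    return str(path)


@pytest.fixture
def small_community():
    return [TaxonProfile("SAR11_IIIa", 0.20), TaxonProfile("HIMB11", 0.05)]
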