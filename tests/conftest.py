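import pytest

from ramdecode import fixtures


@pytest.fixture(scope="session")
def models():
    return fixtures.gene_models()


@pytest.fixture(scope="session")
def slices():
    return fixtures.reference_slices()


@pytest.fixture(scope="session")
def sites_df():
    return fixtures.sites_table()


@pytest.fixture(scope="session")
def study():
    """(panel, genotype matrix, truth phase) for the packaged 96-ram panel."""
    return fixtures.study_panel()


@pytest.fixture(scope="session")
def decode_result(study):
    from ramdecode.pipeline import decode_panel

    panel, matrix, _ = study
    return decode_panel(matrix, panel)
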