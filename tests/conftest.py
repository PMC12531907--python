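import pytest

import hemotyper as ht
from hemotyper import concordance as conc
from hemotyper.io import read_serology
from hemotyper.pipeline import run_inference


@pytest.fixture(scope="session")
def panel():
    return ht.load_panel()


@pytest.fixture(scope="session")
def fixture_cohort(panel):
    return ht.published_fixture(panel)


@pytest.fixture(scope="session")
def fixture_paths(fixture_cohort, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("fixture")
    return fixture_cohort.write(str(outdir))


@pytest.fixture(scope="session")
def fixture_result(fixture_paths, panel):
    return run_inference(fixture_paths["vcf"], fixture_paths["depth"], panel)


@pytest.fixture(scope="session")
def fixture_serology(fixture_paths, panel):
    return read_serology(fixture_paths["serology"], panel)


@pytest.fixture(scope="session")
def fixture_report(fixture_result, fixture_serology, panel):
    return conc.summarize(fixture_result.predictions, fixture_serology, panel)
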