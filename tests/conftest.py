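import logging

import pytest

from rgenevo.pipeline import PipelineConfig, run_pipeline
from rgenevo.synthetic_data import SimConfig, generate_cohort, write_cohort

logging.getLogger("rgenevo.paleo").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_cohort():
    """The default study conditions: 4 species, one biased WGD, tandem
    arrays, transpositions, planted miRNA targets."""
    return generate_cohort(SimConfig())


@pytest.fixture(scope="session")
def cohort_dir(default_cohort, tmp_path_factory):
    d = tmp_path_factory.mktemp("cohort")
    write_cohort(default_cohort, d)
    return d


@pytest.fixture(scope="session")
def pipeline_result(cohort_dir, tmp_path_factory):
    out = tmp_path_factory.mktemp("pipeline_out")
    return run_pipeline(PipelineConfig(seed=0), cohort_dir, out)
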