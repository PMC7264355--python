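import numpy as np
import pytest

from icmod.pipeline import run_pipeline
from icmod.synth import SynthConfig, generate_multiomics, pipeline_config

TIMES = np.arange(0.0, 46.0, 3.0)  # CT0-21, 2 days, concatenated


@pytest.fixture(scope="session")
def times():
    return TIMES


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic study (seed 42), shared across the suite."""
    return generate_multiomics(SynthConfig(seed=42))


@pytest.fixture(scope="session")
def bundle_paths(bundle, tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle")
    return bundle.write(out)


@pytest.fixture(scope="session")
def pipeline_run(bundle_paths, tmp_path_factory):
    """One full pipeline execution on the default bundle; (report, out_dir)."""
    out = tmp_path_factory.mktemp("results")
    rep = run_pipeline(pipeline_config(bundle_paths, out, seed=42))
    return rep, out
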