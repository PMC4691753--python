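"""Shared fixtures: a hand-built toy genome and one full synthetic study.

The expensive artifacts (the default synthetic dataset and one end-to-end
pipeline run) are session-scoped; individual tests treat them as read-only.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from mirmzt.pipeline import PipelineConfig, run_all
from mirmzt.simulate import default_config, generate_dataset

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

SESSION_SEED = 11


@pytest.fixture(scope="session")
def dataset():
    """The default synthetic study (fixed seed), shared read-only."""
    return generate_dataset(default_config(SESSION_SEED))


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full end-to-end pipeline run on the default synthetic study."""
    outdir = tmp_path_factory.mktemp("pipeline") / "run"
    config = PipelineConfig(outdir=str(outdir), rng_seed=SESSION_SEED)
    report = run_all(config)
    return config, report


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
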