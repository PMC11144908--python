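"""Shared fixtures.

The `study` fixture runs the full hybrid pipeline once, at a reduced
but non-trivial scale (64 cases, shortened CNN schedule), and is shared
by the end-to-end and acceptance tests.  Everything it produces is a
deterministic function of the config seed.
"""

import warnings

import pytest

from swallowtail.pipeline import PipelineConfig, run_pipeline

warnings.filterwarnings("ignore", category=FutureWarning)

STUDY_CONFIG = PipelineConfig(
    n_hc=32,
    n_pd=32,
    n_rater2=16,
    seed=11,
    cnn_epochs=25,
    cnn_patience=8,
    detector_epochs=12,
)


@pytest.fixture(scope="session")
def study():
    """One hybrid pipeline run on a 64-case synthetic cohort."""
    return run_pipeline(STUDY_CONFIG, "hybrid")
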