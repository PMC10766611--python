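import numpy as np
import pandas as pd
import pytest

from glycocast import CGMSeries, CohortSpec, FOUR_CLASS, generate_cohort
from glycocast.fsl import ExtractorConfig
from glycocast.pipeline import PipelineConfig


def make_series(values, patient_id="p1", start="2020-01-01", interval=15):
    return CGMSeries(patient_id, pd.Timestamp(start), np.asarray(values, float), interval)


def constant_series(value=100.0, n_days=14, **kw):
    return make_series(np.full(n_days * 96, value), **kw)


@pytest.fixture(scope="session")
def small_cohort():
    """16 patients, 4 per class, default (separable) generator settings."""
    return generate_cohort(CohortSpec(n_per_class=4, scheme=FOUR_CLASS, seed=11))


@pytest.fixture(scope="session")
def tiny_extractor_config():
    """Narrow CNN for fast structural/training tests (feature dim stays 4096)."""
    return ExtractorConfig(channels=(4, 8, 16, 32), epochs=1, batch_size=8)


@pytest.fixture(scope="session")
def tiny_pipeline_config(tiny_extractor_config):
    return PipelineConfig(
        extractor=tiny_extractor_config,
        n_pairs=16,
        distance_epochs=20,
        knn_k=3,
        imputer_epochs=50,
    )
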