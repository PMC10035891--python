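import numpy as np
import pytest

from dfcmeta import synthetic as syn
from dfcmeta.datatypes import RegionTimeSeries


@pytest.fixture(scope="session")
def tiny_cohort() -> syn.CohortDataset:
    """Small two-cohort dataset used by io/pipeline tests."""
    templates = syn.make_block_templates(
        12, [np.arange(0, 4), np.arange(4, 8)], within=1.0, between=0.05,
        baseline=0.05,
    )
    config = syn.SimulationConfig(
        n_regions=12,
        n_subjects_per_group=3,
        n_frames=60,
        tr=2.0,
        coupling_templates=templates,
        dwell_mean=40.0,
        phase_noise_sd=0.3,
        case_coupling_scale=0.5,
        case_block_size=4,
        seed=7,
    )
    return syn.generate_cohorts(config)


@pytest.fixture
def cosine_series() -> RegionTimeSeries:
    """Two in-band cosines at exact FFT bins (TR=2 s, T=500)."""
    t = np.arange(500) * 2.0
    rows = np.vstack(
        [np.cos(2 * np.pi * 0.04 * t), np.cos(2 * np.pi * 0.02 * t)]
    )
    return RegionTimeSeries(rows, tr=2.0)
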