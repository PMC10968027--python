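"""Shared fixtures.

The heavy end-to-end fixtures are session-scoped so the synthetic-recovery
tests reuse one simulated study per configuration.
"""

from __future__ import annotations

import numpy as np
import pytest

from adhdaid.io_preprocess import Segment
from adhdaid.montage import CHANNELS_1020
from adhdaid.pipeline import PipelineConfig, run_pipeline
from adhdaid.synthetic import SimConfig, simulate_dataset


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture()
def segment_19ch(rng) -> Segment:
    """One 19-channel, 4-second segment of EEG-like noise."""
    return Segment(
        record_id="fixture",
        start_sample=0,
        data=20.0 * rng.standard_normal((19, 512)),
        label=1,
        fs=128.0,
        channels=CHANNELS_1020,
    )


@pytest.fixture(scope="session")
def strong_effect_result():
    """Default pipeline on the study-sized strong-effect dataset.

    20 records per class, 60 s each, band-power shift delta = 0.5 —
    the generator's default study conditions.
    """
    records = simulate_dataset(SimConfig(seed=101))
    return run_pipeline(records, PipelineConfig(seed=101))


@pytest.fixture(scope="session")
def null_effect_result():
    """Default pipeline on a null dataset (delta = 0, smaller for runtime)."""
    records = simulate_dataset(
        SimConfig(n_subjects_per_class=10, duration_s=32.0, effect=0.0,
                  seed=202))
    return run_pipeline(records, PipelineConfig(seed=202))
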