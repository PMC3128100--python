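from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fairechip.config import PipelineConfig
from fairechip.model import GenomicInterval, PeakRecord, PeakSet

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def config() -> PipelineConfig:
    return PipelineConfig(seed=0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_peaks(intervals, source="", score=50.0):
    """PeakSet from (chrom, start, end) tuples."""
    return PeakSet(
        PeakRecord(GenomicInterval(c, s, e), score, 4, source) for c, s, e in intervals
    )


@pytest.fixture
def peaks_factory():
    return make_peaks
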