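"""Shared fixtures and deterministic settings for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

# Deterministic, CI-friendly hypothesis profile: no deadline flakiness,
# derandomized so failures reproduce byte-for-byte.
settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: A let-7-like mature whose first two nucleotides contain neither G nor U
#: together, so the synthetic hairpin constructor can always pick an
#: unpairable 3' tail letter.
SAFE_MATURE = "UAAGGUAGUAGGUUGUAUAGCC"


@pytest.fixture
def safe_mature() -> str:
    return SAFE_MATURE


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
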