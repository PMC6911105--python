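"""Shared fixtures: noise-free synthetic records reused across test modules."""

import numpy as np
import pytest

from pwavedet.synthetic_ecg import generate_record, preset


def clean_preset(name, duration=60.0, fs=360.0, seed=11, **kw):
    """Noise-free, wander-free preset script (controlled conditions)."""
    return preset(
        name,
        duration=duration,
        fs=fs,
        seed=seed,
        noise_rms=0.0,
        baseline_wander=(0.0, 0.0),
        **kw,
    )


@pytest.fixture(scope="session")
def sinus():
    """60 s noise-free normal sinus rhythm at 70 bpm, 360 Hz."""
    return generate_record(clean_preset("normal_sinus"))


@pytest.fixture(scope="session")
def avb2():
    """60 s noise-free second-degree AV block (every 4th P blocked)."""
    return generate_record(clean_preset("avb2"))


@pytest.fixture(scope="session")
def bigeminy():
    """60 s noise-free ventricular bigeminy."""
    return generate_record(clean_preset("bigeminy"))


@pytest.fixture()
def rng():
    """Fresh deterministic generator per test (no cross-test state)."""
    return np.random.default_rng(2026)
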