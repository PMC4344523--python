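"""Shared fixtures: expensive simulated datasets are session-scoped."""

from __future__ import annotations

import numpy as np
import pytest

import halofish as hf
from halofish.pipeline import PipelineParams, analyze_stack, simulate_and_calibrate


@pytest.fixture(scope="session")
def default_config() -> hf.SimConfig:
    return hf.SimConfig(rng_seed=1)


@pytest.fixture(scope="session")
def small_config() -> hf.SimConfig:
    """A reduced field for fast unit tests (same optics and camera)."""
    return hf.SimConfig(field_size_voxels=(28, 64, 64), rng_seed=0)


@pytest.fixture(scope="session")
def params() -> PipelineParams:
    return PipelineParams()


@pytest.fixture(scope="session")
def calibration(default_config, params):
    """Calibration fitted on simulated 135/270-repeat standard slides."""
    return simulate_and_calibrate(default_config, params, n_foci=120, seed=3)


@pytest.fixture(scope="session")
def gm847_g1_run(default_config, params, calibration):
    """20 GM847-preset G1 nuclei analyzed end to end.

    Returns a list of (ground truth, NucleusMetrics, foci-by-channel).
    """
    out = []
    for i in range(20):
        truth, stack = hf.simulate_nucleus(
            hf.GM847, "G1", default_config, seed=1000 + i,
            nucleus_id=f"gm847-g1-{i:02d}",
        )
        metrics, foci = analyze_stack(
            stack, calibration, params, truth.nucleus_id
        )
        out.append((truth, metrics, foci))
    return out


def analyze_batch(preset, n, phase, config, params, calibration, seed0):
    """Simulate and analyze ``n`` nuclei; returns (truths, metrics) lists."""
    truths, metrics = [], []
    for i in range(n):
        truth, stack = hf.simulate_nucleus(
            preset, phase, config, seed=seed0 + i,
            nucleus_id=f"{preset.name}-{i:03d}",
        )
        m, _ = analyze_stack(stack, calibration, params, truth.nucleus_id)
        truths.append(truth)
        metrics.append(m)
    return truths, metrics
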