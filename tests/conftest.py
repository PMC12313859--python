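"""Shared fixtures: small scenes and one short stitched scan.

The heavier fixtures are session-scoped so the feature-extraction cost is
paid once across the suite.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import hsistitch as hs

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def texture_scene():
    return hs.generate_scene(0, "texture", 2000, 1200)


@pytest.fixture(scope="session")
def usaf_scene():
    return hs.generate_scene(0, "usaf", 2000, 1200)


@pytest.fixture(scope="session")
def short_scan(texture_scene):
    """Zero-noise constant-translation scan, 12 frames at 3 px/interval."""
    traj = hs.make_trajectory("translation", 12, 3.0)
    return hs.simulate_scan(texture_scene, traj, seed=0)


@pytest.fixture(scope="session")
def short_streams(short_scan):
    frames, lines = hs.ingest(short_scan)
    return frames, lines


@pytest.fixture(scope="session")
def short_result(short_scan, short_streams):
    frames, lines = short_streams
    stitcher = hs.FreehandStitcher(short_scan.calibration)
    return stitcher.run(frames, lines)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_line(timestamp_ms: int, value: float = 0.5, index: int = 0) -> hs.HSILine:
    """Cheap constant-reflectance HSI line for bookkeeping tests."""
    return hs.HSILine(
        spectra=np.full((540, 100), value), timestamp_ms=timestamp_ms, index=index
    )
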