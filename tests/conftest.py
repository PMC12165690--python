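import numpy as np
import pytest

from crpnet.signals import EdgeFrameSeries, RegionSignalSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_frames(frames: np.ndarray, n_regions: int, coupling: str = "bold",
                tr: float = 3.0) -> EdgeFrameSeries:
    return EdgeFrameSeries(frames, tr=tr, coupling=coupling, n_regions=n_regions)


@pytest.fixture
def toy_frames(rng):
    """Random 40-frame bold-style edge series on 10 regions."""
    return make_frames(rng.standard_normal((40, 45)), n_regions=10)


@pytest.fixture
def fast_signals(rng):
    """Broadband fast-modality signals: 6 regions, 30 s at 250 Hz."""
    return RegionSignalSet(rng.standard_normal((6, 7500)), fs=250.0, modality="fast")
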