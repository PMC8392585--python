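import numpy as np
import pytest
from hypothesis import settings

from ntcpkit.dvh import CUMULATIVE, DIFFERENTIAL, DoseVolumeHistogram

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def uniform_dvh(dose: float, volume: float = 1.0, width: float = 1e-6,
                label: str = "organ") -> DoseVolumeHistogram:
    """Near-point-mass organ: all volume in one narrow bin centred on `dose`."""
    return DoseVolumeHistogram(
        label, DIFFERENTIAL, [dose - width / 2, dose + width / 2], [volume], volume
    )


def two_bin_dvh(d1: float, d2: float, f1: float = 0.5, volume: float = 1.0,
                label: str = "organ") -> DoseVolumeHistogram:
    """Two bins with centres exactly at d1 < d2 and volume split f1 / 1-f1."""
    w = (d2 - d1)
    edges = [d1 - w / 2, d1 + w / 2, d2 + w / 2]
    return DoseVolumeHistogram(
        label, DIFFERENTIAL, edges, [f1 * volume, (1 - f1) * volume], volume
    )


def random_realistic_dvh(rng: np.random.Generator) -> DoseVolumeHistogram:
    """Random plateau-then-falloff cumulative DVH (generator-family shape)."""
    total = float(rng.uniform(10, 120))
    a = float(rng.uniform(0, 40))
    b = a + float(rng.uniform(5, 50))
    g = float(rng.uniform(0.3, 5.0))
    edges = np.linspace(0.0, b, int(rng.integers(8, 60)))
    s = np.ones_like(edges)
    fall = edges > a
    s[fall] = np.clip((b - edges[fall]) / (b - a), 0, None) ** g
    return DoseVolumeHistogram("rand", CUMULATIVE, edges, total * s, total)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
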