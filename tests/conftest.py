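import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sweepdate.panel import MarkerMap, PhasedPanel

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def panel_from_strings(haps: list[str], spacing: int = 1000) -> PhasedPanel:
    """Build a panel from chromosome allele strings (2 per sample)."""
    assert len(haps) % 2 == 0
    m = len(haps[0])
    markers = MarkerMap(
        "14",
        tuple(f"m{i}" for i in range(m)),
        np.arange(1, m + 1, dtype=np.int64) * spacing,
    )
    hap = np.array([[int(ch) for ch in row] for row in haps], dtype=np.uint8)
    samples = tuple(f"s{i}" for i in range(len(haps) // 2))
    return PhasedPanel(samples, hap, markers)


@pytest.fixture
def four_chrom_panel() -> PhasedPanel:
    """Two samples / four chromosomes spelling {01, 01, 11, 00}."""
    return panel_from_strings(["01", "01", "11", "00"])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
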