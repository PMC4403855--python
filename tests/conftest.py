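import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=100)
settings.load_profile("ci")

from bundlekit.filament import FilamentState, SimParams


@pytest.fixture
def loose_params():
    """Roomy parameters for hand-built geometric fixtures (lengths up to 0.2)."""
    return SimParams(N=3, T=10, G=0.05, S=0.2, B=0.2, k=5.0, w=0.005, L0=0.1, seed=0)


@pytest.fixture
def straight_state():
    """A straight 5-cell filament of 0.1-long cells at y = 0.5 (away from walls)."""
    xs = 0.25 + 0.1 * np.arange(6)
    return FilamentState(np.column_stack([xs, np.full(6, 0.5)]))


@pytest.fixture
def kinked_state():
    """A 3-cell filament with a bent middle junction (stores bending energy)."""
    nodes = np.array([
        [0.30, 0.50],
        [0.42, 0.50],
        [0.53, 0.55],   # kink here
        [0.65, 0.55],
    ])
    return FilamentState(nodes)
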