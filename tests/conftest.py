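import numpy as np
import pytest

import polarpath as pp


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def white_bg_stimulus():
    """One colored k=0.08, jitter-20 stimulus shared across tests."""
    return pp.assemble_stimulus(
        "white_background", pp.EggParams(k=0.08, jitter_deg=20), 42)


@pytest.fixture(scope="session")
def no_color_stimulus():
    return pp.assemble_stimulus(
        "no_color", pp.EggParams(k=0.04, jitter_deg=20), 7)


def make_ring_stimulus(n_edges=36, radius=300.0, center=(960.0, 540.0)):
    """Fully supported ring of chords around the canvas center: consecutive
    chords span 8 degrees with 2-degree gaps, all endpoints on the circle."""
    edges = []
    for i in range(n_edges):
        a0 = np.radians(i * 10.0)
        a1 = np.radians(i * 10.0 + 8.0)
        p1 = (center[0] + radius * np.cos(a0), center[1] - radius * np.sin(a0))
        p2 = (center[0] + radius * np.cos(a1), center[1] - radius * np.sin(a1))
        edges.append(pp.EdgeSegment(p1=p1, p2=p2, label="boundary"))
    return pp.StimulusCanvas(edges=edges, egg=None, condition="no_color",
                             fixation=center)


@pytest.fixture
def ring_stimulus():
    return make_ring_stimulus()
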