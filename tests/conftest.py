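import numpy as np
import pytest

from overlapfit.model_core import SpectrumWindow


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_window():
    """A 20-point single-peptide toy window (two isotope peaks, mild noise)."""
    from overlapfit.model_core import PeptideState, SharedState, mean_intensity
    from overlapfit.peak_shape import ShapeParams

    x = 99.5 + 0.1 * np.arange(20)
    pep = PeptideState(M=100.0, H=100.0, R=np.array([1.0, 0.5]), odds=0.5)
    shared = SharedState(S=1.0015, sigma=5.0, shape=ShapeParams("normal", 0.075))
    base = SpectrumWindow(x=x, y=np.zeros_like(x))
    mean = mean_intensity([pep], shared, base)
    noise = np.random.default_rng(7).normal(0, 5.0, x.size)
    return SpectrumWindow(x=x, y=mean + noise), pep, shared
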