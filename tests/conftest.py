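import numpy as np
import pytest
from dataclasses import replace

from imfspat.extraction import GrowthParams, extract_imf
from imfspat.phantom import generate_phantom, preset


@pytest.fixture(scope="session")
def young_phantom():
    return generate_phantom(preset("young"))


@pytest.fixture(scope="session")
def old_phantom():
    return generate_phantom(replace(preset("old"), seed=1))


@pytest.fixture(scope="session")
def young_extraction(young_phantom):
    ph = young_phantom
    return extract_imf(ph.ff, ph.muscle, GrowthParams())


@pytest.fixture(scope="session")
def old_extraction(old_phantom):
    ph = old_phantom
    return extract_imf(ph.ff, ph.muscle, GrowthParams())


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = a.astype(bool)
    b = b.astype(bool)
    return 2.0 * (a & b).sum() / (a.sum() + b.sum())
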