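import numpy as np
import pytest

from mitotype.synthetic import (
    NetworkImageParams,
    ProteomeSimParams,
    make_network_image,
    make_proteome,
)


@pytest.fixture(scope="session")
def parallel_image():
    """Jitter- and noise-free horizontal tube network with ground truth."""
    params = NetworkImageParams(pattern="parallel", base_angle=0.0, seed=11)
    return make_network_image(params)


@pytest.fixture(scope="session")
def grid_image():
    """Jitter-free 0/90-degree tube grid with ground truth."""
    params = NetworkImageParams(pattern="grid", base_angle=0.0, seed=11)
    return make_network_image(params)


@pytest.fixture(scope="session")
def blank_image():
    return make_network_image(NetworkImageParams(pattern="blank"))


@pytest.fixture(scope="session")
def zero_noise_ten_class_proteome():
    """All ten phenotype/sign classes planted at FC 4 with zero noise."""
    from mitotype.synthetic import PHENOTYPES

    planted = [(p, s, 10, 4.0) for p in PHENOTYPES for s in ("+", "-")]
    params = ProteomeSimParams(n_proteins=300, planted=planted, noise_cv=0.0, seed=3)
    matrix, truth = make_proteome(params)
    return params, matrix, truth


def grating(angle_deg: float, size: int = 200, period: float = 12.0) -> np.ndarray:
    """Sinusoidal grating whose stripes run along ``angle_deg`` (CCW, y-up)."""
    rows, cols = np.mgrid[0:size, 0:size]
    x, y = cols.astype(float), -rows.astype(float)
    phi = np.deg2rad(angle_deg)
    u = -np.sin(phi) * x + np.cos(phi) * y
    return 100.0 + 50.0 * np.sin(2.0 * np.pi * u / period)
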