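import numpy as np
import pytest

from bchekit import (
    KineticParameters,
    generate_rate_curve,
    load_registry,
)

# Published family/control BTC parameter sets used as generative truth.
PROBAND = KineticParameters(vmax=0.50, km_um=265.0)                 # AKS, b = 1
FATHER = KineticParameters(vmax=7.51, km_um=21.0, kss_mm=0.49, b=2.4)   # US
MOTHER = KineticParameters(vmax=6.07, km_um=27.0, kss_mm=0.51, b=2.5)   # AKU
USUAL = KineticParameters(vmax=7.5, km_um=18.0, kss_mm=1.0, b=3.2)      # UU
ATYPICAL = KineticParameters(vmax=1.22, km_um=150.0, kss_mm=1.1, b=1.2)  # AA


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture
def noiseless_michaelian_curve():
    return generate_rate_curve(PROBAND, noise_cv=0.0, replicates=1, seed=0)


@pytest.fixture
def noiseless_two_site_curve():
    return generate_rate_curve(USUAL, noise_cv=0.0, replicates=1, seed=0)


@pytest.fixture
def noisy_usual_curve():
    return generate_rate_curve(USUAL, noise_cv=0.03, replicates=3, seed=42)
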