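import pytest

from condcath import ElectrodeConfig, SourceStrength, TissueModel


@pytest.fixture
def cfg():
    """Default tetrapolar geometry: 1 mm spheres, 20 mm inner / 40 mm outer pair."""
    return ElectrodeConfig(r0=1.0, L=20.0, d=40.0)


@pytest.fixture
def source():
    return SourceStrength(V0=1.0)


@pytest.fixture
def saline():
    """Insulating-surround tissue model (glass-container conditions)."""
    return TissueModel(sigma_bl=0.7)


@pytest.fixture
def phantom_tissue():
    """Conductive-wall phantom conditions."""
    return TissueModel(sigma_bl=0.7, sigma_m=0.3, sigma_ba=0.2, wall_thickness=10.0)
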