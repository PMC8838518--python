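import numpy as np
import pytest

from neophantom import (
    ThermalSensorModel,
    default_layout,
    default_view_transforms,
)


@pytest.fixture(scope="session")
def layout():
    return default_layout((640, 360))


@pytest.fixture(scope="session")
def small_layout():
    return default_layout((320, 180))


@pytest.fixture(scope="session")
def ideal_sensor():
    """Identity response, no noise: measured equals surface temperature."""
    return ThermalSensorModel(k1_true=1.0, k2_true=0.0, noise_sigma=0.0, quantization=0.0)


@pytest.fixture(scope="session")
def lepton_like_sensor():
    """Sensor whose true response matches the fitted line Ts = 1.82*Tm - 20.18."""
    return ThermalSensorModel(k1_true=1.82, k2_true=-20.18, noise_sigma=0.0)


@pytest.fixture(scope="session")
def views(layout):
    return default_view_transforms(layout.canvas_size, (160, 120))
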