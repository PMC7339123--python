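import numpy as np
import pytest

import bilayerlab as bl


@pytest.fixture
def capsaicin_like_adsorption():
    """Noiseless Langmuir series in the strong-modifier regime
    (saturation 118 mV, desorption constant 32 uM)."""
    return bl.gen_adsorption_series(bl.AdsorptionModel(dphi_max=118.0, k_desorption=32.0))


@pytest.fixture
def control_thermogram():
    """Noiseless control scan: pretransition at 33.9 C plus a sharp
    (0.4 C FWHM) main transition at 41.3 C."""
    from bilayerlab.dsc import enthalpy_for_fwhm

    comps = [
        bl.MeltingComponent(33.9, enthalpy_for_fwhm(33.9, 1.2), 5_000.0),
        bl.MeltingComponent(41.3, enthalpy_for_fwhm(41.3, 0.4), 30_000.0),
    ]
    return bl.gen_thermogram(comps, np.arange(28.0, 46.0, 0.02))
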