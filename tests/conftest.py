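"""Shared fixtures: phantoms are generated once per session where possible."""

import numpy as np
import pytest

from ctoam import synthetic_data as sd


@pytest.fixture(scope="session")
def noiseless_affected():
    """Noise-free affected joint (lesion + peaks) with ground truth."""
    cfg = sd.affected_config(noise_sd_hu=0.0, seed=7)
    return cfg, *sd.generate_volume(cfg)


@pytest.fixture(scope="session")
def default_pair():
    """Default-seeded bilateral pair (affected, contralateral) with noise."""
    return sd.generate_bilateral_pair(sd.affected_config(seed=0))


@pytest.fixture()
def slab_volume():
    """A flat 3 mm slab of 800 HU bone at 0.5 mm spacing, air elsewhere.

    The slab occupies z indices 10..15 (6 layers); its articular surface for
    the proximal view (rays along -z) is the z = 15 layer.
    """
    from ctoam.volume import CTVolume

    hu = np.full((20, 20, 24), -1000.0)
    hu[4:16, 4:16, 10:16] = 800.0
    return CTVolume(hu=hu, spacing=(0.5, 0.5, 0.5))
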