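import dataclasses

import numpy as np
import pytest

from iscatlab import IPSFModel, OpticalConfig


@pytest.fixture
def cfg():
    return OpticalConfig()


@pytest.fixture
def ipsf():
    return IPSFModel()


@pytest.fixture
def flat_phase_ipsf():
    """Model with negligible Gouy curvature: phase slope is 4 pi n / lambda."""
    return dataclasses.replace(IPSFModel(), gouy_range=1.0e7)


def contrast_of(stack, cfg):
    """Contrast of a rendered stack against the known reference level r^2."""
    r2 = cfg.reference_reflectivity**2
    return (np.asarray(stack.data, dtype=float) - r2) / r2
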