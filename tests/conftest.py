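import math

import numpy as np
import pytest

from cohear import GammatoneSpec, StimulusSpec
from cohear.stimuli import TWO_PI


@pytest.fixture(scope="session")
def default_filter() -> GammatoneSpec:
    return GammatoneSpec()


def zero_ipd(w):
    return np.zeros_like(np.asarray(w, dtype=float))


def itd_ipd(delta_t_s):
    def ipd(w):
        return np.asarray(w, dtype=float) * delta_t_s

    return ipd


def broadband_noise(rho=1.0, delta_t_ms=0.0, tone_ipd=math.pi, bandwidth_hz=900.0):
    """Convenience: 900-Hz noise band at 500 Hz with optional whole-band ITD."""
    ipd = itd_ipd(delta_t_ms * 1e-3) if delta_t_ms else zero_ipd
    return StimulusSpec(ipd, rho, tone_ipd, TWO_PI * bandwidth_hz)


def wrap_angle(a: float) -> float:
    """Wrap to (-pi, pi]."""
    return -((-a + math.pi) % (2 * math.pi) - math.pi)
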