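import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bioalbedo import IRFRegression, Spectrum

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def field_regression() -> IRFRegression:
    """The published log-linear density-IRF relation at the field median PAR."""
    return IRFRegression(
        slope_a=5.52,
        intercept_b=-24.03,
        r_squared=0.41,
        residual_sd=10.0,
        reference_par=351.0,
    )


@pytest.fixture
def flat_spectrum():
    def _make(value: float, lo: float = 350.0, hi: float = 2500.0, kind="reflectance"):
        wl = np.arange(lo, hi + 0.5, 1.0)
        return Spectrum(wl, np.full(wl.shape, value), kind=kind)

    return _make
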