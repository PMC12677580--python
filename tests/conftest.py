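import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from scipy.optimize import brentq
from scipy.special import i0e, i1e

from chiralign import GridSpec, SceneParams, generate_scene

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def vonmises_sd_half_deg(kappa: float) -> float:
    """Closed-form axial circular SD (half-circle deg) of a doubled von
    Mises law with concentration kappa: R̄ = I1(κ)/I0(κ)."""
    rbar = i1e(kappa) / i0e(kappa)  # scaled ratio avoids overflow at large kappa
    return float(np.rad2deg(np.sqrt(-2.0 * np.log(rbar))) / 2.0)


def kappa_from_sd_half_deg(sd_deg: float) -> float:
    """Invert the closed-form axial SD to a concentration."""
    return float(brentq(lambda k: vonmises_sd_half_deg(k) - sd_deg,
                        1e-3, 1e4))


@pytest.fixture(scope="session")
def small_scene():
    """A modest synthetic scene shared by cropping/pipeline tests:
    120 rectangles, µ=−8°, κ=6, mixed coverage straddling 0.8."""
    grid = GridSpec(um_per_px=4.0, n_rectangles=120)
    params = SceneParams(mu_deg=-8.0, kappa=6.0, seed=7)
    image, truth = generate_scene(grid, params)
    return grid, params, image, truth
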