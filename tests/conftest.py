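import numpy as np
import pytest

from dissofront.synthgen import SceneSpec, simulate_immersion_stack

# small scene geometry shared by the imaging unit tests: fast to render,
# big enough for sub-pixel tracking to work
SMALL = dict(image_size=(192, 192), radius_px=50.0, pixel_size_mm=0.05)


@pytest.fixture(scope="session")
def static_stack():
    spec = SceneSpec(**SMALL, n_frames=6, seed=11)
    return simulate_immersion_stack(spec)


@pytest.fixture(scope="session")
def wetting_stack():
    # 2 px/frame inward at 1 min/frame -> 0.1 mm/min
    spec = SceneSpec(
        **SMALL, n_frames=11, wetting_velocity=0.1, frame_interval_min=1.0, seed=12
    )
    return simulate_immersion_stack(spec)


@pytest.fixture(scope="session")
def gel_stack():
    # 1 px/frame outward -> 0.05 mm/min
    spec = SceneSpec(
        **SMALL, n_frames=11, gel_velocity=0.05, frame_interval_min=1.0, seed=13
    )
    return simulate_immersion_stack(spec)


@pytest.fixture(scope="session")
def erosion_stack():
    spec = SceneSpec(
        **SMALL,
        n_frames=16,
        erosion_velocity=0.02,
        roughness_sd_px=1.0,
        frame_interval_min=1.0,
        seed=14,
    )
    return simulate_immersion_stack(spec)


def ols_slope_oracle(t: np.ndarray, d: np.ndarray) -> float:
    """Closed-form OLS slope: sum((t-tbar)(d-dbar)) / sum((t-tbar)^2)."""
    t = np.asarray(t, dtype=float)
    d = np.asarray(d, dtype=float)
    return float(np.sum((t - t.mean()) * (d - d.mean())) / np.sum((t - t.mean()) ** 2))
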