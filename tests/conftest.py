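import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cytosizer import OpticsSpec, ParticleSpec, render_frame

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def clean_optics():
    """Noise- and blur-free optics on a native 120 px frame (no resize)."""
    return OpticsSpec(blur_sigma_px=0.0, noise_sigma=0.0, frame_side_px=120)


@pytest.fixture
def render_bead_px():
    """Render a circular bead of a given pixel diameter on a 120 px frame."""

    def _render(diameter_px: float, seed: int = 0, noise_sigma: float = 0.01,
                jitter: float = 2.0):
        optics = OpticsSpec(noise_sigma=noise_sigma, frame_side_px=120)
        spec = ParticleSpec.circle(diameter_px * optics.um_per_pixel,
                                   center_jitter_px=jitter)
        return render_frame(spec, optics, seed=seed)

    return _render


def reflect_pad(arr: np.ndarray, half: int) -> np.ndarray:
    # edge-repeating mirror: matches the pipeline's declared border policy
    return np.pad(arr, half, mode="symmetric")


def brute_force_correlate(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Direct double-loop correlation with reflect border (oracle)."""
    half = kernel.shape[0] // 2
    pad = reflect_pad(image.astype(float), half)
    out = np.zeros_like(image, dtype=float)
    for i in range(image.shape[0]):
        for j in range(image.shape[1]):
            out[i, j] = (pad[i:i + kernel.shape[0], j:j + kernel.shape[1]] * kernel).sum()
    return out


def brute_force_rank(image: np.ndarray, side: int, op) -> np.ndarray:
    """Direct double-loop min/max filter with reflect border (oracle)."""
    half = side // 2
    pad = reflect_pad(image, half)
    out = np.zeros_like(image)
    for i in range(image.shape[0]):
        for j in range(image.shape[1]):
            out[i, j] = op(pad[i:i + side, j:j + side])
    return out
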