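import numpy as np
import pytest

from plaquemap._geometry import circle_points
from plaquemap.imaging_io import Contour, ContourStack
from plaquemap.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def simple_phantom():
    """Zero-deformation phantom with axial + circumferential WSS structure."""
    spec = PhantomSpec(
        n_sections=6,
        wss_axial_gradient_pa_per_mm=0.5,
        wss_circumferential_amplitude_pa=1.0,
        wss_baseline_pa=2.0,
        rng_seed=11,
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def deformed_phantom():
    """Phantom with 1 mm similarity + B-spline deformations."""
    spec = PhantomSpec(
        n_sections=6,
        deformation_magnitude_mm=1.0,
        wss_axial_gradient_pa_per_mm=0.5,
        rng_seed=23,
    )
    return generate_phantom(spec)


def circle_stack(radius=3.0, n_slices=4, center=(0.0, 0.0), n=128, structure="lumen"):
    return ContourStack(
        [
            Contour(k, float(k), structure, circle_points(radius, center, n))
            for k in range(n_slices)
        ]
    )


@pytest.fixture
def lumen_stack():
    return circle_stack()
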