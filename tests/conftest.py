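import math

import numpy as np
import pytest

import walltomo as wt


def axial_vonmises_sample(rng, mode_deg, sd_deg, n):
    """Axial angles around a mode with the generator's noise law."""
    kappa = 1.0 / (2.0 * math.radians(sd_deg)) ** 2
    return (mode_deg + np.degrees(rng.vonmises(0.0, kappa, n)) / 2.0) % 180.0


@pytest.fixture(scope="session")
def bimodal_angles():
    rng = np.random.default_rng(42)
    return np.concatenate(
        [
            axial_vonmises_sample(rng, 42.0, 8.0, 500),
            axial_vonmises_sample(rng, 135.0, 10.0, 500),
        ]
    )


@pytest.fixture(scope="session")
def random_traceset():
    """Thirty random 3D polylines for isometry/round-trip checks."""
    rng = np.random.default_rng(7)
    traces = []
    for i in range(30):
        n = int(rng.integers(4, 12))
        pts = np.cumsum(rng.normal(0, 5, (n, 3)), axis=0) + rng.uniform(0, 500, 3)
        traces.append(wt.FiberTrace(i, pts))
    return wt.TraceSet(traces, provenance="random fixture")


@pytest.fixture(scope="session")
def small_phantom():
    """Small rendered phantom with meshing, shared across tests."""
    fs = wt.FiberFieldSpec(
        box_dims=(400.0, 400.0, 200.0),
        n_layers=4,
        layer_thickness=50.0,
        fibers_per_layer=6,
        fiber_length_range=(150.0, 250.0),
        slope_sd=0.0,
        seed=5,
    )
    ms = wt.MeshingSpec(density_at_surface=4000.0, depth_decay=200.0, seed=6)
    rs = wt.RenderSpec(
        voxel_size=2.0, fiber_radius=3.5, meshing_radius=2.0, noise_sd=0.0, seed=7
    )
    return wt.make_phantom(fs, ms, rs)
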