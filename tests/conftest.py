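import numpy as np
import pytest

import deerfit as df


@pytest.fixture(scope="session")
def grid():
    return df.DistanceGrid()


@pytest.fixture(scope="session")
def single_gaussian(grid):
    return df.DistanceDistribution.from_components(
        [df.GaussianComponent(3.5, 0.25, 1.0)], grid
    )


@pytest.fixture(scope="session")
def time_axis():
    return np.linspace(0.0, 3.0, 300)


@pytest.fixture(scope="session")
def clean_trace(single_gaussian, time_axis):
    """Noiseless single-Gaussian trace with known parameters."""
    return df.compose_signal(
        single_gaussian,
        df.BackgroundModel(kappa=0.2, dim=3.0),
        df.ModulationDepth(0.3),
        time_axis,
        meta={"pair": "pair-A"},
    )


@pytest.fixture(scope="session")
def toy_bundle():
    return df.generate_toy_bundle(n_helices=4, residues_per_helix=12, bundle_radius=14.0)


def riemann_kernel(t: float, r: float, n: int = 1_000_000) -> float:
    """Midpoint Riemann-sum oracle for the powder-averaged dipolar kernel."""
    u = (np.arange(n) + 0.5) / n
    return float(
        np.mean(np.cos((1.0 - 3.0 * u**2) * 2.0 * np.pi * (52.04 / r**3) * t))
    )
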