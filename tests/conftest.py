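import warnings

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(autouse=True)
def _quiet_fit_warnings():
    """Silence expected convergence-advice warnings inside bulk fitting tests."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*slow phase.*")
        warnings.filterwarnings("ignore", message=".*pKa_nuc.*")
        yield


@pytest.fixture(scope="session")
def mtr1_surface():
    """Canonical MTR1-like preset surface (barrier 16.3, TS2 xi_AT -0.24)."""
    from ribomech.synthetic_data import gen_surface, mtr1_surface_spec

    return gen_surface(mtr1_surface_spec())


@pytest.fixture(scope="session")
def mtr1_converged_path(mtr1_surface):
    from ribomech.landscape import string_mfep

    return string_mfep(mtr1_surface, (-1.5, -2.5), (1.5, 2.5),
                       n_images=32, max_iter=3000)


def grid_index(surface, point):
    """Nearest grid-node index of a coordinate point."""
    i = int(round((point[0] - surface.axis_pt[0])
                  / (surface.axis_pt[1] - surface.axis_pt[0])))
    j = int(round((point[1] - surface.axis_at[0])
                  / (surface.axis_at[1] - surface.axis_at[0])))
    return i, j
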