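import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def registry():
    from znbuffer.io import bundled_registry

    return bundled_registry()


@pytest.fixture(scope="session")
def par(registry):
    return registry.probes["PAR"]


@pytest.fixture(scope="session")
def znaf(registry):
    return registry.probes["ZnAF-2F"]


def grid_scan_free_zinc(system, n_grid=4001, refine_iters=60):
    """Independent oracle: dense log10 grid sign scan of the mass-balance
    residual, then plain interval bisection between the bracketing grid
    points.  Shares no code path with the package solver's root finder."""
    from znbuffer.equilibria import _bound_zinc

    def residual(log_z):
        z = 10.0 ** log_z
        return system.zn_total - z - _bound_zinc(system, z)

    grid = np.linspace(-20.0, -1.0, n_grid)
    vals = np.array([residual(g) for g in grid])
    sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    assert sign_change.size >= 1, "oracle found no sign change"
    lo, hi = grid[sign_change[0]], grid[sign_change[0] + 1]
    for _ in range(refine_iters):
        mid = 0.5 * (lo + hi)
        if residual(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
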