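import pytest

import tearmap as tm


@pytest.fixture(scope="session")
def small_grid():
    """Coarse standard grid used where resolution is not the point."""
    return tm.make_standard_grid(5.0, 24, 72)


@pytest.fixture(scope="session")
def small_params(small_grid):
    """Default calibration on the coarse grid, small cohort, fixed seed."""
    p = tm.default_params(grid=small_grid, seed=11)
    p.group_sizes = (5, 6, 7)
    return p


@pytest.fixture(scope="session")
def small_cohort(small_params):
    cohort, truths = tm.generate_cohort(small_params, "OD")
    return cohort, truths


@pytest.fixture(scope="session")
def quadratic_map():
    """Smooth analytic field a + b (r/R)^2 on the full-resolution grid."""
    grid = tm.make_standard_grid(5.0, 50, 180)
    r, _ = grid.mesh()
    a, b = 0.05, 0.1
    return tm.TearFilmMap(grid=grid, values=a + b * (r / 5.0) ** 2), (a, b)
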