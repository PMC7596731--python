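import numpy as np
import pytest
from hypothesis import settings

import ciiros as c

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")

#: default succinate grid used throughout (log-spaced, subsaturating to
#: saturating); classification results are reported on this grid
SUCC_GRID = np.geomspace(1.0, 5000.0, 60)


@pytest.fixture(scope="session")
def params():
    return c.ParameterSet()


@pytest.fixture(scope="session")
def assembled(params):
    return c.build_network("assembled_only", params)


@pytest.fixture(scope="session")
def mixed():
    p = c.ParameterSet(CIIt=100.0, ABt=135.0, CDt=135.0)
    return c.build_network("mixed", p), p


@pytest.fixture(scope="session")
def succ_grid():
    return SUCC_GRID


@pytest.fixture(scope="session")
def sweep_cache(assembled, params):
    """Lazily computed, session-shared succinate sweeps per condition."""
    cache: dict[tuple, c.SweepResult] = {}

    def get(**overrides) -> c.SweepResult:
        key = tuple(sorted(overrides.items()))
        if key not in cache:
            cache[key] = c.sweep(assembled, params.copy(**overrides),
                                 "succinate", SUCC_GRID)
        return cache[key]

    return get


@pytest.fixture(scope="session")
def baseline_steady(assembled, params):
    """Basal steady state at saturating succinate."""
    return c.solve_steady(assembled, params.copy(succ=5000.0))
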