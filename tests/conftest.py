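import warnings

import numpy as np
import pytest

from teardrop import (
    LESION_CONDITIONS,
    SimParams,
    build_arc_bank,
    compute_edge_map,
    curved_response,
    get_exemplar,
    run,
)

warnings.filterwarnings("ignore", category=RuntimeWarning,
                        message=".*did not converge.*")


@pytest.fixture(scope="session")
def bank():
    return build_arc_bank()


@pytest.fixture(scope="session")
def fast_params():
    """Shared simulation constants for the test suite (model defaults with a
    step budget small enough for many runs)."""
    return SimParams(n_steps=250, convergence_tol=1e-5)


@pytest.fixture(scope="session")
def exemplars():
    from teardrop import make_exemplars
    return {d.name: d for d in make_exemplars()}


class _RunCache:
    """Lazily computed, session-shared equilibria keyed by (display, lesion)."""

    def __init__(self, params):
        self.params = params
        self._cache = {}

    def get(self, display, lesion="intact", record_history=False):
        key = (display.name, lesion, record_history)
        if key not in self._cache:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                self._cache[key] = run(
                    display, lesion=LESION_CONDITIONS[lesion],
                    params=self.params, record_history=record_history)
        return self._cache[key]


@pytest.fixture(scope="session")
def runs(fast_params):
    return _RunCache(fast_params)


@pytest.fixture(scope="session")
def curved_square(bank, exemplars):
    return curved_response(compute_edge_map(exemplars["square"]), bank)


def circle_display(radius, canvas=64):
    from teardrop.stimuli import _display_from_mask
    yy, xx = np.mgrid[0:canvas, 0:canvas]
    c = (canvas - 1) / 2.0
    mask = (yy - c) ** 2 + (xx - c) ** 2 <= radius ** 2
    return _display_from_mask(mask, f"disk_r{radius:g}")
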