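"""Shared fixtures: small simulated sessions reused across test modules.

Everything is generated programmatically from fixed seeds; no data files.
"""

import numpy as np
import pytest

from sfcode import responses, simdata


@pytest.fixture(scope="session")
def small_session():
    """Mixed session: 24 neurons, 6 bases x 12 variants x 10 blocks."""
    rng = np.random.default_rng(101)
    pop = simdata.make_population(24, rng=rng)
    manifest = simdata.make_stimulus_manifest(n_base=6, n_face=3, n_nonface=2)
    sess = simdata.simulate_session(
        pop, manifest, simdata.SessionSpec(n_blocks=10), rng
    )
    return pop, sess


@pytest.fixture(scope="session")
def small_tensor(small_session):
    _, sess = small_session
    return responses.bin_rates(sess)


@pytest.fixture(scope="session")
def small_ztensor(small_tensor):
    z, _excluded = responses.zscore(small_tensor)
    return z


@pytest.fixture(scope="session")
def tuned_session():
    """Scrambled-band-only session with strong tuning: 40 neurons, 15 blocks."""
    rng = np.random.default_rng(202)
    pop = simdata.make_population(40, rng=rng)
    manifest = simdata.make_stimulus_manifest(
        n_base=10, n_face=4, n_nonface=3,
        include_intact=False, include_unscrambled=False,
    )
    sess = simdata.simulate_session(
        pop, manifest, simdata.SessionSpec(n_blocks=15), rng
    )
    return pop, sess


@pytest.fixture(scope="session")
def tuned_tensor(tuned_session):
    _, sess = tuned_session
    return responses.bin_rates(sess)
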