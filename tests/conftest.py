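"""Shared fixtures: the synthetic umbrella-sampling study and toy structures.

The session-scoped umbrella dataset reproduces the standard study
conditions (64 kJ/mol landscape, 47 windows at 0.05 nm spacing,
k = 1000 kJ/mol/nm^2, 1e5 retained samples per window) and is reused by
the WHAM and bootstrap tests.
"""

import numpy as np
import pytest

import calyxsim as cs

STUDY_SEED = 1
N_SAMPLES_PER_WINDOW = 100_000
SAMPLE_STRIDE = 10


@pytest.fixture(scope="session")
def landscape64():
    return cs.make_unbinding_landscape(64.0)


def _dataset(landscape, n_samples, seed):
    n_steps = int(round(n_samples * SAMPLE_STRIDE / 0.9))
    params = cs.LangevinParams(n_steps=n_steps, seed=seed)
    return cs.generate_umbrella_dataset(
        landscape, cs.default_umbrella_centers(), params,
        sample_stride=SAMPLE_STRIDE)


@pytest.fixture(scope="session")
def umbrella_dataset_64(landscape64):
    """47 windows, 1e5 retained samples each, fixed seed."""
    return _dataset(landscape64, N_SAMPLES_PER_WINDOW, STUDY_SEED)


@pytest.fixture(scope="session")
def umbrella_dataset_64_double(landscape64):
    """Same study with twice the samples per window, generated from the
    same noise stream (paired design: the convergence comparison is then
    not confounded by between-realisation spread of the bootstrap error)."""
    return _dataset(landscape64, 2 * N_SAMPLES_PER_WINDOW, STUDY_SEED)


@pytest.fixture(scope="session")
def toy_calyx():
    return cs.make_toy_calyx()


@pytest.fixture(scope="session")
def flat_landscape():
    return cs.ModelLandscape(((1.0, 0.0), (3.0, 0.0)), (1.0, 3.0))
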