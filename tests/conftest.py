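"""Shared fixtures: small synthetic fields and a matched calibration.

Field sizes here are scaled down from the production imaging conditions
(fewer beads per field, smaller frames) so the suite stays fast; the
bead geometry, densities and exposure settings keep their defaults.
"""

import dataclasses
import warnings

import numpy as np
import pytest

from beadassay import (CalibrationConfig, GeneratorParams,
                       generate_bead_field, match_pi_setup)


@pytest.fixture(scope="session")
def small_params() -> GeneratorParams:
    """A fast field: 6 beads in a 700 px frame, default optics."""
    return GeneratorParams(n_beads=6, shape=(700, 700))


@pytest.fixture(scope="session")
def tiny_params() -> GeneratorParams:
    """A minimal field for per-pixel oracle tests."""
    return GeneratorParams(n_beads=2, shape=(420, 420),
                           bead_diameter_mean_um=300.0,
                           bead_diameter_sd_um=30.0)


@pytest.fixture(scope="session")
def live_fields(small_params):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return [generate_bead_field(small_params, seed=100 + i)
                for i in range(3)]


@pytest.fixture(scope="session")
def dead_fields(small_params):
    params = dataclasses.replace(small_params, viability_fraction=0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return [generate_bead_field(params, seed=200 + i) for i in range(3)]


@pytest.fixture(scope="session")
def matched_config(live_fields, dead_fields) -> CalibrationConfig:
    """Calibration fitted on the session's live/dead control fields."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return match_pi_setup(dead_fields, live_fields,
                              [600.0, 800.0, 1000.0, 2000.0])


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
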