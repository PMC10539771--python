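"""Shared fixtures.

The expensive fixture is a phase-matched 90/180 pair at the study
conditions (10 kHz rf, 50 kHz band, 720 us, Q = 0.8, +/-5 % Gaussian B1)
designed once per session by the same morphing pipeline as a production
run, at reduced resolution (1 us slices, 51 offsets, coarser ramp) so the
suite stays within minutes.
"""

import numpy as np
import pytest

from sordor.morph import design_pair

SMALL_PAIR_PARAMS = dict(nu1_hz=1e4, bandwidth_hz=5e4, tp=720e-6, q=0.8,
                         slice_duration=1e-6, ramp_start_hz=1e4,
                         ramp_step_hz=5e3, b1_range=0.05, n_b1=5,
                         n_offsets=101, ramp_iterations=400,
                         final_iterations=3000, seed=1)


@pytest.fixture(scope="session")
def small_pair():
    """Desk-scale optimised pair shared across validation tests."""
    return design_pair(**SMALL_PAIR_PARAMS)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
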