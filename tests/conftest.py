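"""Shared fixtures: a fast small-lattice case and the two-group study cohort."""

from __future__ import annotations

import numpy as np
import pytest

from biorange import phantom, pipeline


SMALL_CONFIG = dict(
    grid_shape=(64, 64, 64),
    body_radius=44.0,
    ptv_radius=14.0,
    ptv_offset=(-6.0, 0.0, 0.0),
    gantry_angles=(90.0, 255.0, 285.0),
    prescribed_dose=54.0,
    n_fractions=27,
)


@pytest.fixture(scope="session")
def small_case() -> phantom.PhantomCase:
    """A compact 3-field brain-like case for fast integration tests."""
    return phantom.generate_case(phantom.PhantomConfig(**SMALL_CONFIG), seed=7)


@pytest.fixture(scope="session")
def small_case_result(small_case):
    return pipeline.evaluate_case(small_case)


@pytest.fixture(scope="session")
def cohort():
    """The seeded study cohort: 10 brain-like + 10 skull-base-like cases."""
    return pipeline.run_cohort(n_brain=10, n_skullbase=10, seed=1234)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(99)
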