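"""Shared fixtures.

The expensive artifacts — the default-geometry phantom, the standard
corrupted scenario and the full mask optimizations — are session-scoped so
that the unit, property and end-to-end suites share one computation.
"""

import numpy as np
import pytest

from phimo.detect import DetectConfig, optimize_exclusion_masks
from phimo.phantom import make_digital_phantom
from phimo.recon import UnrolledConfig
from phimo.scenarios import standard_corruption_scenario


@pytest.fixture(scope="session")
def phantom8():
    """Default-geometry phantom (92 PE, 64 RO, 8 slices, 12 echoes)."""
    return make_digital_phantom(seed=0)


@pytest.fixture(scope="session")
def tiny_phantom():
    """Small phantom for operator-level tests."""
    return make_digital_phantom(pe=32, ro=32, n_slices=2, n_echoes=6, n_coils=2, seed=1)


@pytest.fixture(scope="session")
def scenario6(phantom8):
    """Standard corrupted scenario: single 6-mm event, 12 known lines/package."""
    return standard_corruption_scenario(seed=0, amplitude_mm=6.0, phantom=phantom8)


@pytest.fixture(scope="session")
def detection6(scenario6):
    """Full mask optimization on the standard 6-mm scenario."""
    ph, _, _, kspace, _ = scenario6
    mask_even, mask_odd, history = optimize_exclusion_masks(
        kspace, ph.csm, UnrolledConfig(), ph.brain_mask, ph.sg_map,
        DetectConfig(seed=0),
    )
    return mask_even, mask_odd, history


@pytest.fixture(scope="session")
def clean_detection(phantom8):
    """Full mask optimization on the motion-free phantom."""
    ph = phantom8
    return optimize_exclusion_masks(
        ph.clean_kspace, ph.csm, UnrolledConfig(), ph.brain_mask, ph.sg_map,
        DetectConfig(seed=0),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
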