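"""Shared fixtures.

The session-scoped fixtures at the bottom are the expensive simulation
artifacts shared by the acceptance tests (parameter-grid feature tables and
the recovery cohort); everything else is cheap.
"""

from __future__ import annotations

import numpy as np
import pytest

from reachseq import (
    GridSpec,
    PlantParams,
    default_grid,
    default_layout,
    generate_cohort,
    matched_grids,
    recovery_cohort,
    simulate_grid,
)


@pytest.fixture(scope="session")
def layout():
    return default_layout()


@pytest.fixture(scope="session")
def geom0(layout):
    """Sequence-0 geometry (blue -> olive -> home)."""
    return layout.sequence_geometry(0)


@pytest.fixture(scope="session")
def plant():
    """Canonical noisy plant used throughout the simulations."""
    return PlantParams(add_noise=8000.0)


@pytest.fixture(scope="session")
def quiet_plant():
    """Plant with every noise source off (deterministic dynamics)."""
    return PlantParams(sigma_c=0.0, sigma_s=0.0, add_noise=0.0)


# ---------------------------------------------------------------------------
# expensive shared artifacts (acceptance tests)
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def vpsoc_default_table(geom0):
    """Packaged vpSOC(3) grid simulated on sequence 0 (seed 0)."""
    table, failures = simulate_grid(default_grid("vpsoc3"), geom0)
    return table, failures


@pytest.fixture(scope="session")
def hiseq_default_table(geom0):
    """Packaged HiSeq grid simulated on sequence 0 (seed 0)."""
    table, failures = simulate_grid(default_grid("hiseq"), geom0)
    return table, failures


@pytest.fixture(scope="session")
def matched_tables(geom0):
    """Both models simulated over the identical matched grid (seed 1)."""
    vp_spec, hi_spec = matched_grids(n_trials=20, seed=1)
    vp, _ = simulate_grid(vp_spec, geom0)
    hi, _ = simulate_grid(hi_spec, geom0)
    return vp, hi


@pytest.fixture(scope="session")
def recovery_dataset(layout):
    """20-participant synthetic cohort, sequence 0 only (seed 100)."""
    return generate_cohort(recovery_cohort(seed=100), layout=layout)
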