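"""Shared fixtures: transfer tables are expensive, so they are computed once
per session (full default grid, the same one used in production runs)."""

import numpy as np
import pytest

from slowbrain import (
    NodeParams,
    compute_transfer_tables,
    synthetic_connectome,
)
from slowbrain.params import SLEEP_MODEL


@pytest.fixture(scope="session")
def table():
    """Transfer tables on the production grid (takes ~2 min once)."""
    return compute_transfer_tables()


@pytest.fixture(scope="session")
def connectome80():
    """The reference 80-region surrogate connectome."""
    return synthetic_connectome(80, seed=1)


@pytest.fixture(scope="session")
def sleep_params():
    """Node parameters of the reference sleep model (K_gl handled separately)."""
    return NodeParams(**{k: v for k, v in SLEEP_MODEL.items() if k != "K_gl"})


@pytest.fixture(scope="session")
def state_maps(table):
    """Noiseless 21 x 21 single-node state-space scans without (b = 0) and
    with (b = 20 pA, tau_A = 600 ms) spike-triggered adaptation."""
    from slowbrain import scan_grid

    m0 = scan_grid(NodeParams(b=0.0), table, resolution=21)
    m20 = scan_grid(NodeParams(b=20.0, tau_A=600.0), table, resolution=21)
    return m0, m20
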