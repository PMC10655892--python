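"""Shared fixtures: small deterministic systems and one reduced SAC.

The compacted-cylinder (SAC) ensemble is expensive to make, so it is
built once per session at reduced scale and shared by the contact-
scaling, valence and elasticity tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from condensac.config import RunConfig
from condensac.protocols import run_compaction


@pytest.fixture(scope="session")
def tiny_bbp():
    from condensac.fixtures import make_fixture

    return make_fixture("tiny_bbp")


@pytest.fixture(scope="session")
def random_system():
    """20-bead bottlebrush + 6 bridges in a periodic box (oracle tests)."""
    from condensac.topology import (
        build_uniform_bottlebrush,
        initial_bottlebrush_coords,
        place_bridges,
    )

    topo = build_uniform_bottlebrush(4, 5)
    pos = initial_bottlebrush_coords(topo, seed=3)
    bridges = place_bridges(6, 14.0, seed=4, near=pos)
    return topo, np.vstack([pos, bridges]), 14.0


@pytest.fixture(scope="session")
def sac_ensemble():
    """Reduced compacted chromosome: 100 Poisson loops, mean 80 kbp, A=1.

    The strong-topoisomerase corner compacts fastest; the run stops at
    the R_g plateau (or the 4000-tau budget).  Returns the full
    ProtocolResult; the final state in ``result.extras['state']`` is the
    steady-state SAC shared by the contact-probability, valence and
    pulling tests.
    """
    import warnings

    config = RunConfig(
        loop_mode="poisson",
        n_loops=100,
        L_loop_beads=40,
        A_kBT=1.0,
        n_bridges=150,
        seed=2024,
        phase_durations={"equilibration": 50.0, "compaction": 4000.0},
        snapshot_stride_tau=50.0,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_compaction(config)
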