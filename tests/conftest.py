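"""Shared fixtures: small toy systems plus one session-scoped SAMC run and
its independent uniform-walk reference (both reused by the acceptance tests)."""

from __future__ import annotations

import numpy as np
import pytest

from p20kit import prime20_model as pm
from p20kit import samc_sampler as ss

TOY_SEED = 2
SAMC_SEED = 7
ORACLE_SEED = 123
ORACLE_STEPS = 220_000


def make_bb_toy(params: pm.InteractionParams) -> pm.CGSystem:
    """Two 2-residue chains in a small periodic box (backbone wells only)."""
    return pm.build_system("QQ", 2, 14.0, seed=TOY_SEED, params=params)


@pytest.fixture(scope="session")
def bb_params() -> pm.InteractionParams:
    """Backbone-only parameters: sidechain wells disabled."""
    return pm.InteractionParams(sc_wells={})


@pytest.fixture(scope="session")
def bb_toy_config() -> ss.SamcConfig:
    return ss.SamcConfig(gamma0=1.0, t0=40.0, gamma_min=1e-4, seed=SAMC_SEED,
                         max_displacement=0.05, max_chain_translation=2.0)


@pytest.fixture(scope="session")
def bb_samc(bb_params, bb_toy_config):
    """One converged SAMC run on the backbone toy (shared; ~30 s)."""
    system = make_bb_toy(bb_params)
    dos = ss.run_samc(system, bb_toy_config, bb_params)
    return {"dos": dos, "system": system, "config": bb_toy_config,
            "params": bb_params}


@pytest.fixture(scope="session")
def bb_oracle(bb_params, bb_toy_config):
    """Uniform-measure reference walk on the same toy.

    Every constraint-valid move is accepted (symmetric proposals), so the
    stationary distribution is uniform over valid configurations and the
    level-occupation histogram is proportional to the density of states.
    This is an independent path through the public API: no DOS, no
    acceptance rule.
    """
    system = make_bb_toy(bb_params)
    rng = np.random.default_rng(ORACLE_SEED)
    occupancy: dict[tuple[int, int], int] = {}
    current = pm.count_interactions(system, bb_params).as_tuple()
    for _ in range(ORACLE_STEPS):
        proposal = ss.propose_move(system, bb_toy_config, rng, bb_params)
        if proposal.valid:
            pm.apply_proposal(system, proposal)
            current = pm.count_interactions(system, bb_params).as_tuple()
        occupancy[current] = occupancy.get(current, 0) + 1
    return occupancy


@pytest.fixture(scope="session")
def sc_params() -> pm.InteractionParams:
    """Sidechain-only parameters: backbone well disabled, SC-SC well only."""
    return pm.InteractionParams(hb_well=None,
                                sc_wells={("SC", "SC"): (4.7, 6.1)})


def make_sc_toy(params: pm.InteractionParams) -> pm.CGSystem:
    """Two single-residue chains; reachable levels are (0, 0) and (0, 1)."""
    return pm.build_system("Q", 2, 12.0, seed=5, params=params)
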