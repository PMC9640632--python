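"""Shared fixtures: networks, stand-in rate tables, and prebuilt CTMCs."""

from __future__ import annotations

import numpy as np
import pytest

from metcheck.ctmc_engine import build_ctmc
from metcheck.network_model import load_default_network, parse_network
from metcheck.rate_instantiation import (
    load_default_chain_map,
    tables_from_raw,
)
from metcheck.synthetic_data import MFA_REFERENCE, simulate_mfa_table

ONE_REACTION = """
species A init=1 max=1
species B init=0 max=1
R: A -> B @ k
"""

PING_PONG = """
species A init=1 max=1
species B init=0 max=1
F: A -> B @ lam
G: B -> A @ mu
"""

CHAIN_3 = """
species A init=1 max=1
species B init=0 max=1
species C init=0 max=1
R1: A -> B @ k1
R2: B -> C @ k2
"""


@pytest.fixture(scope="session")
def default_model():
    return load_default_network()


@pytest.fixture(scope="session")
def standin_tables():
    """Four-phenotype rate tables from the synthetic MFA stand-in (seed 1)."""
    raw = simulate_mfa_table(seed=1)
    chains = load_default_chain_map()
    return tables_from_raw(raw, chains, MFA_REFERENCE)


@pytest.fixture(scope="session")
def wt_normoxia_ctmc(default_model, standin_tables):
    """Full default network (caps 5, nutrients 5) under wild-type normoxia."""
    return build_ctmc(default_model, standin_tables[("IDHwt", "normoxia")])


@pytest.fixture()
def one_reaction():
    def make(k: float = 1.0):
        model = parse_network(ONE_REACTION)
        return model, {"k": k}

    return make


@pytest.fixture()
def ping_pong():
    def make(lam: float, mu: float):
        model = parse_network(PING_PONG)
        return model, {"lam": lam, "mu": mu}

    return make


@pytest.fixture()
def chain3():
    def make(k1: float, k2: float):
        model = parse_network(CHAIN_3)
        return model, {"k1": k1, "k2": k2}

    return make


def random_ctmc(rng: np.random.Generator, n_states: int):
    """Random dense-ish CTMC wrapped in the engine's container (test oracle aid)."""
    import scipy.sparse as sp

    from metcheck.ctmc_engine import CTMC

    Q = rng.uniform(0.0, 2.0, (n_states, n_states))
    Q *= rng.random((n_states, n_states)) < 0.3
    np.fill_diagonal(Q, 0.0)
    R = sp.csr_matrix(Q)
    model = parse_network(ONE_REACTION)  # placeholder model; unused by kernels
    return (
        CTMC(
            model=model,
            states=np.arange(n_states, dtype=np.int16).reshape(-1, 1),
            initial_indices=(0,),
            rate_matrix=R,
            exit_rates=np.asarray(R.sum(axis=1)).ravel(),
            command_transitions={},
        ),
        Q,
    )
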